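"""Region-level volume of activation, composite maps and group comparisons.

The per-subject voxel map is reduced to a *volume of activation* (VOA) per
atlas region: the number of activated voxels of a given sign, plus their
mean percent change.  Group-level inference mirrors the published table
logic: per region and window, the per-subject VOA counts of a treatment arm
are compared to vehicle with the (tie-corrected) Kruskal-Wallis rank test,
and a region is called significantly different when p <= 0.05.  The single
count printed per group in such tables is taken from the group *composite
map* — the voxel-wise average of the subjects' percent-change maps,
retaining voxels activated in at least ``min_frequency`` of subjects
(default 0.5) — while the p-value always comes from the per-subject count
distributions.  No correction across regions is applied by default (the
published tables apply none); BH across regions is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import Atlas
from .voxel_stats import VoxelStatMap, fdr_adjust

__all__ = [
    "CompositeMap",
    "volume_of_activation",
    "composite_map",
    "composite_region_counts",
    "kruskal_wallis_region",
    "pairwise_group_tables",
    "significant_region_table",
]


def volume_of_activation(
    statmap: VoxelStatMap, labels: np.ndarray, sign: int = +1
) -> pd.DataFrame:
    """Per-region activated-voxel counts and mean percent change, per window.

    Counts voxels with ``activated`` true and the requested sign (+1 or -1).
    Regions with no activated voxel report count 0 and mean change 0.0.
    Columns: subject_id, treatment, region_id, window, activated_voxels,
    mean_pct_change.
    """
    labels = np.asarray(labels)
    if labels.shape != statmap.grid_shape:
        raise ValueError("label grid does not match stat map grid")
    region_ids = np.unique(labels[labels > 0])
    rows = []
    for window, w in statmap.windows.items():
        act = w.activated & (w.sign == np.sign(sign))
        for rid in region_ids:
            in_region = act & (labels == rid)
            n = int(in_region.sum())
            mean_pct = float(w.pct_change[in_region].mean()) if n else 0.0
            rows.append(
                {
                    "subject_id": statmap.subject_id,
                    "treatment": statmap.treatment,
                    "region_id": int(rid),
                    "window": window,
                    "activated_voxels": n,
                    "mean_pct_change": mean_pct,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "treatment",
            "region_id",
            "window",
            "activated_voxels",
            "mean_pct_change",
        ],
    )


@dataclass
class CompositeMap:
    """Group composite of per-subject stat maps for one window.

    ``mean_pct`` is the voxel-wise mean percent change across subjects;
    ``frequency`` the fraction of subjects in which the voxel is activated
    (with the requested sign); ``retained`` the display mask
    (frequency >= min_frequency).
    """

    window: str
    sign: int
    min_frequency: float
    mean_pct: np.ndarray
    frequency: np.ndarray
    retained: np.ndarray
    n_subjects: int


def composite_map(
    statmaps: Sequence[VoxelStatMap],
    window: str,
    min_frequency: float = 0.5,
    sign: int = +1,
) -> CompositeMap:
    """Voxel-by-voxel average of subjects' percent-change maps for one window."""
    if not statmaps:
        raise ValueError("need at least one stat map")
    shape = statmaps[0].grid_shape
    if any(m.grid_shape != shape for m in statmaps):
        raise ValueError("stat maps do not share a common grid")
    pct = np.zeros(shape)
    freq = np.zeros(shape)
    for m in statmaps:
        w = m.windows[window]
        pct += np.nan_to_num(w.pct_change, nan=0.0)
        freq += (w.activated & (w.sign == np.sign(sign))).astype(float)
    n = len(statmaps)
    pct /= n
    freq /= n
    retained = (freq >= min_frequency) & (freq > 0)
    return CompositeMap(
        window=window,
        sign=int(np.sign(sign)),
        min_frequency=min_frequency,
        mean_pct=pct,
        frequency=freq,
        retained=retained,
        n_subjects=n,
    )


def composite_region_counts(comp: CompositeMap, labels: np.ndarray) -> dict[int, int]:
    """Retained-voxel count per region of a composite map."""
    labels = np.asarray(labels)
    sel = labels[comp.retained & (labels > 0)]
    ids, counts = np.unique(sel, return_counts=True)
    out = {int(i): 0 for i in np.unique(labels[labels > 0])}
    out.update({int(i): int(c) for i, c in zip(ids, counts)})
    return out


def kruskal_wallis_region(
    counts_by_group: Mapping[str, Sequence[float]],
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p over per-subject counts.

    All observations identical (a common case for all-zero VOA counts)
    yields H = 0, p = 1.
    """
    groups = [np.asarray(v, dtype=float) for v in counts_by_group.values()]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _kw_table_for_pair(
    voa: pd.DataFrame,
    comp_counts: Mapping[str, Mapping[int, int]],
    atlas: Atlas,
    window: str,
    group_a: str,
    group_b: str,
    alpha: float,
    adjust: str,
) -> pd.DataFrame:
    sub = voa[voa["window"] == window]
    rows = []
    for rid in atlas.region_ids:
        reg = sub[sub["region_id"] == rid]
        counts = {
            g: reg.loc[reg["treatment"] == g, "activated_voxels"].to_numpy()
            for g in (group_a, group_b)
        }
        h, p = kruskal_wallis_region(counts)
        rows.append(
            {
                "region_id": rid,
                "region_name": atlas.region_name(rid),
                "window": window,
                f"count_{group_a}": comp_counts[group_a].get(rid, 0),
                f"count_{group_b}": comp_counts[group_b].get(rid, 0),
                "kw_H": h,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    if adjust == "fdr_bh":
        table["p_value"], _ = fdr_adjust(table["p_value"].to_numpy(), q=alpha)
    elif adjust != "none":
        raise ValueError(f"unknown adjust option {adjust!r}")
    table["significant"] = table["p_value"] <= alpha
    return table


def pairwise_group_tables(
    statmaps: Sequence[VoxelStatMap],
    labels: np.ndarray,
    atlas: Atlas,
    control: str = "vehicle",
    windows: Sequence[str] | None = None,
    alpha: float = 0.05,
    min_frequency: float = 0.5,
    sign: int = +1,
    adjust: str = "none",
) -> dict[str, pd.DataFrame]:
    """Treatment-vs-control VOA comparison tables, one per treatment.

    For every region and window: Kruskal-Wallis on the per-subject activated
    voxel counts of the two arms, with per-group representative counts taken
    from each arm's composite map.  ``significant`` is p <= alpha.
    """
    treatments = sorted({m.treatment for m in statmaps})
    if control not in treatments:
        raise ValueError(f"control group {control!r} absent from cohort")
    if windows is None:
        windows = statmaps[0].scheme.names
    voa = pd.concat(
        [volume_of_activation(m, labels, sign=sign) for m in statmaps],
        ignore_index=True,
    )
    by_group = {t: [m for m in statmaps if m.treatment == t] for t in treatments}
    out: dict[str, pd.DataFrame] = {}
    for treatment in treatments:
        if treatment == control:
            continue
        tables = []
        for window in windows:
            comp_counts = {
                g: composite_region_counts(
                    composite_map(by_group[g], window, min_frequency, sign), labels
                )
                for g in (control, treatment)
            }
            tables.append(
                _kw_table_for_pair(
                    voa[voa["treatment"].isin([control, treatment])],
                    comp_counts,
                    atlas,
                    window,
                    control,
                    treatment,
                    alpha,
                    adjust,
                )
            )
        out[treatment] = pd.concat(tables, ignore_index=True)
    return out


def significant_region_table(
    rows: pd.DataFrame, window: str | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Filter a comparison table to significant regions, sorted by ascending p.

    Keeps rows with ``p_value <= alpha`` (optionally restricted to one
    window) — the machine twin of the bold rows of a published VOA table.
    """
    if "p_value" not in rows.columns:
        raise ValueError("table must carry a p_value column")
    table = rows
    if window is not None:
        if "window" not in table.columns:
            raise ValueError("table has no window column to filter on")
        table = table[table["window"] == window]
    table = table[table["p_value"] <= alpha]
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)
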