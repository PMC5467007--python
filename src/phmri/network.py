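"""Circuit-level BOLD time courses and group-by-time statistics.

A circuit (network) time course is the mean percent BOLD change, relative
to each voxel's own baseline mean, over all voxels of the circuit's
regions, evaluated at every post-treatment acquisition (450 values for a
500-volume session with a 50-volume baseline).  Window means of those
series feed a two-way mixed-design ANOVA — treatment group as the
between-subject factor, analysis window as the within-subject factor —
whose group x window interaction tests whether treatments diverge over
time.  Dunnett's many-to-one procedure then compares each treatment to the
vehicle control within a window while controlling the family-wise error of
the multiple treatment contrasts.

The mixed ANOVA is computed from its sums-of-squares decomposition here
(the interaction mean square over the within-subject error mean square);
no sphericity correction is applied by default, as the within factor has
only three levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import Atlas
from .session import BoldSession
from .voxel_stats import WindowScheme

__all__ = [
    "NetworkTimeCourse",
    "network_series",
    "rm_anova_interaction",
    "dunnett_vs_control",
    "RmAnovaResult",
]


@dataclass
class NetworkTimeCourse:
    """Mean circuit %BOLD change per post-treatment acquisition, plus window means."""

    subject_id: str
    treatment: str
    network: str
    acquisitions: np.ndarray  # 1-based acquisition indices (post-baseline)
    series: np.ndarray  # mean % BOLD change at each acquisition
    window_means: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "treatment": self.treatment,
                "network": self.network,
                "acquisition": self.acquisitions,
                "pct_bold": self.series,
            }
        )


def network_series(
    session: BoldSession,
    labels: np.ndarray,
    atlas: Atlas,
    network: str,
    scheme: WindowScheme | None = None,
) -> NetworkTimeCourse:
    """Circuit-mean percent-change series of one session.

    Each voxel's series is converted to percent change about its own
    baseline mean; the circuit value at an acquisition is the plain mean
    over all member-region voxels (so larger regions weigh proportionally
    to their voxel count).  Voxels with zero baseline mean are excluded.
    """
    scheme = scheme if scheme is not None else WindowScheme()
    regions = atlas.network_regions(network)
    labels = np.asarray(labels)
    if labels.shape != session.grid_shape:
        raise ValueError("label grid does not match session grid")
    mask = np.isin(labels, list(regions))
    if not mask.any():
        raise ValueError(f"network {network!r} covers no voxels on this grid")
    series = session.data[mask]  # (n_voxels, T)
    mb = series[:, scheme.baseline_slice()].mean(axis=1)
    ok = mb != 0
    if not ok.any():
        raise ValueError(f"network {network!r} has no voxels with nonzero baseline")
    pct = 100.0 * (series[ok] - mb[ok, None]) / mb[ok, None]
    mean_pct = pct.mean(axis=0)

    post_start = scheme.baseline[1]  # first post-baseline acquisition, 1-based
    acqs = np.arange(post_start, session.n_acquisitions + 1)
    post = mean_pct[post_start - 1 :]
    window_means = {
        name: float(mean_pct[scheme.window_slice(name)].mean())
        for name in scheme.names
    }
    return NetworkTimeCourse(
        subject_id=session.subject_id,
        treatment=session.treatment,
        network=network,
        acquisitions=acqs,
        series=post,
        window_means=window_means,
    )


class RmAnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


def rm_anova_interaction(window_means: pd.DataFrame) -> RmAnovaResult:
    """Group x window interaction of a two-way mixed-design ANOVA.

    ``window_means`` must carry columns ``subject``, ``group``, ``window``
    and ``value``, with every subject observed in every window (a complete
    repeated-measures layout).  Groups may be unbalanced in size.  Returns
    the interaction F, its degrees of freedom (g-1)(w-1) and (N-g)(w-1),
    and the p-value from the F reference distribution.
    """
    df = window_means
    required = {"subject", "group", "window", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"window_means needs columns {sorted(required)}")
    wide = df.pivot_table(index=["group", "subject"], columns="window", values="value")
    if wide.isna().any().any():
        raise ValueError("unbalanced design: some subjects are missing windows")
    groups = wide.index.get_level_values("group")
    g = groups.nunique()
    w = wide.shape[1]
    if g < 2 or w < 2:
        raise ValueError("need >= 2 groups and >= 2 windows")
    Y = wide.to_numpy()  # (N subjects, w windows)
    N = Y.shape[0]

    subj_mean = Y.mean(axis=1)  # per subject
    group_labels = groups.to_numpy()
    uniq = pd.unique(group_labels)
    cell_mean = np.vstack([Y[group_labels == lab].mean(axis=0) for lab in uniq])  # (g, w)
    n_j = np.array([(group_labels == lab).sum() for lab in uniq])
    group_mean = cell_mean.mean(axis=1)  # per group, over windows
    win_mean = (n_j[:, None] * cell_mean).sum(axis=0) / N  # weighted column means
    grand = (n_j * group_mean).sum() / N

    # interaction: weighted cell deviations from additivity
    dev = cell_mean - group_mean[:, None] - win_mean[None, :] + grand
    ss_int = float((n_j[:, None] * dev**2).sum())
    # within-subject error: subject x window residual within groups
    resid = np.empty_like(Y)
    for lab, cm in zip(uniq, cell_mean):
        sel = group_labels == lab
        resid[sel] = Y[sel] - subj_mean[sel, None] - cm[None, :] + cm.mean()
    ss_err = float((resid**2).sum())

    df1 = (g - 1) * (w - 1)
    df2 = (N - g) * (w - 1)
    if df2 <= 0:
        raise ValueError("not enough subjects for the within-subject error term")
    ms_int = ss_int / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        f_stat = 0.0 if ms_int == 0 else float("inf")
        p = 1.0 if ms_int == 0 else 0.0
    else:
        f_stat = ms_int / ms_err
        p = float(stats.f.sf(f_stat, df1, df2))
    return RmAnovaResult(F=float(f_stat), df1=df1, df2=df2, p=p)


def dunnett_vs_control(
    window_means: Mapping[str, Sequence[float]] | pd.DataFrame,
    control: str = "vehicle",
    window: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett many-to-one comparisons of each treatment against the control.

    Accepts either a mapping group -> observations or a long DataFrame with
    columns ``group``, ``value`` (and optionally ``window`` to select on).
    Returns a DataFrame with columns ``treatment``, ``statistic``,
    ``p_adj`` — two-sided p-values adjusted for the multiplicity of the
    treatment-vs-control contrasts via the multivariate-t distribution of
    the contrast statistics.

    With a single treatment group the procedure degenerates to the pooled-
    variance two-sample t-test, which is computed in closed form; with
    several treatments the multivariate-t tail probability is evaluated
    numerically (``seed`` fixes the quadrature for reproducibility).
    """
    if isinstance(window_means, pd.DataFrame):
        df = window_means
        if window is not None:
            df = df[df["window"] == window]
        data = {g: grp["value"].to_numpy(dtype=float) for g, grp in df.groupby("group")}
    else:
        data = {g: np.asarray(v, dtype=float) for g, v in window_means.items()}
    if control not in data:
        raise ValueError(f"control group {control!r} missing")
    treatments = [g for g in data if g != control]
    if not treatments:
        raise ValueError("need at least one treatment group")
    if len(treatments) == 1:
        a, b = data[control], data[treatments[0]]
        n_a, n_b = a.size, b.size
        dof = n_a + n_b - 2
        s2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / dof
        diff = b.mean() - a.mean()
        if s2 == 0:
            t_stat = 0.0 if diff == 0 else np.sign(diff) * np.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            t_stat = diff / np.sqrt(s2 * (1.0 / n_a + 1.0 / n_b))
            p = 2.0 * stats.t.sf(abs(t_stat), dof)
        stat, pvals = np.array([t_stat]), np.array([p])
    else:
        res = stats.dunnett(
            *(data[t] for t in treatments),
            control=data[control],
            alternative="two-sided",
            rng=np.random.default_rng(seed),
        )
        stat, pvals = np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)
    return pd.DataFrame({"treatment": treatments, "statistic": stat, "p_adj": pvals})
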