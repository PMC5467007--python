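"""End-to-end orchestration: simulate a cohort, analyze it, write results.

``run_simulate`` writes a synthetic cohort (atlas, 4D NIfTI sessions,
manifest, ground-truth response spec).  ``run_analyze`` runs the full
analysis on a cohort directory: per-session drift correction and smoothing,
voxel-wise activation maps, per-region volume-of-activation tables with
treatment-vs-vehicle Kruskal-Wallis comparisons, group composite maps, and
circuit time courses with the mixed ANOVA and Dunnett post-hoc tests.  All
outputs are CSV/NIfTI plus a machine-readable JSON run log from which the
exact configuration can be re-created.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import Atlas, load_atlas, save_atlas
from .config import PipelineConfig
from .network import NetworkTimeCourse, dunnett_vs_control, network_series, rm_anova_interaction
from .preprocess import correct_drift, estimate_drift, global_mean_series, smooth_gaussian
from .registration import propagate_labels
from .roi_stats import composite_map, pairwise_group_tables, significant_region_table
from .session import BoldSession
from .simulate import (
    DEFAULT_GROUP_SIZES,
    ResponseSpec,
    SessionConfig,
    generate_atlas,
    generate_cohort,
    load_cohort,
    write_cohort,
)
from .voxel_stats import VoxelStatMap, activation_map

__all__ = ["run_simulate", "run_analyze", "AnalysisResults"]


def run_simulate(
    config: PipelineConfig,
    response_spec: ResponseSpec,
    session_config: SessionConfig | None = None,
    group_sizes: Mapping[str, int] = DEFAULT_GROUP_SIZES,
    n_regions: int = 12,
) -> pd.DataFrame:
    """Generate and write a synthetic cohort; returns the manifest.

    The atlas is loaded from the configured paths when present, otherwise
    generated (deterministically from ``config.seed``) and written there.
    """
    cfg = session_config if session_config is not None else SessionConfig()
    label_path = Path(config.atlas_labels)
    if label_path.exists():
        atlas = load_atlas(config.atlas_labels, config.atlas_regions, config.atlas_networks)
    else:
        label_path.parent.mkdir(parents=True, exist_ok=True)
        atlas = generate_atlas(cfg.shape, n_regions=n_regions, seed=config.seed,
                               voxel_size=cfg.voxel_size)
        save_atlas(atlas, config.atlas_labels, config.atlas_regions, config.atlas_networks)
    sessions = generate_cohort(atlas, response_spec, cfg, group_sizes, seed=config.seed)
    out_dir = Path(config.manifest).parent
    manifest = write_cohort(sessions, out_dir)
    response_spec.to_yaml(out_dir / "ground_truth.yaml")
    return manifest


@dataclass
class AnalysisResults:
    """In-memory results of a full pipeline run."""

    statmaps: list[VoxelStatMap]
    drift_log: pd.DataFrame
    group_tables: dict[str, pd.DataFrame]
    network_stats: pd.DataFrame
    timecourses: list[NetworkTimeCourse] = field(default_factory=list)
    run_log: dict = field(default_factory=dict)


def _analyze_session(
    session: BoldSession, atlas: Atlas, config: PipelineConfig
) -> tuple[VoxelStatMap, dict, np.ndarray, BoldSession]:
    series = global_mean_series(session, atlas)
    est = estimate_drift(series, session.tr_seconds, limit=config.drift_limit)
    session = correct_drift(session, est)
    session = smooth_gaussian(session, config.fwhm_mm)
    labels = propagate_labels(session, atlas)
    statmap = activation_map(
        session,
        labels,
        scheme=config.scheme(),
        threshold_pct=config.threshold_pct,
        q=config.fdr_q,
    )
    drift_row = {
        "subject_id": session.subject_id,
        "slope_pct_per_min": est.slope,
        "corrected": est.corrected,
    }
    return statmap, drift_row, labels, session


def run_analyze(
    config: PipelineConfig,
    sessions: list[BoldSession] | None = None,
    atlas: Atlas | None = None,
    write_maps: bool = False,
) -> AnalysisResults:
    """Run the full analysis; writes tables and the run log to the output dir.

    ``sessions`` / ``atlas`` may be passed in-memory (e.g. straight from the
    simulator); otherwise they are loaded from the configured paths.
    """
    if atlas is None:
        atlas = load_atlas(config.atlas_labels, config.atlas_regions, config.atlas_networks)
    if sessions is None:
        sessions = load_cohort(config.manifest)
    if not sessions:
        raise ValueError("empty cohort")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    statmaps: list[VoxelStatMap] = []
    drift_rows: list[dict] = []
    labels = None
    tc_frames: list[pd.DataFrame] = []
    timecourses: list[NetworkTimeCourse] = []
    scheme = config.scheme()
    window_mean_rows: list[dict] = []
    for session in sessions:
        statmap, drift_row, labels, preprocessed = _analyze_session(session, atlas, config)
        statmaps.append(statmap)
        drift_rows.append(drift_row)
        if write_maps:
            statmap.to_nifti(out / "statmaps", voxel_size=session.voxel_size)
        for network in atlas.networks:
            tc = network_series(preprocessed, labels, atlas, network, scheme)
            timecourses.append(tc)
            tc_frames.append(tc.to_frame())
            for window, value in tc.window_means.items():
                window_mean_rows.append(
                    {
                        "subject": tc.subject_id,
                        "group": tc.treatment,
                        "network": network,
                        "window": window,
                        "value": value,
                    }
                )

    drift_log = pd.DataFrame(drift_rows, columns=["subject_id", "slope_pct_per_min", "corrected"])
    drift_log.to_csv(out / "drift_log.csv", index=False)

    group_tables = pairwise_group_tables(
        statmaps,
        labels,
        atlas,
        control=config.control_group,
        alpha=config.alpha,
        min_frequency=config.min_frequency,
    )
    for treatment, table in group_tables.items():
        table.to_csv(out / f"voa_{treatment}_vs_{config.control_group}.csv", index=False)
        for window in scheme.names:
            sig = significant_region_table(table, window=window, alpha=config.alpha)
            tag = window.replace("-", "_")
            sig.to_csv(out / f"significant_{treatment}_w{tag}.csv", index=False)

    # composite maps per group and window (retained-voxel count recorded in log)
    composite_counts: dict[str, dict[str, int]] = {}
    groups = sorted({m.treatment for m in statmaps})
    for group in groups:
        maps = [m for m in statmaps if m.treatment == group]
        composite_counts[group] = {}
        for window in scheme.names:
            comp = composite_map(maps, window, min_frequency=config.min_frequency)
            composite_counts[group][window] = int(comp.retained.sum())

    # network-level statistics
    net_rows: list[dict] = []
    wm = pd.DataFrame(window_mean_rows)
    if not wm.empty:
        pd.concat(tc_frames, ignore_index=True).to_csv(
            out / "network_timecourses.csv", index=False
        )
        wm.to_csv(out / "network_window_means.csv", index=False)
        for network, sub in wm.groupby("network"):
            anova = rm_anova_interaction(sub)
            row = {
                "network": network,
                "interaction_F": anova.F,
                "df1": anova.df1,
                "df2": anova.df2,
                "p_value": anova.p,
            }
            net_rows.append(row)
            if sub["group"].nunique() >= 2 and config.control_group in set(sub["group"]):
                for window in scheme.names:
                    dn = dunnett_vs_control(
                        sub.rename(columns={"group": "group"}),
                        control=config.control_group,
                        window=window,
                    )
                    for r in dn.itertuples():
                        net_rows.append(
                            {
                                "network": network,
                                "window": window,
                                "treatment": r.treatment,
                                "dunnett_p_adj": r.p_adj,
                            }
                        )
    network_stats = pd.DataFrame(net_rows)
    network_stats.to_csv(out / "network_stats.csv", index=False)

    run_log = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_subjects": len(sessions),
        "groups": {g: sum(m.treatment == g for m in statmaps) for g in groups},
        "drift": drift_rows,
        "activated_voxels": {
            m.subject_id: {w: m.activated_count(w) for w in scheme.names} for m in statmaps
        },
        "composite_retained_voxels": composite_counts,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=float))

    return AnalysisResults(
        statmaps=statmaps,
        drift_log=drift_log,
        group_tables=group_tables,
        network_stats=network_stats,
        timecourses=timecourses,
        run_log=run_log,
    )
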