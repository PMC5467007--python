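"""Synthetic atlas-space 4D BOLD cohorts with known ground truth.

The simulator emulates the acquisition design the analysis assumes: a
continuous session of ``n_acquisitions`` volumes at a fixed TR (default 500
volumes at 6.0 s = 50 min), the first 50 forming a pre-injection baseline,
followed by a drug response.  Each voxel of region r carries

    v(t) = baseline_level * (1 + response_r(t)/100 + eps(t)/100) * (1 + drift(t)/100)

where drift is a gain linear in minutes (``drift_slope`` %/min) applied
multiplicatively — scanner drift scales the measured signal, and this
composition is exactly what division-based drift correction removes —, the response is a
ramp-to-plateau kernel per (treatment, region) — onset acquisition, ramp
duration, plateau amplitude in percent of baseline — and eps is independent
Gaussian noise with standard deviation ``noise_sd`` percent.  Background
voxels are zero, mimicking brain-extracted data.  The ramp kernel is used
instead of a haemodynamic basis function because the downstream analysis
only consumes window means, which the ramp parameterises transparently.

The default grid is a reduced 24x24x12 desk-scale volume; the acquisition
geometry of the emulated study (96x96 in-plane matrix over a 3.0 cm field
of view, 22 slices) is available via :meth:`SessionConfig.paper_scale`.

What the simulator deliberately omits: head motion, slice-timing offsets,
susceptibility distortion, physiological noise and temporal autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .atlas import Atlas
from .session import BoldSession

__all__ = [
    "RegionResponse",
    "ResponseSpec",
    "SessionConfig",
    "DEFAULT_GROUP_SIZES",
    "generate_atlas",
    "generate_session",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

#: Treatment-arm sizes of the emulated four-arm cohort design.
DEFAULT_GROUP_SIZES: Mapping[str, int] = {
    "vehicle": 9,
    "idalopirdine": 10,
    "donepezil": 8,
    "combination": 9,
}

N_BASELINE = 50  # acquisitions before drug presentation


@dataclass(frozen=True)
class RegionResponse:
    """Ramp-to-plateau drug response of one region under one treatment.

    ``onset_acquisition`` is 1-based and must fall after the 50-acquisition
    baseline.  With ``ramp_duration`` 0 the response steps straight to
    ``plateau_amplitude_pct`` (percent of baseline; negative allowed for
    negative BOLD); otherwise it rises linearly over that many acquisitions.
    """

    onset_acquisition: int = N_BASELINE + 1
    ramp_duration: int = 0
    plateau_amplitude_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.onset_acquisition <= N_BASELINE:
            raise ValueError(
                f"onset_acquisition must be > {N_BASELINE} (post-baseline), "
                f"got {self.onset_acquisition}"
            )
        if self.ramp_duration < 0:
            raise ValueError("ramp_duration must be non-negative")
        if not np.isfinite(self.plateau_amplitude_pct):
            raise ValueError("plateau_amplitude_pct must be finite")

    def profile(self, n_acquisitions: int) -> np.ndarray:
        """Response amplitude (%) at each acquisition 1..n (0-based array)."""
        k = np.arange(1, n_acquisitions + 1)
        amp = self.plateau_amplitude_pct
        if self.ramp_duration == 0:
            return np.where(k >= self.onset_acquisition, amp, 0.0)
        frac = np.clip((k - self.onset_acquisition + 1) / self.ramp_duration, 0.0, 1.0)
        return np.where(k >= self.onset_acquisition, amp * frac, 0.0)


class ResponseSpec:
    """Ground-truth drug-response profiles keyed by (treatment, region_id).

    Treatments absent from the mapping (e.g. vehicle) respond nowhere.
    """

    def __init__(self, responses: Mapping[tuple[str, int], RegionResponse] | None = None):
        self.responses: dict[tuple[str, int], RegionResponse] = dict(responses or {})

    def for_treatment(self, treatment: str) -> dict[int, RegionResponse]:
        return {
            rid: resp
            for (trt, rid), resp in self.responses.items()
            if trt == treatment
        }

    def treatments(self) -> set[str]:
        return {trt for trt, _ in self.responses}

    def region_ids(self) -> set[int]:
        return {rid for _, rid in self.responses}

    # -- serialisation -------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = [
            {
                "treatment": trt,
                "region_id": rid,
                "onset_acquisition": r.onset_acquisition,
                "ramp_duration": r.ramp_duration,
                "plateau_amplitude_pct": r.plateau_amplitude_pct,
            }
            for (trt, rid), r in sorted(self.responses.items())
        ]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ResponseSpec":
        doc = yaml.safe_load(Path(path).read_text()) or []
        responses = {
            (str(d["treatment"]), int(d["region_id"])): RegionResponse(
                onset_acquisition=int(d.get("onset_acquisition", N_BASELINE + 1)),
                ramp_duration=int(d.get("ramp_duration", 0)),
                plateau_amplitude_pct=float(d.get("plateau_amplitude_pct", 0.0)),
            )
            for d in doc
        }
        return cls(responses)


@dataclass(frozen=True)
class SessionConfig:
    """Acquisition geometry and noise model of one simulated session."""

    shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_acquisitions: int = 500
    tr_seconds: float = 6.0
    baseline_level: float = 1000.0
    noise_sd: float = 1.0  # percent of baseline
    drift_slope: float = 0.0  # percent signal per minute
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_acquisitions < 60:
            raise ValueError("n_acquisitions must be >= 60 (baseline plus a window)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def paper_scale(cls, **overrides) -> "SessionConfig":
        """Full acquisition geometry: 96x96 matrix over a 3.0 cm FOV, 22 slices."""
        params = dict(
            shape=(96, 96, 22),
            voxel_size=(30.0 / 96, 30.0 / 96, 1.0),  # mm
        )
        params.update(overrides)
        return cls(**params)


def generate_atlas(
    shape: tuple[int, int, int],
    n_regions: int,
    seed: int,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    networks: bool = True,
) -> Atlas:
    """Deterministically pack ``n_regions`` rectangular region blobs into a grid.

    The grid is divided into 4-voxel cells; each region occupies a random
    block of 2-3 voxels per axis inside its own cell, guaranteeing at least
    one background voxel between regions.  Region ids are 1..n_regions.
    When ``networks`` is true, three overlapping circuits are defined over
    the regions round-robin (the third doubles as members of the first for
    n >= 6), exercising the overlapping-circuit case.

    Raises if the grid cannot host the requested number of regions.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    cell = 4
    cells_per_axis = [s // cell for s in shape]
    n_cells = int(np.prod(cells_per_axis))
    if n_cells < n_regions:
        raise ValueError(
            f"grid {shape} hosts at most {n_cells} regions; {n_regions} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_cells, size=n_regions, replace=False)
    labels = np.zeros(shape, dtype=np.int32)
    for rid, c in enumerate(np.sort(chosen), start=1):
        ci, cj, ck = np.unravel_index(c, cells_per_axis)
        sizes = rng.integers(2, cell, size=3)  # 2..3 voxels per axis
        x0, y0, z0 = ci * cell, cj * cell, ck * cell
        labels[x0 : x0 + sizes[0], y0 : y0 + sizes[1], z0 : z0 + sizes[2]] = rid
    regions = pd.DataFrame(
        {
            "region_id": np.arange(1, n_regions + 1),
            "region_name": [f"region_{i:03d}" for i in range(1, n_regions + 1)],
        }
    )
    nets: dict[str, frozenset[int]] = {}
    if networks:
        names = ["extended_amygdala", "striato_pallidal", "septo_hippocampal"]
        ids = list(range(1, n_regions + 1))
        for i, name in enumerate(names[: max(1, min(3, n_regions))]):
            members = set(ids[i::3])
            if members:
                nets[name] = frozenset(members)
        # circuits overlap in real anatomy; share one region across the
        # first two circuits when possible
        if len(nets) >= 2 and n_regions >= 2:
            first, second = list(nets)[:2]
            nets[first] = nets[first] | {min(nets[second])}
    return Atlas(labels=labels, voxel_size=voxel_size, regions=regions, networks=nets)


def generate_session(
    atlas: Atlas,
    spec: ResponseSpec,
    cfg: SessionConfig,
    treatment: str,
    subject_id: str = "sim",
) -> BoldSession:
    """Simulate one 4D session for ``treatment`` on the given atlas.

    Noise is drawn only for in-brain voxels; background stays exactly zero.
    With ``noise_sd=0`` and ``drift_slope=0`` the post-plateau mean of a
    responsive region equals ``baseline_level * (1 + amplitude/100)``.
    """
    if atlas.shape != cfg.shape:
        raise ValueError(f"atlas grid {atlas.shape} does not match config grid {cfg.shape}")
    responses = spec.for_treatment(treatment)
    known = set(atlas.region_ids)
    missing = set(responses) - known
    if missing:
        raise ValueError(f"response spec references missing regions {sorted(missing)}")

    T = cfg.n_acquisitions
    t_min = np.arange(T) * cfg.tr_seconds / 60.0
    gain = 1.0 + cfg.drift_slope * t_min / 100.0  # multiplicative scanner drift

    frac = np.zeros(cfg.shape + (T,))
    for rid, resp in responses.items():
        frac[atlas.labels == rid, :] += resp.profile(T) / 100.0

    brain = atlas.brain_mask
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        noise = rng.normal(0.0, cfg.noise_sd / 100.0, size=(int(brain.sum()), T))
        frac[brain] += noise

    data = np.zeros(cfg.shape + (T,))
    data[brain] = cfg.baseline_level * (1.0 + frac[brain]) * gain
    return BoldSession(
        data=data,
        tr_seconds=cfg.tr_seconds,
        voxel_size=cfg.voxel_size,
        subject_id=subject_id,
        treatment=treatment,
    )


def _subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    atlas: Atlas,
    spec: ResponseSpec,
    cfg: SessionConfig,
    group_sizes: Mapping[str, int] = DEFAULT_GROUP_SIZES,
    seed: int = 0,
) -> list[BoldSession]:
    """Simulate one session per subject across all treatment arms.

    Subject seeds are derived deterministically from ``seed`` so the cohort
    is bit-reproducible; subject ids are ``<treatment>_<k>``.
    """
    sessions: list[BoldSession] = []
    index = 0
    for treatment, n in group_sizes.items():
        for k in range(1, n + 1):
            sub_cfg = replace(cfg, seed=_subject_seed(seed, index))
            sessions.append(
                generate_session(
                    atlas, spec, sub_cfg, treatment, subject_id=f"{treatment}_{k:02d}"
                )
            )
            index += 1
    return sessions


def write_cohort(sessions: list[BoldSession], out_dir: str | Path) -> pd.DataFrame:
    """Write sessions as 4D NIfTI files plus a cohort manifest CSV.

    Returns the manifest (``subject_id,treatment,path``) which is also
    written to ``<out_dir>/manifest.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        fname = f"{s.subject_id}.nii.gz"
        s.to_nifti(out / fname)
        rows.append({"subject_id": s.subject_id, "treatment": s.treatment, "path": fname})
    manifest = pd.DataFrame(rows, columns=["subject_id", "treatment", "path"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_cohort(manifest_path: str | Path) -> list[BoldSession]:
    """Load a cohort written by :func:`write_cohort` (paths relative to manifest)."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    sessions = []
    for row in manifest.itertuples():
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest_path.parent / path
        sessions.append(
            BoldSession.from_nifti(path, subject_id=row.subject_id, treatment=row.treatment)
        )
    return sessions
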