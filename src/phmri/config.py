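"""Pipeline configuration: the analysis constants and file locations.

The defaults aggregate the analysis constants of the emulated study design:
2% BOLD amplitude threshold, FDR level q = 0.05, drift limit 0.015 %/min,
0.8 mm smoothing FWHM, alpha = 0.05 for region tables, and a composite-map
retention frequency of 0.5.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .voxel_stats import DEFAULT_WINDOWS, WindowScheme

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    atlas_labels: str = "atlas_labels.nii.gz"
    atlas_regions: str = "atlas_regions.csv"
    atlas_networks: str = "atlas_networks.csv"
    manifest: str = "cohort/manifest.csv"
    output_dir: str = "results"
    baseline: tuple[int, int] = (1, 51)
    windows: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_WINDOWS.items()}
    )
    threshold_pct: float = 2.0
    fdr_q: float = 0.05
    drift_limit: float = 0.015
    fwhm_mm: float = 0.8
    alpha: float = 0.05
    min_frequency: float = 0.5
    control_group: str = "vehicle"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_q", "alpha", "min_frequency"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.threshold_pct < 0:
            raise ValueError("threshold_pct must be non-negative")
        if self.drift_limit <= 0:
            raise ValueError("drift_limit must be positive")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")
        self.baseline = tuple(self.baseline)  # type: ignore[assignment]
        self.windows = {str(k): tuple(v) for k, v in self.windows.items()}
        # validate the window layout eagerly
        self.scheme()

    def scheme(self) -> WindowScheme:
        return WindowScheme(baseline=self.baseline, windows=self.windows)

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline"] = list(self.baseline)
        d["windows"] = {k: list(v) for k, v in self.windows.items()}
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "baseline" in d:
            d["baseline"] = tuple(d["baseline"])
        if "windows" in d:
            d["windows"] = {k: tuple(v) for k, v in d["windows"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
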