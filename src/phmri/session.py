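"""One subject's 4D BOLD acquisition and acquisition-index conventions.

Acquisition indices are 1-based in all public interfaces, matching the
convention of numbering scanner repetitions 1..N (baseline = acquisitions
1-50 at TR 6 s).  Internally arrays are 0-based; `acq_slice` converts a
half-open 1-based acquisition range into a numpy slice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["BoldSession", "acq_slice"]


def acq_slice(start: int, stop: int) -> slice:
    """0-based slice for the half-open, 1-based acquisition range [start, stop)."""
    if not (1 <= start < stop):
        raise ValueError(f"invalid acquisition range [{start}, {stop})")
    return slice(start - 1, stop - 1)


@dataclass
class BoldSession:
    """A 4D BOLD series for one imaging session.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz, n_acquisitions)
        Signal intensity; background (extra-cerebral) voxels may be zero.
    tr_seconds : float
        Repetition time between volumes.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    subject_id, treatment : str
        Cohort bookkeeping labels.
    """

    data: np.ndarray
    tr_seconds: float
    voxel_size: tuple[float, float, float]
    subject_id: str = "subject"
    treatment: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x,y,z,t), got shape {self.data.shape}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    @property
    def n_acquisitions(self) -> int:
        return self.data.shape[3]

    def times_minutes(self) -> np.ndarray:
        """Acquisition times in minutes: t_k = (k-1) * TR / 60 for 1-based k."""
        return np.arange(self.n_acquisitions) * self.tr_seconds / 60.0

    def with_data(self, data: np.ndarray) -> "BoldSession":
        """Copy of this session carrying new voxel data, same metadata."""
        return replace(self, data=data)

    # -- NIfTI I/O -----------------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        img = nib.Nifti1Image(self.data.astype(np.float32), aff)
        img.header.set_zooms((*self.voxel_size, self.tr_seconds))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, str(path))

    @classmethod
    def from_nifti(
        cls,
        path: str | Path,
        subject_id: str = "subject",
        treatment: str = "unknown",
        tr_seconds: float | None = None,
    ) -> "BoldSession":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if tr_seconds is None and len(zooms) > 3 else tr_seconds
        if tr is None or tr <= 0:
            raise ValueError(f"repetition time missing from {path}; pass tr_seconds")
        return cls(
            data=data,
            tr_seconds=float(tr),
            voxel_size=tuple(float(z) for z in zooms[:3]),
            subject_id=subject_id,
            treatment=treatment,
        )
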