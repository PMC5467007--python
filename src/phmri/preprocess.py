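"""Session preprocessing: global linear drift correction and Gaussian smoothing.

Slow scanner drift over a ~50 min session is modelled as a single linear
trend of the whole-brain mean signal.  The slope is expressed as percent of
the fitted intercept per minute, and the correction is applied only when it
exceeds a predefined limit (default +/-0.015 %/min) — a deliberately global
strategy: fitting per-voxel trends would absorb genuine drug responses.
Removal is multiplicative (each voxel is divided by the fitted fractional
trend), which leaves percent-change quantities of superposed responses
untouched.

Both steps are exposed as scikit-learn style transformers
(:class:`DriftCorrector`, :class:`GaussianSmoother`) operating on 4D arrays,
with thin session-level functions wrapping them.  Smoothing uses a Gaussian
kernel parameterised by its full width at half maximum (FWHM) in mm, with
reflective boundary handling so the brain rim is not darkened.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas import Atlas
from .session import BoldSession

__all__ = [
    "DriftEstimate",
    "DriftCorrector",
    "GaussianSmoother",
    "global_mean_series",
    "estimate_drift",
    "correct_drift",
    "smooth_gaussian",
    "fwhm_to_sigma",
]

DEFAULT_DRIFT_LIMIT = 0.015  # % signal per minute


@dataclass(frozen=True)
class DriftEstimate:
    """Global linear drift of a session.

    slope is in percent of the fitted intercept (signal at t=0) per minute;
    intercept is in raw signal units; ``corrected`` records whether the
    slope magnitude exceeded ``limit`` and the session was (to be) corrected.
    """

    slope: float
    intercept: float
    corrected: bool
    limit: float = DEFAULT_DRIFT_LIMIT

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise ValueError("drift limit must be positive")
        if self.corrected != (abs(self.slope) > self.limit):
            raise ValueError("corrected flag inconsistent with slope and limit")


def global_mean_series(session: BoldSession, atlas: Atlas) -> np.ndarray:
    """Whole-brain mean intensity at each acquisition (in-brain voxels only)."""
    if session.grid_shape != atlas.shape:
        raise ValueError(
            f"session grid {session.grid_shape} does not match atlas grid {atlas.shape}"
        )
    mask = atlas.brain_mask
    if not mask.any():
        raise ValueError("empty brain mask: atlas contains no labelled voxels")
    return session.data[mask].mean(axis=0)


def estimate_drift(
    series: np.ndarray,
    tr_seconds: float,
    limit: float = DEFAULT_DRIFT_LIMIT,
) -> DriftEstimate:
    """Ordinary least-squares linear fit of a mean-intensity series over time.

    Time is acquisition time in minutes, t_k = (k-1)*TR/60 for 1-based k.
    The fitted slope (signal units per minute) is normalised by the fitted
    intercept to give %/min; the ``corrected`` flag is |slope| > limit.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("need a 1D series of at least 2 acquisitions")
    t = np.arange(series.size) * tr_seconds / 60.0
    if np.ptp(t) == 0:
        raise ValueError("zero-variance time axis")
    slope_sig, intercept = np.polyfit(t, series, 1)
    if intercept == 0:
        raise ValueError("fitted intercept is zero; %/min slope undefined")
    slope_pct = 100.0 * slope_sig / intercept
    return DriftEstimate(
        slope=float(slope_pct),
        intercept=float(intercept),
        corrected=bool(abs(slope_pct) > limit),
        limit=limit,
    )


class DriftCorrector(BaseEstimator, TransformerMixin):
    """Estimate and remove a session's global linear drift.

    ``fit`` computes the whole-brain mean series over ``mask`` and its
    least-squares slope in %/min; ``transform`` divides every voxel series
    by the fitted fractional trend ``1 + slope * t_min / 100`` — but only
    when the slope magnitude exceeds ``limit``, in which case the input is
    returned unchanged (bit-exactly).

    Fitted attributes: ``estimate_`` (:class:`DriftEstimate`),
    ``slope_pct_per_min_``, ``corrected_``.
    """

    def __init__(self, tr_seconds: float = 6.0, limit: float = DEFAULT_DRIFT_LIMIT):
        self.tr_seconds = tr_seconds
        self.limit = limit

    def fit(self, X: np.ndarray, y: None = None, *, mask: np.ndarray | None = None):
        X = np.asarray(X)
        if X.ndim != 4:
            raise ValueError("X must be a 4D (x,y,z,t) array")
        if mask is None:
            mask = np.ones(X.shape[:3], dtype=bool)
        if not mask.any():
            raise ValueError("empty brain mask")
        series = X[mask].mean(axis=0)
        self.estimate_ = estimate_drift(series, self.tr_seconds, self.limit)
        self.slope_pct_per_min_ = self.estimate_.slope
        self.corrected_ = self.estimate_.corrected
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "estimate_"):
            raise ValueError("DriftCorrector is not fitted")
        X = np.asarray(X)
        if not self.estimate_.corrected:
            return X
        t_min = np.arange(X.shape[3]) * self.tr_seconds / 60.0
        trend = 1.0 + self.estimate_.slope * t_min / 100.0
        return X / trend


def correct_drift(session: BoldSession, est: DriftEstimate) -> BoldSession:
    """Remove the estimated global trend; identity when ``est.corrected`` is False."""
    if not est.corrected:
        return session
    t_min = session.times_minutes()
    trend = 1.0 + est.slope * t_min / 100.0
    return session.with_data(session.data / trend)


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum (same units)."""
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class GaussianSmoother(BaseEstimator, TransformerMixin):
    """Volume-wise 3D Gaussian smoothing of a 4D series.

    The kernel width is given as FWHM in mm (default 0.8) and converted to a
    per-axis sigma in voxel units using ``voxel_size``.  Boundaries are
    reflective; ``fwhm_mm=0`` is the identity.
    """

    def __init__(self, fwhm_mm: float = 0.8, voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)):
        self.fwhm_mm = fwhm_mm
        self.voxel_size = voxel_size

    def fit(self, X: np.ndarray | None = None, y: None = None):
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self.fit()
        X = np.asarray(X)
        if X.ndim != 4:
            raise ValueError("X must be a 4D (x,y,z,t) array")
        if self.fwhm_mm == 0:
            return X
        sigma_vox = [fwhm_to_sigma(self.fwhm_mm) / v for v in self.voxel_size]
        return ndimage.gaussian_filter(X, sigma=(*sigma_vox, 0.0), mode="reflect")


def smooth_gaussian(session: BoldSession, fwhm_mm: float) -> BoldSession:
    """Smooth each acquisition volume with a 3D Gaussian kernel of given FWHM."""
    sm = GaussianSmoother(fwhm_mm=fwhm_mm, voxel_size=session.voxel_size)
    out = sm.fit().transform(session.data)
    if out is session.data:
        return session
    return session.with_data(out)
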