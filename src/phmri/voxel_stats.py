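"""Voxel-wise activation statistics for an off-on pharmacological challenge.

For every in-brain voxel, the mean signal of the pre-injection baseline
(acquisitions 1-50, i.e. the first 5 min at TR 6 s) is compared to the mean
of each post-treatment analysis window (defaults: minutes 15-25, 25-35 and
35-45, 100 acquisitions each).  The per-voxel test is Welch's two-sample
t-test (two-tailed, unequal variances, Welch-Satterthwaite degrees of
freedom).  Because ~15,000 voxels are tested per subject, raw p-values are
corrected by the Benjamini-Hochberg step-up false-discovery-rate procedure,
applied within subject across brain voxels, separately per window.  A voxel
is called *activated* only if its FDR-adjusted p is at or below q AND its
percent BOLD change clears an amplitude threshold (default 2%, accounting
for normal BOLD fluctuation in the awake rat brain); the amplitude filter is
applied to |change| so both positive and negative responses are retained,
each carrying its sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .session import BoldSession, acq_slice

__all__ = [
    "WindowScheme",
    "WindowStats",
    "VoxelStatMap",
    "ActivationMapper",
    "percent_change",
    "welch_t",
    "fdr_adjust",
    "activation_map",
]

DEFAULT_WINDOWS: Mapping[str, tuple[int, int]] = MappingProxyType(
    {"15-25": (150, 250), "25-35": (250, 350), "35-45": (350, 450)}
)


@dataclass(frozen=True)
class WindowScheme:
    """Baseline and post-treatment analysis windows as 1-based half-open ranges.

    The default baseline (1, 51) covers acquisitions 1-50; the default
    windows, named by their minute span at TR 6 s, cover 100 acquisitions
    each and are pairwise disjoint (shared printed endpoints such as
    acquisition 250 belong to the later window only).
    """

    baseline: tuple[int, int] = (1, 51)
    windows: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )

    def __post_init__(self) -> None:
        b0, b1 = self.baseline
        if not (1 <= b0 < b1):
            raise ValueError(f"empty or invalid baseline range {self.baseline}")
        ranges = sorted(self.windows.items(), key=lambda kv: kv[1])
        prev_end = b1
        for name, (w0, w1) in ranges:
            if not (1 <= w0 < w1):
                raise ValueError(f"empty or invalid window {name!r}: {(w0, w1)}")
            if w0 < b1:
                raise ValueError(f"window {name!r} does not follow the baseline")
            if w0 < prev_end:
                raise ValueError(f"window {name!r} overlaps a previous window")
            prev_end = w1
        object.__setattr__(self, "windows", dict(self.windows))

    @property
    def names(self) -> list[str]:
        return list(self.windows)

    def baseline_slice(self) -> slice:
        return acq_slice(*self.baseline)

    def window_slice(self, name: str) -> slice:
        if name not in self.windows:
            raise KeyError(f"unknown window {name!r}")
        return acq_slice(*self.windows[name])

    @property
    def max_acquisition(self) -> int:
        """Smallest series length (1-based) covering baseline and all windows."""
        return max([self.baseline[1] - 1] + [w1 - 1 for _, w1 in self.windows.values()])


# ---------------------------------------------------------------------------
# elementary statistics


def percent_change(voxel_series: np.ndarray, scheme: WindowScheme, window: str) -> float:
    """Percent BOLD change of one voxel: 100*(mean(window)-mean(baseline))/mean(baseline).

    Returns NaN when the baseline mean is zero (undefined voxel; such voxels
    are excluded from statistical maps).
    """
    series = np.asarray(voxel_series, dtype=float)
    mb = series[scheme.baseline_slice()].mean()
    mw = series[scheme.window_slice(window)].mean()
    if mb == 0:
        return float("nan")
    return float(100.0 * (mw - mb) / mb)


def _welch_from_stats(mb, vb, nb, mw, vw, nw):
    """Vectorised Welch t and two-tailed p from sample means/variances/sizes.

    Degenerate voxels (both sample variances zero) get t=0, p=1 when the
    means agree and t=+/-inf, p=0 when they differ.
    """
    mb, vb, mw, vw = (np.asarray(a, dtype=float) for a in (mb, vb, mw, vw))
    se2 = vb / nb + vw / nw
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mw - mb) / np.sqrt(se2)
        df = se2**2 / ((vb / nb) ** 2 / (nb - 1) + (vw / nw) ** 2 / (nw - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    diff = mw - mb
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return t, p


def welch_t(baseline_samples: np.ndarray, window_samples: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t-test of window vs baseline samples.

    Returns (t, two-tailed p); t is positive when the window mean exceeds
    the baseline mean.  Both degenerate all-constant cases are defined:
    equal constants give (0, 1), different constants give (+/-inf, 0).
    """
    a = np.asarray(baseline_samples, dtype=float)
    b = np.asarray(window_samples, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    t, p = _welch_from_stats(
        a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size
    )
    return float(t), float(p)


def welch_p_betainc(t: float, df: float) -> float:
    """Two-tailed Student-t tail probability via the regularised incomplete beta.

    Closed form p = I_{df/(df+t^2)}(df/2, 1/2); used as an independent check
    of the distribution path taken by :func:`welch_t`.
    """
    if not np.isfinite(t):
        return 0.0
    return float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))


def fdr_adjust(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (adjusted p-values, rejection mask at level q).  Adjusted
    p-values are monotone and >= raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# per-subject activation map


@dataclass
class WindowStats:
    """Per-voxel statistics of one baseline-vs-window comparison (3D grids)."""

    pct_change: np.ndarray
    t_stat: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    activated: np.ndarray
    sign: np.ndarray  # int8: +1 / -1 over defined voxels, 0 outside


@dataclass
class VoxelStatMap:
    """Per-subject voxel-wise statistics for every analysis window.

    ``brain_mask`` marks the voxels that entered the FDR family: labelled
    in-brain voxels with a nonzero baseline mean.  Grids hold NaN (floats)
    or 0/False outside that mask.
    """

    subject_id: str
    treatment: str
    scheme: WindowScheme
    threshold_pct: float
    q: float
    brain_mask: np.ndarray
    windows: dict[str, WindowStats]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.brain_mask.shape  # type: ignore[return-value]

    def activated_count(self, window: str, sign: int | None = None) -> int:
        w = self.windows[window]
        m = w.activated
        if sign is not None:
            m = m & (w.sign == np.sign(sign))
        return int(m.sum())

    def to_nifti(self, out_dir: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> None:
        """Write per-window pct-change / t / adjusted-p / mask volumes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
        for name, w in self.windows.items():
            tag = name.replace("-", "_")
            for field_name, grid in (
                ("pct", w.pct_change),
                ("t", w.t_stat),
                ("padj", w.p_adj),
                ("mask", w.activated.astype(np.uint8)),
            ):
                img = nib.Nifti1Image(np.asarray(grid, dtype=np.float32), aff)
                nib.save(img, str(out / f"{self.subject_id}_w{tag}_{field_name}.nii.gz"))


class ActivationMapper(BaseEstimator):
    """Compute a :class:`VoxelStatMap` from a preprocessed 4D BOLD array.

    Parameters mirror the analysis constants: the window scheme, the
    amplitude threshold in percent BOLD change (applied to |change|), and
    the FDR level q.  ``labels`` is the region grid aligned to the session;
    only labelled voxels enter the statistics.
    """

    def __init__(
        self,
        labels: np.ndarray | None = None,
        scheme: WindowScheme | None = None,
        threshold_pct: float = 2.0,
        q: float = 0.05,
    ):
        self.labels = labels
        self.scheme = scheme
        self.threshold_pct = threshold_pct
        self.q = q

    def _validated(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, WindowScheme]:
        if self.labels is None:
            raise ValueError("ActivationMapper requires a label grid")
        if self.threshold_pct < 0:
            raise ValueError("threshold_pct must be non-negative")
        scheme = self.scheme if self.scheme is not None else WindowScheme()
        X = np.asarray(X, dtype=float)
        if X.ndim != 4:
            raise ValueError("X must be a 4D (x,y,z,t) array")
        labels = np.asarray(self.labels)
        if labels.shape != X.shape[:3]:
            raise ValueError(
                f"label grid {labels.shape} does not match session grid {X.shape[:3]}"
            )
        if X.shape[3] < scheme.max_acquisition:
            raise ValueError(
                f"series has {X.shape[3]} acquisitions; scheme needs {scheme.max_acquisition}"
            )
        return X, labels, scheme

    def fit(self, X: np.ndarray, y: None = None):
        self._validated(X)
        return self

    def transform(
        self, X: np.ndarray, subject_id: str = "subject", treatment: str = "unknown"
    ) -> VoxelStatMap:
        X, labels, scheme = self._validated(X)
        base = X[..., scheme.baseline_slice()]
        mb = base.mean(axis=-1)
        vb = base.var(axis=-1, ddof=1)
        nb = base.shape[-1]
        brain = (labels > 0) & (mb != 0)

        windows: dict[str, WindowStats] = {}
        shape = X.shape[:3]
        for name in scheme.names:
            win = X[..., scheme.window_slice(name)]
            mw = win.mean(axis=-1)
            vw = win.var(axis=-1, ddof=1)
            nw = win.shape[-1]

            pct = np.full(shape, np.nan)
            t = np.full(shape, np.nan)
            p_raw = np.full(shape, np.nan)
            p_adj = np.full(shape, np.nan)
            with np.errstate(divide="ignore", invalid="ignore"):
                pct[brain] = 100.0 * (mw[brain] - mb[brain]) / mb[brain]
            t[brain], p_raw[brain] = _welch_from_stats(
                mb[brain], vb[brain], nb, mw[brain], vw[brain], nw
            )
            adj, reject = fdr_adjust(p_raw[brain], self.q)
            p_adj[brain] = adj
            activated = np.zeros(shape, dtype=bool)
            activated[brain] = reject & (np.abs(pct[brain]) >= self.threshold_pct)
            sign = np.zeros(shape, dtype=np.int8)
            sign[brain] = np.sign(pct[brain]).astype(np.int8)
            windows[name] = WindowStats(
                pct_change=pct, t_stat=t, p_raw=p_raw, p_adj=p_adj,
                activated=activated, sign=sign,
            )
        return VoxelStatMap(
            subject_id=subject_id,
            treatment=treatment,
            scheme=scheme,
            threshold_pct=self.threshold_pct,
            q=self.q,
            brain_mask=brain,
            windows=windows,
        )


def activation_map(
    session: BoldSession,
    labels: np.ndarray,
    scheme: WindowScheme | None = None,
    threshold_pct: float = 2.0,
    q: float = 0.05,
) -> VoxelStatMap:
    """Voxel-wise percent change, Welch tests, per-window FDR and activation mask."""
    mapper = ActivationMapper(
        labels=labels, scheme=scheme, threshold_pct=threshold_pct, q=q
    )
    return mapper.transform(
        session.data, subject_id=session.subject_id, treatment=session.treatment
    )
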