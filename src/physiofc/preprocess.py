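"""Shared BOLD conditioning for both correction pipelines.

Initial-volume discard, despiking, percent-signal-change normalization
(:math:`\\Delta`BOLD), combined polynomial-drift + motion nuisance removal
by orthogonal projection, and motion-outlier flagging.

Processing order follows the target protocol: discard the first 12
volumes, despike, (RETROICOR correction, when that arm runs), normalize to
percent change, then remove drift and motion in a single projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
from scipy.ndimage import median_filter
from scipy.special import eval_legendre

__all__ = [
    "BoldSeries",
    "MotionParams",
    "trim_initial",
    "despike",
    "to_percent_change",
    "legendre_design",
    "remove_nuisance",
    "flag_motion_outliers",
]


@dataclass
class BoldSeries:
    """Region x time (or voxel x time) BOLD matrix with provenance.

    ``units`` is "raw" (scanner units) or "percent_change" after
    normalization.
    """

    data: np.ndarray
    tr: float
    n_discarded: int = 0
    units: str = "raw"
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition midpoints of the retained frames, seconds from scan
        start (discarded volumes still advance the clock)."""
        return (self.n_discarded + np.arange(self.n_frames) + 0.5) * self.tr

    def with_data(self, data, step: str, **kw) -> "BoldSeries":
        out = replace(self, data=data, **kw)
        out.provenance = self.provenance + [step]
        return out


@dataclass
class MotionParams:
    """Six rigid-body motion parameters (3 translations mm, 3 rotations
    deg) per timepoint, plus optional outlier flags."""

    params: np.ndarray
    outlier_flags: Optional[np.ndarray] = None

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be timepoints x 6")

    def __len__(self):
        return self.params.shape[0]

    def trimmed(self, n: int) -> "MotionParams":
        return MotionParams(params=self.params[n:])


def trim_initial(bold: BoldSeries, n: int = 12) -> BoldSeries:
    """Discard the first ``n`` volumes (pre-equilibrium magnetization)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return bold
    if bold.n_frames <= n:
        raise ValueError(
            f"series has {bold.n_frames} frames, cannot discard {n}")
    return bold.with_data(bold.data[:, n:], f"trim_initial(n={n})",
                          n_discarded=bold.n_discarded + n)


def despike(series: np.ndarray, window: int = 11, k: float = 4.0
            ) -> np.ndarray:
    """Compress artefactual spikes toward a running-median fence.

    Samples deviating more than ``k`` MADs from a centered running median
    of width ``window`` are mapped through a smooth saturating clamp: a
    deviation d beyond the fence F becomes ``F + s * tanh((d - F)/s)``,
    bounding any spike at ``F + s`` while leaving non-spike samples
    untouched.  The MAD unit ``s`` is the normal-consistent robust scale
    (1.4826 x the median absolute deviation from the running median), so
    the default fence sits at ~4 robust standard deviations and ordinary
    signal extremes pass through.  Rows with zero dispersion pass through
    unchanged.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    n = x.shape[1]
    if window > n:
        raise ValueError("despike window longer than series")
    if n < 15:
        raise ValueError("despike needs at least 15 timepoints")
    med = median_filter(x, size=(1, window), mode="nearest")
    d = x - med
    mad = 1.4826 * np.median(np.abs(d), axis=1, keepdims=True)
    out = x.copy()
    for i in range(x.shape[0]):
        s = mad[i, 0]
        if s == 0:
            continue
        fence = k * s
        over = np.abs(d[i]) > fence
        if not over.any():
            continue
        dev = np.abs(d[i, over])
        clamped = fence + s * np.tanh((dev - fence) / s)
        out[i, over] = med[i, over] + np.sign(d[i, over]) * clamped
    return out if np.asarray(series).ndim == 2 else out[0]


def to_percent_change(series: np.ndarray) -> np.ndarray:
    """Per-row percent signal change: x -> 100 * (x - mean) / mean."""
    x = np.atleast_2d(np.asarray(series, dtype=float))
    mean = x.mean(axis=1, keepdims=True)
    bad = np.nonzero(mean.ravel() <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive mean in region(s) {bad.tolist()}; cannot "
            "normalize to percent change")
    out = 100.0 * (x - mean) / mean
    return out if np.asarray(series).ndim == 2 else out[0]


def legendre_design(n_timepoints: int, poly_order: int = 5) -> np.ndarray:
    """Legendre polynomials of orders 0..poly_order on the scan interval,
    mapped to [-1, 1].  Orthogonal basis, numerically stable at order 5."""
    t = np.linspace(-1.0, 1.0, n_timepoints)
    return np.column_stack(
        [eval_legendre(k, t) for k in range(poly_order + 1)])


def _check_rank(design: np.ndarray):
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify dependent columns via rank-revealing QR-style sweep
        dep = []
        cols = []
        for j in range(design.shape[1]):
            trial = design[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols) + 1:
                cols.append(j)
            else:
                dep.append(j)
        raise ValueError(f"rank-deficient nuisance design; dependent "
                         f"columns: {dep}")


def remove_nuisance(series: np.ndarray,
                    motion: Optional[MotionParams] = None,
                    poly_order: int = 5) -> np.ndarray:
    """Project out polynomial drift and motion in one least-squares pass.

    The design holds Legendre polynomials of orders 0..poly_order plus the
    six motion columns (when given).  The residual is orthogonal to every
    design column, and the operation is idempotent (a projector).
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    n = x.shape[1]
    design = legendre_design(n, poly_order)
    if motion is not None:
        if len(motion) != n:
            raise ValueError("motion parameters length mismatch with series")
        m = motion.params - motion.params.mean(axis=0)
        design = np.column_stack([design, m])
    _check_rank(design)
    q, _ = np.linalg.qr(design)
    resid = x - (x @ q) @ q.T
    return resid if np.asarray(series).ndim == 2 else resid[0]


def flag_motion_outliers(motion: MotionParams, threshold: float = 0.4,
                         radius_mm: float = 50.0) -> np.ndarray:
    """Flag timepoints whose motion-parameter derivative norm exceeds
    ``threshold`` (strict inequality).

    Rotations (degrees) are converted to arc length in mm on a sphere of
    ``radius_mm`` before the frame-to-frame Euclidean norm is taken — the
    standard enorm-style volume-wise criterion.  The first timepoint has no
    predecessor and is never flagged.  Flags are reported, not applied.
    """
    p = motion.params.copy()
    p[:, 3:] = np.deg2rad(p[:, 3:]) * radius_mm
    d = np.diff(p, axis=0)
    enorm = np.linalg.norm(d, axis=1)
    # strict inequality, with a float-tolerance guard at the boundary
    flags = np.concatenate([[False], enorm > threshold + 1e-9])
    motion.outlier_flags = flags
    return flags
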