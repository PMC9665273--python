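"""RETROICOR: Fourier phase-regressor correction of BOLD series.

Builds low-order Fourier expansions of the cardiac and respiratory phases
(cos/sin of m*phi for m = 1..order) at BOLD frame times, and removes their
jointly fitted contribution from each region (or voxel) time series by
ordinary least squares.  Order 2 is the default, the convention of the
standard implementations; orders 1-4 are supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .physio import PhaseSeries

__all__ = ["RetroicorDesign", "build_retroicor_regressors",
           "apply_retroicor"]


@dataclass
class RetroicorDesign:
    """Fourier phase regressors at frame times: 4 x order columns, every
    entry in [-1, 1]."""

    order: int
    columns: np.ndarray  # frames x (4*order)
    labels: List[str]
    frame_times: np.ndarray

    def __post_init__(self):
        if self.columns.shape[1] != 4 * self.order:
            raise ValueError("design must have 4 x order columns")


def build_retroicor_regressors(cardiac: PhaseSeries, resp: PhaseSeries,
                               order: int = 2) -> RetroicorDesign:
    """Assemble cos(m phi_c), sin(m phi_c), cos(m phi_r), sin(m phi_r)
    for m = 1..order, evaluated at the (shared) frame times."""
    if not 1 <= order <= 4:
        raise ValueError("order must be between 1 and 4")
    if cardiac.times.shape != resp.times.shape or \
            not np.allclose(cardiac.times, resp.times):
        raise ValueError("cardiac and respiratory phases must share "
                         "identical frame times")
    cols, labels = [], []
    for m in range(1, order + 1):
        for name, phi in (("cardiac", cardiac.phase),
                          ("respiratory", resp.phase)):
            cols.append(np.cos(m * phi))
            labels.append(f"{name}_cos{m}")
            cols.append(np.sin(m * phi))
            labels.append(f"{name}_sin{m}")
    return RetroicorDesign(order=order, columns=np.column_stack(cols),
                           labels=labels, frame_times=cardiac.times.copy())


def apply_retroicor(series: np.ndarray, design: RetroicorDesign
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Remove the fitted phase-regressor contribution from each series.

    Returns ``(residual, coefficients)`` where
    ``residual = series - coefficients @ design.columns.T`` and the
    coefficients are the joint OLS fit (region x 4*order).  The fit
    includes an implicit intercept — the phase regressors have nonzero
    temporal means, and correction runs on raw (not yet demeaned) series —
    but only the phase-regressor contribution is subtracted, so the
    series' mean level survives for the subsequent percent-change
    normalization.  The residual is orthogonal to every design column and
    to the constant.  Raises on a rank-deficient design
    (degenerate/constant phases).
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    d = design.columns
    if x.shape[1] != d.shape[0]:
        raise ValueError("series length does not match design frame count")
    aug = np.column_stack([np.ones(d.shape[0]), d])
    if np.linalg.matrix_rank(aug) < aug.shape[1]:
        raise ValueError("rank-deficient RETROICOR design (degenerate "
                         "phase series)")
    coef_aug, *_ = np.linalg.lstsq(aug, x.T, rcond=None)
    coef = coef_aug[1:].T
    resid = x - coef @ d.T
    if np.asarray(series).ndim == 1:
        return resid[0], coef[0]
    return resid, coef
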