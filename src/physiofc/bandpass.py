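"""The 15-band bandpass-filter grid and ideal DFT-domain filtering.

Band edges are exact powers of two: start frequencies 2^x for x = -7..-3
(0.008 to 0.125 Hz) and end frequencies 2^y for y = -6..-2 (0.016 to
0.25 Hz), every pair with end > start — 15 bands in total.  Filtering
retains the discrete-Fourier components whose frequency lies inside the
band (edges inclusive) and zeroes all others, including the DC term: an
ideal, linear-phase filter whose degrees-of-freedom cost is exactly the
number of removed bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

__all__ = [
    "FilterBand",
    "make_filter_grid",
    "apply_bandpass",
    "band_dof",
    "nyquist_frequency",
    "scan_duration",
    "frequency_spacing",
]

X_RANGE = range(-7, -2)  # start-frequency exponents
Y_RANGE = range(-6, -1)  # end-frequency exponents


@dataclass(frozen=True)
class FilterBand:
    """One bandpass band with exact power-of-two edges (Hz)."""

    f_lo: float
    f_hi: float

    def __post_init__(self):
        if self.f_hi <= self.f_lo:
            raise ValueError("f_hi must exceed f_lo")

    @property
    def label(self) -> str:
        """Rounded display form, e.g. '0.008–0.125 Hz' for 2^-7 to 2^-3."""
        return f"{round(self.f_lo, 3):g}–{round(self.f_hi, 3):g} Hz"


def make_filter_grid() -> List[FilterBand]:
    """All (2^x, 2^y) bands with 2^y > 2^x, ordered by (f_lo, f_hi)."""
    bands = [FilterBand(2.0 ** x, 2.0 ** y)
             for x in X_RANGE for y in Y_RANGE if y > x]
    return sorted(bands, key=lambda b: (b.f_lo, b.f_hi))


def nyquist_frequency(tr: float) -> float:
    """Maximum resolvable frequency for a repetition time ``tr`` (s)."""
    return 1.0 / (2.0 * tr)


def scan_duration(n_volumes: int, tr: float) -> float:
    """Scan duration in seconds."""
    return n_volumes * tr


def frequency_spacing(duration_s: float) -> float:
    """DFT frequency spacing (Hz) for a scan of the given duration."""
    return 1.0 / duration_s


def _band_bins(n: int, band: FilterBand, tr: float) -> np.ndarray:
    f = np.fft.rfftfreq(n, tr)
    return (f >= band.f_lo) & (f <= band.f_hi)


def apply_bandpass(series: np.ndarray, band: FilterBand, tr: float
                   ) -> np.ndarray:
    """Ideal DFT-domain bandpass along the time axis.

    Components with f_lo <= f <= f_hi are retained; everything else —
    including the zero-frequency (mean) term — is zeroed.  Linear phase:
    no time shift.  Raises if ``f_hi`` exceeds the Nyquist frequency.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    n = x.shape[1]
    if n < 16:
        raise ValueError("series too short to bandpass (need >= 16 frames)")
    if band.f_hi > nyquist_frequency(tr) + 1e-12:
        raise ValueError(
            f"band upper edge {band.f_hi} Hz exceeds Nyquist "
            f"{nyquist_frequency(tr)} Hz for tr={tr}")
    keep = _band_bins(n, band, tr)
    spec = np.fft.rfft(x, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=1)
    return out if np.asarray(series).ndim == 2 else out[0]


def band_dof(n_timepoints: int, band: FilterBand, tr: float) -> int:
    """Degrees of freedom retained by a band: 2 per retained
    positive-frequency bin, with the Nyquist bin (real-valued) counted
    once."""
    if band.f_hi > nyquist_frequency(tr) + 1e-12:
        raise ValueError("band upper edge exceeds Nyquist frequency")
    keep = _band_bins(n_timepoints, band, tr)
    keep[0] = False  # DC never counts
    dof = 2 * int(keep.sum())
    if n_timepoints % 2 == 0 and keep[-1]:
        dof -= 1  # Nyquist bin carries a single real degree of freedom
    return dof
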