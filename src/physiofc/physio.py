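"""Cardiac and respiratory signal processing.

Peak/trough detection on plethysmography and respiratory-belt traces,
construction of cardiac and respiratory phase time series at BOLD frame
times, and quality classification of recordings.

The cardiac phase :math:`\\phi_c` advances linearly from 0 to :math:`2\\pi`
over each pulse-to-pulse (R-R) interval and resets to 0 at each detected
peak.  The respiratory phase :math:`\\phi_r` is 0 at end-expiration
(troughs), rises linearly to :math:`\\pi` at end-inspiration (peaks), and
runs from :math:`-\\pi` back to 0 during expiration.  The expiratory-side
value at the peak is :math:`-\\pi` (equivalent to :math:`+\\pi` modulo
:math:`2\\pi`) so that :math:`\\cos\\phi_r` and :math:`\\sin\\phi_r` are
continuous across the breath peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import find_peaks, periodogram

__all__ = [
    "PhysioRecording",
    "EventSeries",
    "PhaseSeries",
    "PhysioError",
    "NoEventsError",
    "InsufficientEventsError",
    "SequencingError",
    "detect_extrema",
    "cardiac_phase",
    "respiratory_phase",
    "physio_quality",
    "DEFAULT_MIN_INTERVAL",
]

#: Conservative minimum event separations (s) per channel.
DEFAULT_MIN_INTERVAL = {"cardiac": 0.4, "respiratory": 1.5}


class PhysioError(ValueError):
    """Base error for physiological-signal processing."""


class NoEventsError(PhysioError):
    """Raised when no extrema can be found (missing or flatline trace)."""

    def __init__(self, msg: str, quality: str = "missing"):
        super().__init__(msg)
        self.quality = quality


class InsufficientEventsError(PhysioError):
    """Raised when fewer events than required are available."""


class SequencingError(PhysioError):
    """Raised when respiratory peaks and troughs do not interleave."""


@dataclass
class PhysioRecording:
    """A uniformly sampled cardiac or respiratory trace.

    Parameters
    ----------
    channel : {"cardiac", "respiratory"}
    rate : float
        Sampling rate in samples/s.
    t0 : float
        Time of the first sample in seconds, on the same clock as the BOLD
        frame times (scan start = 0).
    samples : ndarray
        Amplitudes in arbitrary units; empty when the channel is absent.
    present : bool
        False when the channel was never recorded.
    quality : {"clean", "noisy", "dropout", "missing"}
    true_event_times : ndarray, optional
        Ground-truth peak times when the trace came from the simulator
        (cardiac: pulse peaks; respiratory: end-inspiration peaks).
    true_trough_times : ndarray, optional
        Ground-truth trough times (respiratory only).
    """

    channel: str
    rate: float
    t0: float
    samples: np.ndarray
    present: bool = True
    quality: str = "clean"
    true_event_times: Optional[np.ndarray] = None
    true_trough_times: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.channel not in ("cardiac", "respiratory"):
            raise PhysioError(f"unknown channel {self.channel!r}")
        if self.rate <= 0:
            raise PhysioError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.present and self.samples.size:
            raise PhysioError("missing recording must carry zero samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def replace(self, **kw) -> "PhysioRecording":
        return replace(self, **kw)


@dataclass
class EventSeries:
    """Strictly increasing event times (peaks or troughs), in seconds."""

    kind: str  # {"peak", "trough"}
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise PhysioError("event times must be strictly increasing")

    def __len__(self):
        return self.times.size


@dataclass
class PhaseSeries:
    """Phase evaluated at BOLD frame times.

    Cardiac phase lies in [0, 2*pi); respiratory phase in [-pi, pi].
    """

    channel: str
    times: np.ndarray
    phase: np.ndarray
    extrapolated: np.ndarray = None  # boolean, frames outside the event span

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.times.shape != self.phase.shape:
            raise PhysioError("times and phase must align")
        if self.extrapolated is None:
            self.extrapolated = np.zeros(self.times.shape, dtype=bool)


def _prominence_floor(x: np.ndarray, frac: float = 0.25) -> float:
    q75, q25 = np.percentile(x, [75, 25])
    return frac * (q75 - q25)


def detect_extrema(
    rec: PhysioRecording,
    min_interval: Optional[float] = None,
    prominence_frac: float = 0.25,
    troughs: bool = False,
) -> EventSeries:
    """Locate local maxima (or minima) of a physiological trace.

    Uses a local-extremum scan with a minimum-separation constraint and a
    prominence floor of ``prominence_frac`` times the interquartile
    amplitude, which rejects ripple without a channel-specific model.
    Plateau ties resolve to the earliest sample.

    Raises
    ------
    NoEventsError
        If the recording is missing or flat (zero interquartile range).
    """
    if not rec.present or rec.samples.size == 0:
        raise NoEventsError(f"{rec.channel} channel missing", quality="missing")
    x = rec.samples
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr == 0 or np.ptp(x) == 0:
        raise NoEventsError(f"{rec.channel} trace is flat", quality="dropout")
    if min_interval is None:
        min_interval = DEFAULT_MIN_INTERVAL[rec.channel]
    distance = max(1, int(round(min_interval * rec.rate)))
    prom = prominence_frac * iqr
    sig = -x if troughs else x
    idx, _ = find_peaks(sig, distance=distance, prominence=prom)
    if idx.size == 0:
        raise NoEventsError(f"no {'troughs' if troughs else 'peaks'} found",
                            quality=rec.quality)
    return EventSeries(kind="trough" if troughs else "peak",
                       times=rec.t0 + idx / rec.rate)


def _interp_with_extrapolation(node_t, node_u, t):
    """Piecewise-linear interpolation, extending the first/last segment's
    slope beyond the node span."""
    u = np.interp(t, node_t, node_u)
    lo = t < node_t[0]
    hi = t > node_t[-1]
    if lo.any():
        slope = (node_u[1] - node_u[0]) / (node_t[1] - node_t[0])
        u[lo] = node_u[0] + slope * (t[lo] - node_t[0])
    if hi.any():
        slope = (node_u[-1] - node_u[-2]) / (node_t[-1] - node_t[-2])
        u[hi] = node_u[-1] + slope * (t[hi] - node_t[-1])
    return u, lo | hi


def cardiac_phase(peaks: EventSeries, frame_times) -> PhaseSeries:
    """Cardiac phase at the given frame times.

    phi_c(t) = 2*pi * (t - t_k) / (t_{k+1} - t_k) for t in [t_k, t_{k+1});
    frames before the first or after the last peak extrapolate the nearest
    interval's duration.
    """
    if len(peaks) < 2:
        raise InsufficientEventsError("cardiac phase needs >= 2 peaks")
    t = np.asarray(frame_times, dtype=float)
    # Unwrapped phase: 2*pi*k at peak k, linear in between.
    node_u = 2 * np.pi * np.arange(len(peaks))
    u, extrap = _interp_with_extrapolation(peaks.times, node_u, t)
    phase = np.mod(u, 2 * np.pi)
    return PhaseSeries("cardiac", t, phase, extrap)


def respiratory_phase(peaks: EventSeries, troughs: EventSeries,
                      frame_times) -> PhaseSeries:
    """Respiratory phase at the given frame times.

    Troughs (end-expiration) map to 0, peaks (end-inspiration) to pi;
    inspiration spans (0, pi], expiration [-pi, 0).  Implemented through an
    unwrapped phase that gains 2*pi per full breath, then wrapped to
    (-pi, pi], which makes the Fourier regressors cos/sin(m*phi_r)
    continuous across the breath peak.
    """
    if len(peaks) < 1 or len(troughs) < 1:
        raise InsufficientEventsError("need at least one peak and one trough")
    events = np.concatenate([peaks.times, troughs.times])
    kinds = np.concatenate([np.ones(len(peaks)), np.zeros(len(troughs))])
    order = np.argsort(events)
    events, kinds = events[order], kinds[order]
    if np.any(np.diff(kinds) == 0):
        raise SequencingError("respiratory peaks and troughs must interleave")
    if events.size < 2:
        raise InsufficientEventsError("need >= 2 interleaved events")
    # Unwrapped nodes: the phase gains pi per alternating event, with
    # troughs at even multiples of pi and peaks at odd multiples.
    start = 0.0 if kinds[0] == 0 else np.pi
    node_u = start + np.pi * np.arange(events.size)
    t = np.asarray(frame_times, dtype=float)
    u, extrap = _interp_with_extrapolation(events, node_u, t)
    # Wrap to (-pi, pi]: inspiration (trough->peak) lands in (0, pi],
    # expiration (peak->trough) in (-pi, 0).
    phase = np.mod(u + np.pi, 2 * np.pi) - np.pi
    phase[np.isclose(phase, -np.pi)] = -np.pi  # keep the peak at -pi exactly
    return PhaseSeries("respiratory", t, phase, extrap)


def _flatline_fraction(x: np.ndarray, rate: float,
                       min_run_s: float = 1.0) -> float:
    """Fraction of the trace lying in exact flatline runs of at least
    ``min_run_s`` seconds."""
    if x.size < 2:
        return 0.0
    flat = np.diff(x) == 0.0
    # run-length encode
    total = 0
    run = 0
    min_run = max(2, int(round(min_run_s * rate)))
    for f in np.append(flat, False):
        if f:
            run += 1
        else:
            if run + 1 >= min_run:
                total += run + 1
            run = 0
    return total / x.size


def physio_quality(
    rec: PhysioRecording,
    dropout_frac: float = 0.10,
    interval_cv_thresh: float = 0.35,
    hf_power_thresh: float = 0.15,
    amp_cv_thresh: float = 0.40,
) -> str:
    """Classify a recording as clean, noisy, dropout, or missing.

    Rules, in order of precedence:

    missing
        Channel absent (no samples).
    dropout
        Exact flatline runs cover more than ``dropout_frac`` of the trace.
    noisy
        Any of: cycle-interval coefficient of variation above
        ``interval_cv_thresh``; high-frequency residual power fraction
        (above 5x the channel's nominal rate ceiling) above
        ``hf_power_thresh``; peak-amplitude coefficient of variation above
        ``amp_cv_thresh`` (catches position/amplitude-modulation noise); or
        peak detection failure on a non-flat trace.
    clean
        Otherwise.
    """
    if not rec.present or rec.samples.size == 0:
        return "missing"
    x = rec.samples
    if np.ptp(x) == 0:
        return "dropout"
    if _flatline_fraction(x, rec.rate) > dropout_frac:
        return "dropout"
    # High-frequency residual power: fraction of (detrended) power above a
    # cutoff no physiological cycle of this channel can reach.
    cutoff = 5.0 if rec.channel == "cardiac" else 1.5
    f, p = periodogram(x - x.mean(), fs=rec.rate)
    ptot = p.sum()
    if ptot > 0 and p[f > cutoff].sum() / ptot > hf_power_thresh:
        return "noisy"
    try:
        peaks = detect_extrema(rec)
    except NoEventsError:
        return "noisy"
    if len(peaks) >= 3:
        iv = np.diff(peaks.times)
        if iv.std() / iv.mean() > interval_cv_thresh:
            return "noisy"
        # amplitude modulation check on peak heights
        idx = np.clip(np.round((peaks.times - rec.t0) * rec.rate).astype(int),
                      0, x.size - 1)
        amps = x[idx] - np.median(x)
        scale = np.abs(np.median(amps))
        if scale > 0 and amps.std() / scale > amp_cv_thresh:
            return "noisy"
    return "clean"
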