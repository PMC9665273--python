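"""Synthetic ICU resting-state data generator.

Emulates the study conditions this package targets: 10-minute BOLD runs at
TR = 1.25 s (482 volumes, first 12 pre-equilibrium), concurrent optical
plethysmography (~1 Hz) and respiratory-belt (~0.3 Hz) traces, phase-locked
cardiorespiratory contamination of the BOLD signal, slow scanner drift,
motion spikes, and the physiological-recording failure modes seen in
critically ill patients (absent channel, intermittent signal loss,
motion/position noise).

Every generated subject carries its full ground truth (neural series, true
correlation structure, true phases, contamination), so each downstream
correction stage can be validated term by term: the observed percent-signal
matrix is exactly the sum of the stored components.

Design notes
------------
* The neural component is band-limited to [0.008, 0.125] Hz by DFT-bin
  shaping and coloured so that its *empirical* inter-regional correlation
  equals ``target_corr`` exactly (whiten-then-colour); this removes neural
  sampling noise from ground-truth comparisons without changing the
  expectation contract.
* Neural and drift components are orthogonalized in-sample against the
  contamination Fourier design, so regression on the true phases recovers
  the contamination exactly and variance attribution is unambiguous.
* Thermal noise defaults to 0.05 percent-signal units: spatially incoherent
  noise shrinks roughly with the square root of the voxel count under
  region averaging, while the spatially coherent neural (1 %) and
  physiological (0.5 %) components do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import eval_legendre

from .physio import (EventSeries, PhysioRecording, cardiac_phase,
                     respiratory_phase)
from .preprocess import BoldSeries, MotionParams

__all__ = [
    "SimParams",
    "GroundTruth",
    "SubjectBundle",
    "default_target_corr",
    "generate_physio",
    "generate_subject",
    "corrupt_physio",
    "generate_cohort",
]

NEURAL_BAND = (0.008, 0.125)  # Hz, where resting-state signal lives


def _nearest_correlation(c: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal."""
    w, v = np.linalg.eigh(c)
    if w.min() >= floor:
        return c
    w = np.clip(w, floor, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def default_target_corr(n_regions: int = 83) -> np.ndarray:
    """Structured ground-truth correlation matrix.

    Baseline 0.1 everywhere, +0.35 within a lobe-like block, +0.25 between
    homotopic partners (region i paired with i + n/2), loosely mimicking
    the block-plus-homotopy organisation of real connectomes.  Projected to
    the nearest positive-semidefinite correlation matrix.
    """
    c = np.full((n_regions, n_regions), 0.10)
    # eight contiguous lobe-like blocks
    edges = np.linspace(0, n_regions, 9).astype(int)
    for a, b in zip(edges[:-1], edges[1:]):
        c[a:b, a:b] += 0.35
    half = n_regions // 2
    for i in range(half):
        j = i + half
        c[i, j] += 0.25
        c[j, i] += 0.25
    np.fill_diagonal(c, 1.0)
    return _nearest_correlation(c)


@dataclass
class SimParams:
    """Parameters of the synthetic acquisition.

    Defaults mirror the target acquisition: 83 parcellation nodes,
    482 volumes at TR 1.25 s (12 discarded), physio sampled at 50 samples/s,
    cardiac 1.0 +/- 0.05 Hz, respiratory 0.3 +/- 0.03 Hz.  Amplitudes are in
    percent-signal units.
    """

    n_regions: int = 83
    n_volumes: int = 482
    n_discard: int = 12
    tr: float = 1.25
    physio_rate: float = 50.0
    cardiac_rate_mean: float = 1.0
    cardiac_rate_sd: float = 0.05
    resp_rate_mean: float = 0.3
    resp_rate_sd: float = 0.03
    target_corr: Optional[np.ndarray] = None
    neural_sd: float = 1.0
    contamination_amp: float = 0.5
    contamination_order: int = 2
    drift_coeffs: Optional[np.ndarray] = None  # Legendre orders 0..5
    drift_sd: float = 0.3
    spike_rate: float = 1.0  # spikes per 100 timepoints
    spike_amp: float = 4.0
    noise_sd: float = 0.05
    baseline: float = 1000.0
    physio_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.target_corr is None:
            self.target_corr = default_target_corr(self.n_regions)
        self.target_corr = np.asarray(self.target_corr, dtype=float)
        self.validate()

    def validate(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_discard >= self.n_volumes:
            raise ValueError("n_discard must be smaller than n_volumes")
        if self.physio_rate <= 2 * self.cardiac_rate_mean:
            raise ValueError(
                "physio_rate must exceed twice the mean cardiac rate")
        dur = self.n_volumes * self.tr
        if dur < 2 / self.cardiac_rate_mean or dur < 2 / self.resp_rate_mean:
            raise ValueError("scan shorter than two physiological cycles")
        c = self.target_corr
        if c.shape != (self.n_regions, self.n_regions):
            raise ValueError("target_corr shape must match n_regions")
        if not np.allclose(c, c.T):
            raise ValueError("target_corr must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("target_corr must have unit diagonal")
        w = np.linalg.eigvalsh(c)
        if w.min() < -1e-8:
            raise ValueError("target_corr must be positive semi-definite")

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    @property
    def frame_times(self) -> np.ndarray:
        """Per-volume midpoint acquisition times (s from scan start)."""
        return (np.arange(self.n_volumes) + 0.5) * self.tr

    @property
    def retained_frame_times(self) -> np.ndarray:
        return self.frame_times[self.n_discard:]


@dataclass
class GroundTruth:
    """Exact decomposition of a simulated subject's percent-signal data.

    All series live on the retained (post-discard) frame grid and satisfy
    observed_percent = neural + contamination + drift + spikes + noise
    term by term.
    """

    neural_series: np.ndarray
    true_corr: np.ndarray
    cardiac_phase_true: np.ndarray
    resp_phase_true: np.ndarray
    contamination_series: np.ndarray
    drift_series: np.ndarray
    spike_series: np.ndarray
    noise_series: np.ndarray
    baseline: float
    frame_times: np.ndarray

    @property
    def observed_percent(self) -> np.ndarray:
        return (self.neural_series + self.contamination_series +
                self.drift_series + self.spike_series + self.noise_series)

    def percent_of(self, bold: BoldSeries) -> np.ndarray:
        """Exact percent-signal representation of raw observed data on the
        retained frame grid (uses the known baseline, not the sample mean)."""
        data = bold.data
        if data.shape[1] > self.frame_times.size:
            data = data[:, data.shape[1] - self.frame_times.size:]
        return 100.0 * (data / self.baseline - 1.0)


@dataclass
class SubjectBundle:
    """Everything generated for one synthetic subject."""

    subject_id: str
    params: SimParams
    bold: BoldSeries
    truth: GroundTruth
    cardiac: PhysioRecording
    respiratory: PhysioRecording
    motion: MotionParams
    group: str = "patient"


def _draw_cycles(rng, rate_mean, rate_sd, t_start, t_stop):
    """Cycle onset times covering [t_start, t_stop], with per-cycle rates
    drawn around rate_mean."""
    onsets = [t_start]
    intervals = []
    t = t_start
    lo = rate_mean / 3.0
    while t < t_stop:
        r = rng.normal(rate_mean, rate_sd)
        r = max(r, lo)
        iv = 1.0 / r
        intervals.append(iv)
        t += iv
        onsets.append(t)
    return np.array(onsets), np.array(intervals)


_CARDIAC_UPSTROKE = 0.15  # fraction of the cycle spent on the systolic rise


def _cardiac_waveform(theta: np.ndarray) -> np.ndarray:
    """Asymmetric pulse: fast raised-cosine upstroke over the first 15 % of
    the cycle, exponential decay afterwards (plethysmograph-like)."""
    y = np.empty_like(theta)
    up = theta < _CARDIAC_UPSTROKE
    y[up] = 0.5 * (1 - np.cos(np.pi * theta[up] / _CARDIAC_UPSTROKE))
    y[~up] = np.exp(-(theta[~up] - _CARDIAC_UPSTROKE) / 0.25)
    return y


def generate_physio(
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[PhysioRecording, PhysioRecording]:
    """Simulate cardiac (plethysmography) and respiratory (belt) traces.

    Both traces span the scan plus one cycle of padding on each side.  The
    cardiac waveform peaks once per cycle (at 15 % of the cycle); the
    respiratory waveform is a raised cosine per breath, with troughs at
    cycle onsets (end-expiration) and peaks mid-cycle (end-inspiration).
    Ground-truth event times are stored on the recordings.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dur = params.duration
    recs = []
    for channel, rate_mean, rate_sd in (
            ("cardiac", params.cardiac_rate_mean, params.cardiac_rate_sd),
            ("respiratory", params.resp_rate_mean, params.resp_rate_sd)):
        pad = 1.0 / rate_mean
        onsets, intervals = _draw_cycles(rng, rate_mean, rate_sd,
                                         -pad, dur + pad)
        t0 = onsets[0]
        n = int(np.ceil((onsets[-1] - t0) * params.physio_rate))
        t = t0 + np.arange(n) / params.physio_rate
        k = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0,
                    intervals.size - 1)
        theta = (t - onsets[k]) / intervals[k]
        theta = np.clip(theta, 0.0, 1.0 - 1e-12)
        if channel == "cardiac":
            x = _cardiac_waveform(theta)
            true_peaks = onsets[:-1] + _CARDIAC_UPSTROKE * intervals
            true_troughs = None
        else:
            x = 0.5 * (1 - np.cos(2 * np.pi * theta))
            true_peaks = onsets[:-1] + 0.5 * intervals
            true_troughs = onsets[:-1]
        if params.physio_noise_sd > 0:
            x = x + rng.normal(0, params.physio_noise_sd, x.size)
        recs.append(PhysioRecording(
            channel=channel, rate=params.physio_rate, t0=t0, samples=x,
            true_event_times=true_peaks, true_trough_times=true_troughs,
            meta={"rate_mean_hz": rate_mean, "rate_sd_hz": rate_sd}))
    return recs[0], recs[1]


def _bandlimited_white(rng, n_regions, n_frames, tr, band=NEURAL_BAND):
    """White Gaussian rows restricted to the DFT bins inside ``band``."""
    x = rng.standard_normal((n_regions, n_frames))
    f = np.fft.rfftfreq(n_frames, tr)
    keep = (f >= band[0]) & (f <= band[1])
    spec = np.fft.rfft(x, axis=1)
    spec[:, ~keep] = 0.0
    return np.fft.irfft(spec, n=n_frames, axis=1)


def _orthogonalize(x: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Remove the in-sample projection of each row of x onto span(design)."""
    q, _ = np.linalg.qr(design)
    return x - (x @ q) @ q.T


def _retroicor_columns(phi_c, phi_r, order):
    cols = []
    for m in range(1, order + 1):
        cols += [np.cos(m * phi_c), np.sin(m * phi_c),
                 np.cos(m * phi_r), np.sin(m * phi_r)]
    return np.column_stack(cols)


def generate_subject(
    params: SimParams,
    subject_id: str = "S1",
    group: str = "patient",
) -> SubjectBundle:
    """Simulate one subject: observed BOLD, ground truth, physio, motion.

    The observed raw data are ``baseline * (1 + total/100)`` on the
    retained frames, where ``total`` is the stored percent-signal
    decomposition; the ``n_discard`` leading volumes are pre-equilibrium
    junk (elevated, decaying baseline) that any faithful pipeline discards.
    Cardiac power appears at the aliased frequency |f_c - k/tr| because the
    contamination is sampled at frame times.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    r_physio, r_neural, r_amp, r_drift, r_spike, r_noise, r_motion = (
        np.random.default_rng(s) for s in ss.spawn(7))

    cardiac, resp = generate_physio(params, r_physio)
    ft = params.retained_frame_times
    n = ft.size
    R = params.n_regions

    phi_c = cardiac_phase(EventSeries("peak", cardiac.true_event_times),
                          ft).phase
    phi_r = respiratory_phase(
        EventSeries("peak", resp.true_event_times),
        EventSeries("trough", resp.true_trough_times), ft).phase

    m_ord = params.contamination_order
    design = _retroicor_columns(phi_c, phi_r, m_ord)
    # components are orthogonalized against the design plus the constant,
    # matching the implicit intercept of the correction fit
    design_aug = np.column_stack([np.ones(n), design])

    # Neural: band-limited, orthogonal to the contamination design, with
    # empirical correlation matched exactly to target_corr.
    x = _bandlimited_white(r_neural, R, n, params.tr)
    if params.contamination_amp != 0:
        x = _orthogonalize(x, design_aug)
    if n > R + design.shape[1]:
        s = (x @ x.T) / n
        w, v = np.linalg.eigh(s)
        whiten = (v / np.sqrt(w)) @ v.T
        lchol = np.linalg.cholesky(params.target_corr +
                                   1e-10 * np.eye(R))
        neural = (lchol @ whiten @ x) * params.neural_sd
    else:
        warnings.warn("series too short for exact correlation matching; "
                      "using approximate colouring")
        x /= x.std(axis=1, keepdims=True)
        neural = (np.linalg.cholesky(params.target_corr + 1e-10 * np.eye(R))
                  @ x) * params.neural_sd

    # Contamination: per-region Fourier amplitudes scaled so the per-region
    # contamination sd is ~contamination_amp.
    ncol = design.shape[1]
    amps = r_amp.normal(0.0, 1.0, (R, ncol))
    if params.contamination_amp != 0:
        amps *= params.contamination_amp / np.sqrt(ncol / 2.0)
        contamination = amps @ design.T
    else:
        amps[:] = 0.0
        contamination = np.zeros((R, n))

    # Drift: Legendre polynomials (orders 1..5) over the retained interval.
    tnorm = 2 * (ft - ft[0]) / (ft[-1] - ft[0]) - 1
    basis = np.column_stack([eval_legendre(k, tnorm) for k in range(6)])
    if params.drift_coeffs is not None:
        coeffs = np.tile(np.asarray(params.drift_coeffs, float), (R, 1))
    else:
        coeffs = r_drift.normal(0.0, params.drift_sd, (R, 6))
        coeffs[:, 0] = 0.0  # constant absorbed by the baseline
    ncoef = min(coeffs.shape[1], 6)
    drift = coeffs[:, :ncoef] @ basis[:, :ncoef].T
    if params.contamination_amp != 0 and drift.any():
        drift = _orthogonalize(drift, design_aug)

    # Motion spikes: global events hitting every region, plus matching
    # jumps in the motion parameters.
    spikes = np.zeros((R, n))
    n_spikes = r_spike.poisson(params.spike_rate * n / 100.0)
    spike_idx = np.sort(r_spike.choice(n, size=min(n_spikes, n),
                                       replace=False)) if n_spikes else \
        np.array([], dtype=int)
    for i in spike_idx:
        spikes[:, i] += r_spike.normal(0, params.spike_amp, R)

    noise = r_noise.normal(0.0, params.noise_sd, (R, n)) \
        if params.noise_sd > 0 else np.zeros((R, n))

    total = neural + contamination + drift + spikes + noise
    observed_ret = params.baseline * (1.0 + total / 100.0)

    # Pre-equilibrium volumes: elevated baseline decaying toward steady
    # state (discarded by the pipeline).
    nd = params.n_discard
    decay = 1.0 + 0.25 * np.exp(-np.arange(nd) / 4.0)
    junk = params.baseline * decay[None, :] * np.ones((R, 1))
    observed = np.concatenate([junk, observed_ret], axis=1)

    bold = BoldSeries(data=observed, tr=params.tr, units="raw",
                      provenance=["simulated"])

    # Motion parameters: slow sinusoidal wander + steps at spike frames.
    tful = params.frame_times
    motion = np.zeros((params.n_volumes, 6))
    # smooth settling drift lives below the 0.005 Hz detrend band;
    # fast motion enters as the step jumps below
    for j in range(6):
        f0 = r_motion.uniform(0.001, 0.004)
        motion[:, j] = 0.2 * np.sin(2 * np.pi * f0 * tful +
                                    r_motion.uniform(0, 2 * np.pi))
    for i in spike_idx:
        j = r_motion.integers(0, 6)
        motion[nd + i:, j] += r_motion.uniform(0.5, 1.5) * \
            r_motion.choice([-1, 1])
    mot = MotionParams(params=motion)

    truth = GroundTruth(
        neural_series=neural, true_corr=params.target_corr.copy(),
        cardiac_phase_true=phi_c, resp_phase_true=phi_r,
        contamination_series=contamination, drift_series=drift,
        spike_series=spikes, noise_series=noise,
        baseline=params.baseline, frame_times=ft)
    return SubjectBundle(subject_id=subject_id, params=params, bold=bold,
                         truth=truth, cardiac=cardiac, respiratory=resp,
                         motion=mot, group=group)


def corrupt_physio(
    rec: PhysioRecording,
    mode: str,
    rng: Optional[np.random.Generator] = None,
    fraction: float = 0.3,
    n_segments: int = 3,
    snr: float = 0.5,
    depth: float = 0.8,
    mod_freq: float = 0.02,
) -> PhysioRecording:
    """Apply one of the catalogued failure modes to a recording.

    Modes
    -----
    absent
        Channel never recorded: empty trace, ``present=False``.
    dropout
        Intermittent signal loss: ``n_segments`` contiguous flatline
        segments totalling ``fraction`` of the trace.
    motion_noise
        Additive broadband noise at the given signal-to-noise ratio.
    position_noise
        Slow amplitude modulation (depth ``depth`` at ``mod_freq`` Hz),
        as from a badly positioned sensor.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if mode == "absent":
        return PhysioRecording(channel=rec.channel, rate=rec.rate, t0=rec.t0,
                               samples=np.array([]), present=False,
                               quality="missing")
    x = rec.samples.copy()
    if mode == "dropout":
        # non-overlapping flatline segments: one per equal-length chunk
        chunk = x.size // n_segments
        seg_len = max(1, int(round(fraction * chunk)))
        for c in range(n_segments):
            off = int(rng.integers(0, max(1, chunk - seg_len)))
            s = c * chunk + off
            x[s:s + seg_len] = x[s]
        return rec.replace(samples=x, quality="dropout")
    if mode == "motion_noise":
        sig_power = np.var(x)
        noise = rng.normal(0, np.sqrt(sig_power / snr), x.size)
        return rec.replace(samples=x + noise, quality="noisy")
    if mode == "position_noise":
        t = rec.times
        env = 1.0 - depth * (0.5 + 0.5 * np.sin(
            2 * np.pi * mod_freq * t + rng.uniform(0, 2 * np.pi)))
        med = np.median(x)
        return rec.replace(samples=med + (x - med) * env, quality="noisy")
    raise ValueError(f"unknown corruption mode {mode!r}")


DEFAULT_FAILURE_PROBS: Dict[str, float] = {
    "unusable_fmri": 0.0,
    "absent": 0.0,
    "dropout": 0.0,
    "motion_noise": 0.0,
    "position_noise": 0.0,
}


def generate_cohort(
    n_patients: int,
    n_controls: int,
    failure_probs: Optional[Dict[str, float]] = None,
    seed: int = 0,
    params: Optional[SimParams] = None,
    generate_data: bool = True,
) -> Tuple[List["SubjectStatus"], List[Optional[SubjectBundle]]]:
    """Simulate a cohort with independent per-subject failure draws.

    Each subject gets a usable-fMRI flag (probability
    ``failure_probs['unusable_fmri']`` of failure) and, per channel, one
    failure mode drawn from {none, absent, dropout, motion_noise,
    position_noise}.  Data bundles carry traces only for channels present;
    with ``generate_data=False`` only the status table is produced (cheap
    for large cohorts).
    """
    from .compare import SubjectStatus  # local import to avoid a cycle

    probs = dict(DEFAULT_FAILURE_PROBS)
    if failure_probs:
        unknown = set(failure_probs) - set(probs)
        if unknown:
            raise ValueError(f"unknown failure probabilities: {unknown}")
        probs.update(failure_probs)
    for k, v in probs.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability {k} outside [0, 1]")
    modes = ["absent", "dropout", "motion_noise", "position_noise"]
    p_modes = np.array([probs[m] for m in modes])
    if p_modes.sum() > 1.0:
        raise ValueError("channel failure probabilities sum to more than 1")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    base = params if params is not None else SimParams()

    statuses: List[SubjectStatus] = []
    bundles: List[Optional[SubjectBundle]] = []
    specs = [("P", "patient")] * n_patients + [("C", "control")] * n_controls
    quality_of = {"dropout": "dropout", "motion_noise": "noisy",
                  "position_noise": "noisy", None: "clean"}
    for i, (prefix, grp) in enumerate(specs):
        sid = f"{prefix}{i + 1}" if grp == "patient" else \
            f"{prefix}{i + 1 - n_patients}"
        usable = rng.random() >= probs["unusable_fmri"]
        ch_mode = {}
        for ch in ("cardiac", "respiratory"):
            u = rng.random()
            edges = np.cumsum(p_modes)
            k = int(np.searchsorted(edges, u))
            ch_mode[ch] = modes[k] if k < len(modes) else None
        card_mode, resp_mode = ch_mode["cardiac"], ch_mode["respiratory"]
        status = SubjectStatus(
            id=sid, group=grp, usable_fmri=usable,
            cardiac_present=card_mode != "absent",
            resp_present=resp_mode != "absent",
            cardiac_quality=(None if card_mode == "absent"
                             else quality_of[card_mode]),
            resp_quality=(None if resp_mode == "absent"
                          else quality_of[resp_mode]),
            exclusion_reason=None)
        statuses.append(status)
        if not generate_data:
            bundles.append(None)
            continue
        sub_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31))
        p = SimParams(**{**base.__dict__, "seed": sub_seed,
                         "target_corr": base.target_corr})
        bundle = generate_subject(p, subject_id=sid, group=grp)
        crng = np.random.default_rng(sub_seed + 1)
        if card_mode:
            bundle.cardiac = corrupt_physio(bundle.cardiac, card_mode,
                                            rng=crng)
        if resp_mode:
            bundle.respiratory = corrupt_physio(bundle.respiratory,
                                                resp_mode, rng=crng)
        bundles.append(bundle)
    ids = [s.id for s in statuses]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids generated")
    return statuses, bundles
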