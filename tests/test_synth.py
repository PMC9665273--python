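"""Synthetic-data generator: decomposition, spectra, determinism."""

import numpy as np
import pytest
from scipy.signal import periodogram

from physiofc import (SimParams, corrupt_physio, default_target_corr,
                      generate_cohort, generate_physio, generate_subject,
                      physio_quality)


class TestGeneratePhysio:
    def test_cardiac_peak_count_tracks_rate(self):
        """~1 peak per second over a 602.5 s scan (within 10%)."""
        cardiac, _ = generate_physio(SimParams(seed=1))
        from physiofc import detect_extrema
        n = len(detect_extrema(cardiac))
        assert abs(n - 602.5) / 602.5 < 0.10

    def test_zero_rate_sd_gives_equal_intervals(self):
        p = SimParams(seed=1, cardiac_rate_sd=0.0)
        cardiac, _ = generate_physio(p)
        iv = np.diff(cardiac.true_event_times)
        assert np.allclose(iv, 1.0, atol=1.0 / p.physio_rate)

    def test_same_seed_bitwise_identical(self):
        a, _ = generate_physio(SimParams(seed=9))
        b, _ = generate_physio(SimParams(seed=9))
        assert np.array_equal(a.samples, b.samples)

    def test_traces_cover_scan_plus_padding(self):
        p = SimParams(seed=2)
        cardiac, resp = generate_physio(p)
        for rec in (cardiac, resp):
            assert rec.t0 <= 0.0
            assert rec.t0 + rec.duration >= p.duration

    def test_too_short_scan_rejected(self):
        with pytest.raises(ValueError):
            SimParams(n_volumes=3, n_discard=1, tr=0.5,
                      resp_rate_mean=0.3)


class TestGenerateSubject:
    def test_decomposition_conservation(self, default_subject):
        """Observed percent signal equals the sum of stored components."""
        gt = default_subject.truth
        obs = gt.percent_of(default_subject.bold)
        assert np.abs(obs - gt.observed_percent).max() < 1e-10

    def test_corruption_off_observed_equals_neural(self):
        p = SimParams(seed=4, contamination_amp=0.0, noise_sd=0.0,
                      spike_rate=0.0, drift_coeffs=np.zeros(6))
        b = generate_subject(p)
        obs = b.truth.percent_of(b.bold)
        assert np.allclose(obs, b.truth.neural_series, atol=1e-10)

    def test_cardiac_contamination_aliases_to_0p2_hz(self):
        """1 Hz cardiac sampled at 0.8 Hz folds to |1.0 - 0.8| = 0.2 Hz."""
        p = SimParams(seed=5, cardiac_rate_sd=0.0, resp_rate_sd=0.0)
        b = generate_subject(p)
        f, pxx = periodogram(np.cos(b.truth.cardiac_phase_true), fs=1 / 1.25)
        assert abs(f[np.argmax(pxx)] - 0.2) < 2.0 / (470 * 1.25)

    def test_contamination_power_sits_above_neural_band(self):
        """With default rates, <10% of contamination power lies below
        0.15 Hz after aliasing."""
        b = generate_subject(SimParams(seed=5))
        f, pxx = periodogram(b.truth.contamination_series, fs=1 / 1.25,
                             axis=1)
        frac = pxx[:, f < 0.15].sum() / pxx.sum()
        assert frac < 0.10

    def test_neural_empirical_correlation_matches_target(self):
        """10 regions, 2000 frames: empirical correlation of the neural
        series within 0.05 (max abs entry) of target."""
        p = SimParams(seed=1, n_regions=10, n_volumes=2000,
                      target_corr=default_target_corr(10))
        b = generate_subject(p)
        emp = np.corrcoef(b.truth.neural_series)
        assert np.abs(emp - p.target_corr).max() < 0.05

    def test_non_psd_target_rejected(self):
        c = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            SimParams(n_regions=2, target_corr=c)

    def test_seed_determinism(self):
        a = generate_subject(SimParams(seed=7))
        b = generate_subject(SimParams(seed=7))
        assert np.array_equal(a.bold.data, b.bold.data)
        assert np.array_equal(a.motion.params, b.motion.params)

    def test_neural_band_limitation(self):
        """Without contamination (hence no orthogonalization against the
        phase regressors), neural power is confined to [0.008, 0.125] Hz
        on the retained frame grid."""
        nu = generate_subject(SimParams(
            seed=3, contamination_amp=0.0)).truth.neural_series
        f, pxx = periodogram(nu, fs=1 / 1.25, axis=1)
        out = pxx[:, (f < 0.008 - 1e-9) | (f > 0.125 + 1e-9)].sum()
        assert out / pxx.sum() < 1e-3


class TestCorruptPhysio:
    def test_absent_empty_and_flagged(self):
        cardiac, _ = generate_physio(SimParams(seed=2))
        bad = corrupt_physio(cardiac, "absent")
        assert not bad.present and bad.samples.size == 0

    def test_dropout_fraction_by_construction(self):
        cardiac, _ = generate_physio(SimParams(seed=2))
        bad = corrupt_physio(cardiac, "dropout",
                             rng=np.random.default_rng(1), fraction=0.3)
        flat = np.diff(bad.samples) == 0.0
        assert flat.mean() >= 0.28

    def test_motion_noise_classified_noisy(self):
        cardiac, _ = generate_physio(SimParams(seed=2))
        bad = corrupt_physio(cardiac, "motion_noise",
                             rng=np.random.default_rng(1), snr=0.5)
        assert physio_quality(bad) == "noisy"

    def test_unknown_mode_raises(self):
        cardiac, _ = generate_physio(SimParams(seed=2))
        with pytest.raises(ValueError):
            corrupt_physio(cardiac, "gremlins")


class TestGenerateCohort:
    def test_no_failures_everyone_complete(self):
        statuses, _ = generate_cohort(5, 3, seed=1, generate_data=False)
        assert all(s.usable_fmri and s.cardiac_present and s.resp_present
                   for s in statuses)

    def test_absent_fraction_within_three_se(self):
        """P(absent)=0.1 over 1000 subjects: observed fraction within
        3 SE of 0.1 (binomial sampling check)."""
        statuses, _ = generate_cohort(1000, 0, {"absent": 0.1}, seed=4,
                                      generate_data=False)
        frac = np.mean([not s.cardiac_present for s in statuses])
        se = np.sqrt(0.1 * 0.9 / 1000)
        assert abs(frac - 0.1) < 3 * se

    def test_same_seed_identical_cohort(self):
        a, _ = generate_cohort(10, 5, {"absent": 0.2, "dropout": 0.1},
                               seed=6, generate_data=False)
        b, _ = generate_cohort(10, 5, {"absent": 0.2, "dropout": 0.1},
                               seed=6, generate_data=False)
        assert [s.__dict__ for s in a] == [s.__dict__ for s in b]

    def test_bundle_channels_match_status(self, small_params):
        statuses, bundles = generate_cohort(
            4, 0, {"absent": 0.5}, seed=3, params=small_params)
        for s, b in zip(statuses, bundles):
            assert s.cardiac_present == b.cardiac.present

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(2, 0, {"absent": 1.5}, generate_data=False)
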