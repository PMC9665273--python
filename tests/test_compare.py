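"""Pipeline-comparison statistics and feasibility triage."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from physiofc import (SubjectStatus, bh_fdr, cross_pipeline_correlation,
                      feasibility_triage, icc_map, load_example_cohort,
                      paired_t_map)


class TestPairedT:
    def test_identical_pipelines_give_null(self):
        z = np.random.default_rng(0).normal(size=(5, 10))
        ps = paired_t_map(z, z)
        assert np.allclose(ps["t"], 0.0) and np.allclose(ps["p"], 1.0)

    def test_hand_computed_example(self):
        """Differences (1,2,3): t = 2/(1/sqrt(3)) = 3.4641, p from t(2)."""
        zA = np.zeros((3, 1))
        zB = np.array([[1.0], [2.0], [3.0]])
        ps = paired_t_map(zA, zB)
        assert np.isclose(ps["t"][0], 2 * np.sqrt(3))
        assert np.isclose(ps["p"][0], 2 * sps.t.sf(2 * np.sqrt(3), 2))

    def test_agrees_with_scipy_ttest_rel(self):
        rng = np.random.default_rng(5)
        zA = rng.normal(size=(8, 20))
        zB = zA + rng.normal(0, 0.3, size=(8, 20))
        ps = paired_t_map(zA, zB)
        t_ref, p_ref = sps.ttest_rel(zB, zA, axis=0)
        assert np.allclose(ps["t"], t_ref)
        assert np.allclose(ps["p"], p_ref)

    def test_zero_variance_sentinels(self):
        zA = np.zeros((4, 2))
        zB = np.zeros((4, 2))
        zB[:, 0] = 0.7  # constant nonzero difference
        ps = paired_t_map(zA, zB)
        assert np.isposinf(ps["t"][0]) and ps["p"][0] == 0.0
        assert ps["t"][1] == 0.0 and ps["p"][1] == 1.0

    def test_masked_pair_dropped_with_warning(self):
        zA = np.zeros((4, 2))
        zB = np.ones((4, 2))
        zA[2, 1] = np.nan
        with pytest.warns(UserWarning, match="masked"):
            ps = paired_t_map(zA, zB)
        assert np.isnan(ps["t"][1]) and ps["n"][1] == 0

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError):
            paired_t_map(np.zeros((2, 3)), np.ones((2, 3)))


def _bh_bruteforce(p):
    """Textbook step-up definition: adj_(i) = min_{j>=i} (m/j) p_(j)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m / (i + 1) * sorted_p[i])
        adj[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestBhFdr:
    def test_worked_example(self):
        adj, _ = bh_fdr(np.array([0.01, 0.02, 0.04]))
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_equal_pvalues_unchanged(self):
        adj, _ = bh_fdr(np.full(7, 0.2))
        assert np.allclose(adj, 0.2)

    def test_single_pvalue_identity(self):
        adj, _ = bh_fdr(np.array([0.31]))
        assert np.isclose(adj[0], 0.31)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.3]))

    def test_all_permutations_of_six_match_bruteforce(self):
        """Exhaustive step-up oracle over all orderings of 6 p-values."""
        base = np.array([0.001, 0.011, 0.17, 0.33, 0.62, 0.99])
        for perm in itertools.permutations(range(6)):
            p = base[list(perm)]
            adj, rej = bh_fdr(p)
            ref = _bh_bruteforce(p)
            assert np.allclose(adj, ref, atol=1e-12)
            assert np.array_equal(rej, ref < 0.05)


class TestCrossPipelineCorrelation:
    def test_identical_and_affine_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        r, _ = cross_pipeline_correlation(v, v)
        assert np.isclose(r, 1.0)
        r, _ = cross_pipeline_correlation(v, 2 * v)
        assert np.isclose(r, 1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            cross_pipeline_correlation(np.ones(5), np.arange(5.0))

    def test_masked_pairs_dropped(self):
        a = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        b = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        r, _ = cross_pipeline_correlation(a, b)
        assert np.isclose(r, 1.0)


def _icc21_oracle(table):
    """Brute-force two-way ANOVA ICC(2,1) for one n x k table."""
    n, k = table.shape
    grand = table.mean()
    msr = k * ((table.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((table.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((table - table.mean(axis=1, keepdims=True)
            - table.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIccMap:
    def test_perfect_agreement(self):
        z = np.random.default_rng(0).normal(size=(6, 4))
        ps = icc_map(z, z)
        assert np.allclose(ps["icc"], 1.0)

    def test_independent_noise_near_zero(self):
        """n = 200 independent pipelines: ICC within 3 SE of 0."""
        rng = np.random.default_rng(1)
        ps = icc_map(rng.normal(size=(200, 30)), rng.normal(size=(200, 30)))
        se = 1.0 / np.sqrt(200)
        assert np.abs(ps["icc"]).max() < 3 * se + 0.1

    def test_matches_bruteforce_anova_oracle(self):
        """Random small tables agree with the direct variance-component
        computation to 1e-10."""
        rng = np.random.default_rng(2)
        for n in (4, 5, 6):
            zA = rng.normal(size=(n, 8))
            zB = zA + rng.normal(0, 0.5, size=(n, 8))
            ps = icc_map(zA, zB)
            for j in range(8):
                table = np.column_stack([zA[:, j], zB[:, j]])
                assert abs(ps["icc"][j] - _icc21_oracle(table)) < 1e-10

    def test_matches_pingouin_reference(self):
        """Independent cross-check of ICC(2,1) value and p against
        pingouin's implementation on one 6-subject table."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(3)
        zA = rng.normal(size=(6, 1))
        zB = zA + rng.normal(0, 0.4, size=(6, 1))
        ps = icc_map(zA, zB)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(6), 2),
            "raters": np.tile(["A", "B"], 6),
            "score": np.column_stack([zA[:, 0], zB[:, 0]]).ravel()})
        ref = pg.intraclass_corr(data=df, targets="targets",
                                 raters="raters", ratings="score")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        assert abs(ps["icc"][0] - row["ICC"]) < 1e-9
        assert abs(ps["icc_p"][0] - row["pval"]) < 1e-9

    def test_degenerate_between_subject_variance_sentinel(self):
        zA = np.zeros((4, 1))
        zB = np.zeros((4, 1))
        with pytest.warns(UserWarning, match="degenerate"):
            ps = icc_map(zA, zB)
        assert np.isnan(ps["icc"][0])


class TestFeasibilityTriage:
    def test_packaged_cohort_categories(self):
        """Fixture rows reproduce the catalogued triage outcomes."""
        statuses = load_example_cohort()
        res = feasibility_triage(statuses)
        cat = res.statuses.set_index("id")["category"]
        assert cat["P5"] == "incomplete"      # plethysmography absent
        assert cat["C3"] == "poor_quality"    # intermittent signal loss
        assert cat["P1"] == "retained"        # all clean
        assert cat["P6"] == "unusable_fmri"   # failed segmentation

    def test_precedence_fmri_before_physio(self):
        s = SubjectStatus(id="X", group="patient", usable_fmri=False,
                          cardiac_present=False, resp_present=True,
                          cardiac_quality=None, resp_quality="noisy")
        res = feasibility_triage([s])
        assert res.statuses["category"].iloc[0] == "unusable_fmri"

    def test_duplicate_ids_raise(self):
        s = SubjectStatus(id="X", group="patient", usable_fmri=True,
                          cardiac_present=True, resp_present=True)
        with pytest.raises(ValueError):
            feasibility_triage([s, s])

    def test_absent_channel_with_quality_rejected(self):
        with pytest.raises(ValueError):
            SubjectStatus(id="Y", group="control", usable_fmri=True,
                          cardiac_present=False, resp_present=True,
                          cardiac_quality="clean")


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=30))
def test_bh_fdr_invariants(pvals):
    """Adjusted p >= raw p, monotone in the sorted order, capped at 1."""
    p = np.array(pvals)
    adj, _ = bh_fdr(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)
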