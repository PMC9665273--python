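"""Statistical comparison of the two correction pipelines and
feasibility triage.

Per region pair: paired t-tests on Fisher-z values with
Benjamini-Hochberg FDR correction, cross-pipeline Pearson correlation of
group-mean z, and intraclass correlation — ICC(2,1), two-way
random-effects, absolute agreement, single measures — between the two
pipelines, again FDR-corrected.  The triage stage reproduces the cohort
accounting: fMRI usability first, then physiological-channel completeness,
then recording quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairStats",
    "SubjectStatus",
    "TriageResult",
    "paired_t_map",
    "bh_fdr",
    "cross_pipeline_correlation",
    "icc_map",
    "feasibility_triage",
    "load_example_cohort",
]


@dataclass
class SubjectStatus:
    """Per-subject flags driving feasibility triage.

    Quality values are {"clean", "noisy", "dropout"} and must be None for
    an absent channel.
    """

    id: str
    group: str  # {"patient", "control"}
    usable_fmri: bool
    cardiac_present: bool
    resp_present: bool
    cardiac_quality: Optional[str] = "clean"
    resp_quality: Optional[str] = "clean"
    exclusion_reason: Optional[str] = None

    def __post_init__(self):
        if not self.cardiac_present and self.cardiac_quality is not None:
            raise ValueError("absent cardiac channel cannot carry a quality")
        if not self.resp_present and self.resp_quality is not None:
            raise ValueError("absent respiratory channel cannot carry a "
                             "quality")


@dataclass
class PairStats:
    """Long-format per-pair statistics table.

    Columns (as present): t, p, p_fdr, z_diff, n, icc, icc_p, icc_p_fdr.
    """

    table: pd.DataFrame

    def __getitem__(self, col):
        return self.table[col].to_numpy()


def _pair_frame(n_pairs: int) -> pd.DataFrame:
    return pd.DataFrame(index=pd.RangeIndex(n_pairs, name="pair"))


def paired_t_map(zA: np.ndarray, zB: np.ndarray) -> PairStats:
    """Two-sided paired t-test per region pair on z differences (B - A).

    ``zA`` and ``zB`` are subject x pair matrices from the two pipelines
    (A = RETROICOR, B = bandpass by convention).  Pairs with a masked
    (NaN) value in any subject are dropped with a warning (NaN statistics
    returned).  Zero-variance differences yield a +/-inf t sentinel with
    p = 0 (or t = 0, p = 1 when the difference is identically zero).
    """
    zA = np.atleast_2d(np.asarray(zA, float))
    zB = np.atleast_2d(np.asarray(zB, float))
    if zA.shape != zB.shape:
        raise ValueError("pipelines must share subjects and pairs")
    n, n_pairs = zA.shape
    if n < 3:
        raise ValueError("paired t-test needs at least 3 subjects")
    d = zB - zA
    masked = np.isnan(d).any(axis=0)
    if masked.any():
        warnings.warn(f"dropping {int(masked.sum())} pairs with masked "
                      "subject values")
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.full(n_pairs, np.nan)
    p = np.full(n_pairs, np.nan)
    ok = ~masked
    zero_var = ok & (sd == 0)
    reg = ok & (sd > 0)
    t[reg] = mean[reg] / (sd[reg] / np.sqrt(n))
    p[reg] = 2 * sps.t.sf(np.abs(t[reg]), df=n - 1)
    exact_null = zero_var & (mean == 0)
    shifted = zero_var & (mean != 0)
    t[exact_null], p[exact_null] = 0.0, 1.0
    t[shifted] = np.sign(mean[shifted]) * np.inf
    p[shifted] = 0.0
    tab = _pair_frame(n_pairs)
    tab["z_diff"] = mean
    tab["t"] = t
    tab["p"] = p
    tab["n"] = np.where(ok, n, 0)
    p_fdr, reject = bh_fdr(p)
    tab["p_fdr"] = p_fdr
    tab["reject"] = reject
    return PairStats(tab)


def bh_fdr(pvals: np.ndarray, q: float = 0.05
           ) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejections.

    NaN entries are excluded from the family and returned as NaN /
    not-rejected.  Adjusted values are monotone and capped at 1;
    rejection means adjusted p < ``q``.
    """
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    if ok.any():
        _, p_adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        adj[ok] = p_adj
        rej[ok] = p_adj < q
    return adj, rej


def cross_pipeline_correlation(meanZ_A: np.ndarray, meanZ_B: np.ndarray
                               ) -> Tuple[float, float]:
    """Pearson correlation (r, p) across region pairs of group-mean
    Fisher-z values from the two pipelines.  Masked pairs are dropped
    listwise."""
    a = np.asarray(meanZ_A, float)
    b = np.asarray(meanZ_B, float)
    if a.shape != b.shape:
        raise ValueError("mean-z vectors must align")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 pairs after masking")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a mean-z vector")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def _icc21(data: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ICC(2,1) over stacked pair tables.

    ``data`` has shape (n_subjects, k_raters, n_pairs).  Returns
    (icc, F, p) per pair, from the two-way random-effects ANOVA mean
    squares; the significance test is F = MSR/MSE on
    (n-1, (n-1)(k-1)) degrees of freedom.
    """
    n, k, _ = data.shape
    grand = data.mean(axis=(0, 1))
    row_means = data.mean(axis=1)     # subjects x pairs
    col_means = data.mean(axis=0)     # raters x pairs
    ssr = k * ((row_means - grand) ** 2).sum(axis=0)
    ssc = n * ((col_means - grand) ** 2).sum(axis=0)
    sst = ((data - grand) ** 2).sum(axis=(0, 1))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
        F = msr / mse
    p = sps.f.sf(F, n - 1, (n - 1) * (k - 1))
    return icc, F, p


def icc_map(zA: np.ndarray, zB: np.ndarray,
            form: str = "ICC2") -> PairStats:
    """Per-pair intraclass correlation between the two pipelines.

    Default form is ICC(2,1): two-way random effects, absolute agreement,
    single measures; ``form='ICC3'`` gives the consistency variant.
    Pairs with zero between-subject variance (or any masked value) return
    a NaN sentinel and are excluded from the FDR family with a warning.
    """
    zA = np.atleast_2d(np.asarray(zA, float))
    zB = np.atleast_2d(np.asarray(zB, float))
    if zA.shape != zB.shape:
        raise ValueError("pipelines must share subjects and pairs")
    n, n_pairs = zA.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    data = np.stack([zA, zB], axis=1)  # subjects x 2 x pairs
    masked = np.isnan(data).any(axis=(0, 1))
    icc, F, p = _icc21(np.nan_to_num(data))
    if form == "ICC3":
        # consistency: drop the rater variance from the denominator
        grand = data.mean(axis=(0, 1))
        row_means = data.mean(axis=1)
        k = 2
        ssr = k * ((row_means - grand) ** 2).sum(axis=0)
        sst = ((data - grand) ** 2).sum(axis=(0, 1))
        ssc = n * ((data.mean(axis=0) - grand) ** 2).sum(axis=0)
        sse = sst - ssr - ssc
        msr = ssr / (n - 1)
        mse = sse / ((n - 1) * (k - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            icc = (msr - mse) / (msr + (k - 1) * mse)
    elif form != "ICC2":
        raise ValueError("form must be 'ICC2' or 'ICC3'")
    between_var = np.var(np.nan_to_num(data).mean(axis=1), axis=0)
    degen = (between_var == 0) | masked
    if degen.any() and not masked.all():
        warnings.warn(f"{int(degen.sum())} pairs with degenerate or masked "
                      "tables excluded from ICC FDR")
    icc = np.where(degen, np.nan, icc)
    p = np.where(degen, np.nan, p)
    p_fdr, reject = bh_fdr(p)
    tab = _pair_frame(n_pairs)
    tab["icc"] = icc
    tab["icc_F"] = np.where(degen, np.nan, F)
    tab["icc_p"] = p
    tab["icc_p_fdr"] = p_fdr
    tab["icc_reject"] = reject
    return PairStats(tab)


@dataclass
class TriageResult:
    """Feasibility-triage output: per-subject categories and summary."""

    statuses: pd.DataFrame      # id, group, category, reason
    summary: pd.DataFrame       # counts/percentages by group and overall

    @property
    def retained_ids(self) -> List[str]:
        sel = self.statuses["category"] == "retained"
        return self.statuses.loc[sel, "id"].tolist()


def feasibility_triage(statuses: Sequence[SubjectStatus]) -> TriageResult:
    """Partition subjects by the triage precedence: fMRI usability ->
    physio completeness -> physio quality -> retained.

    Categories: ``unusable_fmri`` (imaging artefacts), ``incomplete``
    (usable fMRI, >= 1 channel absent), ``poor_quality`` (channels present
    but any recording not clean), ``retained``.  The summary reports, per
    group and overall: enrolled, usable-fMRI, incomplete, poor-quality and
    retained counts with percentages (incomplete/poor relative to
    usable-fMRI subjects, retained relative to usable-fMRI subjects,
    usable relative to enrolled).
    """
    ids = [s.id for s in statuses]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    rows = []
    for s in statuses:
        if not s.usable_fmri:
            cat = "unusable_fmri"
        elif not (s.cardiac_present and s.resp_present):
            cat = "incomplete"
        elif (s.cardiac_quality != "clean") or (s.resp_quality != "clean"):
            cat = "poor_quality"
        else:
            cat = "retained"
        rows.append((s.id, s.group, cat, s.exclusion_reason))
    df = pd.DataFrame(rows, columns=["id", "group", "category", "reason"])

    def summarize(sub: pd.DataFrame, label: str) -> dict:
        n = len(sub)
        usable = int((sub["category"] != "unusable_fmri").sum())
        inc = int((sub["category"] == "incomplete").sum())
        poor = int((sub["category"] == "poor_quality").sum())
        ret = int((sub["category"] == "retained").sum())
        pct = lambda a, b: 100.0 * a / b if b else np.nan
        return {
            "group": label, "n_enrolled": n, "n_usable_fmri": usable,
            "n_excluded_image_quality": n - usable,
            "n_incomplete": inc, "n_poor_quality": poor,
            "n_retained": ret,
            "pct_usable_fmri": pct(usable, n),
            "pct_incomplete": pct(inc, usable),
            "pct_poor_quality": pct(poor, usable),
            "pct_incomplete_or_poor": pct(inc + poor, usable),
            "pct_retained": pct(ret, usable),
        }

    parts = [summarize(df[df["group"] == g], g)
             for g in ("patient", "control") if (df["group"] == g).any()]
    parts.append(summarize(df, "overall"))
    return TriageResult(statuses=df, summary=pd.DataFrame(parts))


_NOISE_QUALITY = {
    "none": "clean",
    "machine_noise": "noisy",
    "motion": "noisy",
    "bad_position": "noisy",
    "noisy": "noisy",
    "intermittent_loss": "dropout",
}


def _statuses_from_frame(df: pd.DataFrame) -> List[SubjectStatus]:
    out = []
    for _, r in df.iterrows():
        cp = r["cardiac_present"] == "Y"
        rp = r["resp_present"] == "Y"
        out.append(SubjectStatus(
            id=r["id"], group=r["group"],
            usable_fmri=r["usable_fmri"] == "Y",
            cardiac_present=cp, resp_present=rp,
            cardiac_quality=_NOISE_QUALITY[r["cardiac_noise"]] if cp
            else None,
            resp_quality=_NOISE_QUALITY[r["resp_noise"]] if rp else None,
            exclusion_reason=(None if pd.isna(r["exclusion_note"])
                              else r["exclusion_note"])))
    return out


def load_example_cohort() -> List[SubjectStatus]:
    """The packaged 35-subject cohort status table (23 ICU patients with
    severe TBI and 12 healthy controls) used for the feasibility
    accounting."""
    frames = []
    for fname in ("table1_patients.csv", "table2_controls.csv"):
        with resources.files("physiofc.data").joinpath(fname).open() as fh:
            frames.append(pd.read_csv(fh, dtype=str))
    return _statuses_from_frame(pd.concat(frames, ignore_index=True))
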