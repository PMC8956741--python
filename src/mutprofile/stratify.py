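"""Cohort assignment by MSI status and TMB, and prevalence statistics.

Tumors are assigned to three analysis cohorts: MT-L (microsatellite stable
plus TMB < 16 mut/Mb), MT-H (MSI-high, or TMB in [16, 100) where only TMB is
known), and MSS-htmb (annotated MSS but TMB >= 16).  A clinical MSI
annotation always overrides the TMB rule; samples with neither annotation
nor TMB, or unknown MSI with TMB >= 100, are excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from mutprofile.datamodel import SampleRecord, ThresholdConfig, VariantRecord

ANALYSIS_COHORTS = ("MT-L", "MT-H", "MSS-htmb")


def assign_cohort(sample: SampleRecord, thr: ThresholdConfig | None = None) -> str:
    """Cohort label for one sample; total over all inputs.

    TMB exactly at the upper cutpoint with unknown MSI is excluded (the
    boundary is unclaimed by either rule).
    """
    thr = thr or ThresholdConfig()
    msi, tmb = sample.msi_status, sample.tmb
    if msi == "MSI-H":
        return "MT-H"
    if msi == "MSS":
        if tmb is not None and tmb >= thr.tmb_low:
            return "MSS-htmb"
        return "MT-L"
    # MSI unknown: TMB decides
    if tmb is None:
        return "excluded"
    if tmb < thr.tmb_low:
        return "MT-L"
    if tmb < thr.tmb_very_high:
        return "MT-H"
    return "excluded"


def assign_cohorts(
    samples: list[SampleRecord], thr: ThresholdConfig | None = None
) -> list[SampleRecord]:
    """Assign ``cohort`` in place for every sample; returns the input list."""
    for s in samples:
        s.cohort = assign_cohort(s, thr)
    return samples


@dataclass
class CohortSummary:
    cohort: str
    n: int
    n_altered: int
    n_single: int
    n_multi: int
    prevalence: float
    ci_low: float
    ci_high: float
    by_sex: dict = field(default_factory=dict)
    by_subsite: dict = field(default_factory=dict)
    by_age_bin: dict = field(default_factory=dict)

    @property
    def single_share(self) -> float:
        return self.n_single / self.n if self.n else 0.0

    @property
    def multi_share(self) -> float:
        return self.n_multi / self.n if self.n else 0.0


DEFAULT_AGE_BINS = (30, 40, 50, 60, 70, 80)


def _age_bin(age: int | None, edges=DEFAULT_AGE_BINS) -> str:
    if age is None:
        return "missing"
    if age < edges[0]:
        return f"<{edges[0]}"
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo <= age < hi:
            return f"{lo}-{hi - 1}"
    return f"{edges[-1]}+"


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def pten_mutation_counts(
    variants: list[VariantRecord], gene: str = "PTEN"
) -> dict[str, int]:
    """Count of distinct non-synonymous records of ``gene`` per sample."""
    counts: dict[str, int] = {}
    seen: set[tuple] = set()
    for v in variants:
        if v.gene != gene:
            continue
        key = (v.sample_id, v.variant_class, v.hgvs_c, v.hgvs_p, v.codon)
        if key in seen:  # duplicated rows do not inflate multiplicity
            continue
        seen.add(key)
        counts[v.sample_id] = counts.get(v.sample_id, 0) + 1
    return counts


def summarize_cohorts(
    samples: list[SampleRecord],
    variants: list[VariantRecord],
    gene: str = "PTEN",
) -> dict[str, CohortSummary]:
    """Per-cohort alteration prevalence and single/multiple breakdown.

    A sample counts as altered if it carries at least one non-synonymous
    record of the gene, of any class (deletions and rearrangements included).
    Prevalence confidence intervals are Wilson score intervals.
    """
    counts = pten_mutation_counts(variants, gene)
    out: dict[str, CohortSummary] = {}
    for cohort in ANALYSIS_COHORTS:
        members = [s for s in samples if s.cohort == cohort]
        n = len(members)
        n_mut = [counts.get(s.sample_id, 0) for s in members]
        n_altered = sum(1 for k in n_mut if k >= 1)
        n_single = sum(1 for k in n_mut if k == 1)
        n_multi = sum(1 for k in n_mut if k >= 2)
        prev = n_altered / n if n else 0.0
        lo, hi = wilson_interval(n_altered, n) if n else (0.0, 1.0)
        by_sex: dict[str, tuple[int, int]] = {}
        by_subsite: dict[str, tuple[int, int]] = {}
        by_age: dict[str, tuple[int, int]] = {}
        for s, k in zip(members, n_mut):
            for d, key in (
                (by_sex, s.sex or "missing"),
                (by_subsite, s.subsite or "missing"),
                (by_age, _age_bin(s.age)),
            ):
                tot, alt = d.get(key, (0, 0))
                d[key] = (tot + 1, alt + (k >= 1))
        out[cohort] = CohortSummary(
            cohort=cohort, n=n, n_altered=n_altered, n_single=n_single,
            n_multi=n_multi, prevalence=prev, ci_low=lo, ci_high=hi,
            by_sex=by_sex, by_subsite=by_subsite, by_age_bin=by_age,
        )
    return out


def summary_table(summaries: dict[str, CohortSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries.values():
        rows.append({
            "cohort": s.cohort, "n": s.n, "n_altered": s.n_altered,
            "n_single": s.n_single, "n_multi": s.n_multi,
            "prevalence": s.prevalence, "ci_low": s.ci_low, "ci_high": s.ci_high,
            "single_share": s.single_share, "multi_share": s.multi_share,
        })
    return pd.DataFrame(rows)


def compare_proportions(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided p of the two-proportion test with continuity correction.

    Pooled-variance chi-square form with Yates-style continuity correction,
    matching the classical two-sample test for equality of proportions.
    Symmetric in its two groups.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    p_pool = (x1 + x2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 1.0
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    correction = min(abs(p1 - p2), 0.5 * (1 / n1 + 1 / n2))
    z = (abs(p1 - p2) - correction) / se
    return float(2 * stats.norm.sf(z))


@dataclass
class TrendResult:
    slope: float            # log-odds per predictor unit
    se: float | None
    p_value: float | None   # two-sided Wald; None when separated
    separated: bool = False


def trend_logistic(outcome: np.ndarray, predictor: np.ndarray) -> TrendResult:
    """Logistic trend of a binary outcome on one continuous predictor.

    Maximum-likelihood fit with intercept; returns the log-odds slope per
    predictor unit and its two-sided Wald p-value.  Perfect separation is
    flagged and the p-value reported missing.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("predictor must take at least two distinct values")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return TrendResult(slope=math.nan, se=None, p_value=None, separated=True)
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if not math.isfinite(se) or se > 1e3 * max(1.0, abs(slope)):
        return TrendResult(slope=slope, se=None, p_value=None, separated=True)
    return TrendResult(slope=slope, se=se, p_value=float(fit.pvalues[1]))
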