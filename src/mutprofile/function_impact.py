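"""Dichotomization of variants into loss-of-function vs wild-type-like.

The call integrates three evidence tiers, evaluated in a fixed order:
protein truncation within codons 1-352 is damaging outright; curated
clinical labels come next ("conflicting" assessments count as damaging); and
deep-mutational-scanning scores last — lipid-phosphatase fitness < -1.1
indicates impaired catalysis, VAMP-seq abundance < 0.4 substantially reduced
protein levels.  Score-based damaging calls are demoted to NA when the
substitution is common in the general population (frequency >= 1e-5), since
a common germline allele is unlikely to be function-impairing.

Missense/in-frame variants that lose phosphatase activity while retaining
abundance are flagged as dominant-negative (DNE) candidates, consistent with
PTEN acting as a homodimer: a stable catalytically dead subunit can poison
the wild-type partner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

from mutprofile.datamodel import (
    TRUNCATING_CLASSES,
    ThresholdConfig,
    VariantRecord,
)
from mutprofile.io import FunctionScoreRow, FunctionScoreTable
from mutprofile.stratify import wilson_interval

_MISSENSE_RE = re.compile(r"p\.\(?([A-Z])(\d+)([A-Z])\b")


def substitution_key(variant: VariantRecord) -> tuple[int, str] | None:
    """(codon, alt amino acid) key for a missense substitution, else None."""
    m = _MISSENSE_RE.search(variant.hgvs_p or "")
    if not m:
        return None
    return int(m.group(2)), m.group(3)


@dataclass
class ImpactCall:
    variant_key: str
    lof_call: str          # LoF | WT-like | NA
    basis: str             # truncation-rule | clinical-label | lpa-cut |
                           # abundance-cut | none
    dne_flag: bool = False


def dichotomize_lof(
    variant: VariantRecord,
    scores: FunctionScoreTable,
    thr: ThresholdConfig | None = None,
) -> ImpactCall:
    """LoF / WT-like / NA call for one variant.

    Evaluation order: (1) truncating class, codon <= 352 -> LoF
    (truncation-rule); truncating beyond 352 -> WT-like; (2) clinical label
    damaging or conflicting -> LoF; (3) LPA score below cut -> LoF; (4)
    abundance below cut -> LoF; (5) clinical label benign -> WT-like; (6)
    scores present and above both cuts -> WT-like; (7) otherwise NA.
    """
    thr = thr or ThresholdConfig()
    key = f"{variant.gene}:{variant.hgvs_p or variant.hgvs_c}"

    if variant.variant_class in TRUNCATING_CLASSES:
        if variant.codon is None:
            # splice with no codon mapping: impact not resolvable
            return ImpactCall(key, "NA", "none")
        if variant.codon <= thr.trunc_last_codon:
            return ImpactCall(key, "LoF", "truncation-rule")
        return ImpactCall(key, "WT-like", "truncation-rule")

    sub = substitution_key(variant)
    row: FunctionScoreRow | None = scores.get(*sub) if sub else None

    if row is not None and row.clinical_label in ("damaging", "conflicting"):
        return ImpactCall(key, "LoF", "clinical-label",
                          dne_flag=_dne(variant, row, thr))
    if row is not None:
        freq_ok = row.population_freq is None or (
            row.population_freq < thr.population_freq_max
        )
        if row.lpa_score is not None and row.lpa_score < thr.lpa_cut:
            if freq_ok:
                return ImpactCall(key, "LoF", "lpa-cut",
                                  dne_flag=_dne(variant, row, thr))
            return ImpactCall(key, "NA", "none")
        if row.abundance_score is not None and row.abundance_score < thr.abundance_cut:
            if freq_ok:
                return ImpactCall(key, "LoF", "abundance-cut")
            return ImpactCall(key, "NA", "none")
        if row.clinical_label == "benign":
            return ImpactCall(key, "WT-like", "clinical-label")
        if row.lpa_score is not None or row.abundance_score is not None:
            return ImpactCall(key, "WT-like",
                              "lpa-cut" if row.lpa_score is not None
                              else "abundance-cut")
    return ImpactCall(key, "NA", "none")


def _dne(
    variant: VariantRecord, row: FunctionScoreRow, thr: ThresholdConfig
) -> bool:
    """Dominant-negative candidacy: phosphatase-dead but stable missense."""
    if row.dne_curated:
        return True
    if variant.variant_class not in ("missense", "inframe_indel"):
        return False
    return (
        row.lpa_score is not None
        and row.lpa_score < thr.lpa_cut
        and row.abundance_score is not None
        and row.abundance_score >= thr.abundance_cut
    )


def flag_dne(
    call: ImpactCall,
    variant: VariantRecord,
    scores: FunctionScoreTable,
    thr: ThresholdConfig | None = None,
) -> bool:
    """Recompute the DNE flag for a finished call (curated flag wins)."""
    thr = thr or ThresholdConfig()
    sub = substitution_key(variant)
    row = scores.get(*sub) if sub else None
    if row is None:
        return False
    return call.lof_call == "LoF" and _dne(variant, row, thr)


@dataclass
class ScoreComparison:
    welch_t: float
    welch_p: float
    ks_stat: float
    ks_p: float
    boxstats_a: tuple     # (5th, 25th, median, 75th, 95th percentile)
    boxstats_b: tuple


def _boxstats(x: np.ndarray) -> tuple:
    return tuple(float(v) for v in np.percentile(x, [5, 25, 50, 75, 95]))


def compare_score_distributions(
    group_a, group_b
) -> ScoreComparison:
    """Welch's unequal-variance t test and two-sample Kolmogorov-Smirnov
    test between two score distributions, with 5/25/50/75/95-percentile
    boxplot summaries."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t = stats.ttest_ind(a, b, equal_var=False)
    ks = stats.ks_2samp(a, b)
    return ScoreComparison(
        welch_t=float(t.statistic), welch_p=float(t.pvalue),
        ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
        boxstats_a=_boxstats(a), boxstats_b=_boxstats(b),
    )


def lof_fraction(calls: list[ImpactCall]) -> tuple[float, float, float]:
    """Fraction LoF among determinate calls, with Wilson 95% CI."""
    determinate = [c for c in calls if c.lof_call != "NA"]
    if not determinate:
        raise ValueError("no determinate impact calls")
    k = sum(1 for c in determinate if c.lof_call == "LoF")
    n = len(determinate)
    lo, hi = wilson_interval(k, n)
    return k / n, lo, hi
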