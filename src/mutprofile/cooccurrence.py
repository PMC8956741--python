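"""Gene-level co-occurrence / mutual-exclusivity of PTEN alteration classes.

For each (PTEN alteration class, partner gene, cohort) a 2x2 table of sample
counts is tested with a two-sided Fisher exact test.  The odds ratio uses a
Haldane-Anscombe +0.5 correction on all cells when any cell is zero, with a
Woolf logit 95% confidence interval; q-values are Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mutprofile.datamodel import (
    NO_CODON_CLASSES,
    SampleRecord,
    VariantRecord,
)
from mutprofile.stratify import compare_proportions

DEFAULT_PARTNER_GENES = ("APC", "KRAS", "TP53", "SMAD4", "PIK3CA")

#: selectors for which PTEN alterations make a sample "PTEN-positive"
PTEN_SELECTORS = ("all", "point", "point-lof", "deletion")


@dataclass
class CooccurrenceResult:
    a: int                  # both altered
    b: int                  # PTEN only
    c: int                  # partner only
    d: int                  # neither
    odds_ratio: float
    log2_or: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float | None = None
    label: str | None = None


def fisher_twosided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Conditional on the margins, sums the probabilities of every table whose
    hypergeometric probability does not exceed the observed one (with the
    customary small relative gate for floating-point ties).  Equivalent to
    the classical two-sided Fisher test, computed in one vectorized pmf
    evaluation over the support.
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    k = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(k, n, r1, c1)
    obs = pmf[k == a][0]
    return float(min(pmf[pmf <= obs * (1 + 1e-7)].sum(), 1.0))


def fisher_cooccurrence(a: int, b: int, c: int, d: int) -> CooccurrenceResult:
    """Fisher exact test and corrected odds ratio for one 2x2 table."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b + c + d == 0:
        raise ValueError("empty 2x2 table")
    p = fisher_twosided_p(a, b, c, d)
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    or_ = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(or_)
    return CooccurrenceResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=or_, log2_or=log_or / math.log(2),
        ci_low=math.exp(log_or - 1.96 * se),
        ci_high=math.exp(log_or + 1.96 * se),
        p_value=float(p),
    )


def _pten_positive(
    variants: list[VariantRecord], selector: str, gene: str = "PTEN"
) -> set[str]:
    if selector not in PTEN_SELECTORS:
        raise ValueError(f"unknown selector {selector!r}")
    pos = set()
    for v in variants:
        if v.gene != gene:
            continue
        if selector == "all":
            pos.add(v.sample_id)
        elif selector == "point":
            if v.variant_class not in NO_CODON_CLASSES:
                pos.add(v.sample_id)
        elif selector == "point-lof":
            if v.variant_class not in NO_CODON_CLASSES and v.lof_call == "LoF":
                pos.add(v.sample_id)
        elif selector == "deletion":
            if v.variant_class == "deep_deletion":
                pos.add(v.sample_id)
    return pos


def _gene_positive(variants: list[VariantRecord], gene: str) -> set[str]:
    return {v.sample_id for v in variants if v.gene == gene}


def two_by_two(
    sample_ids: list[str], set_a: set[str], set_b: set[str]
) -> tuple[int, int, int, int]:
    a = b = c = d = 0
    for sid in sample_ids:
        in_a, in_b = sid in set_a, sid in set_b
        if in_a and in_b:
            a += 1
        elif in_a:
            b += 1
        elif in_b:
            c += 1
        else:
            d += 1
    return a, b, c, d


def cooccurrence_panel(
    samples: list[SampleRecord],
    variants: list[VariantRecord],
    selector: str = "all",
    genes: tuple[str, ...] = DEFAULT_PARTNER_GENES,
    cohorts: tuple[str, ...] | None = None,
) -> dict[tuple[str, str], CooccurrenceResult]:
    """Fisher co-occurrence of a PTEN alteration class with each partner
    gene, per cohort (``None`` key pools every assigned sample).  Results
    carry the 2x2 counts for audit and BH q-values across the panel."""
    pten_pos = _pten_positive(variants, selector)
    keys, results = [], []
    cohort_list = cohorts if cohorts is not None else (None,)
    for cohort in cohort_list:
        members = [
            s.sample_id for s in samples
            if cohort is None or s.cohort == cohort
        ]
        if not members:
            continue
        for gene in genes:
            gene_pos = _gene_positive(variants, gene)
            res = fisher_cooccurrence(*two_by_two(members, pten_pos, gene_pos))
            res.label = f"{selector}|{gene}|{cohort or 'all'}"
            keys.append((cohort or "all", gene))
            results.append(res)
    if results:
        qs = fdr_adjust([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = q
    return dict(zip(keys, results))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def cooccurrence_by_age(
    samples: list[SampleRecord],
    variants: list[VariantRecord],
    age_bins: list[tuple[int, int]],
    selector: str = "all",
    gene: str = "PIK3CA",
) -> dict[tuple[int, int], CooccurrenceResult | None]:
    """Per-age-bin Fisher co-occurrence (bins inclusive); bins where any
    margin is empty are reported as ``None``."""
    if not any(
        s.age is not None and lo <= s.age <= hi
        for s in samples for lo, hi in age_bins
    ):
        raise ValueError("no samples fall into any age bin")
    pten_pos = _pten_positive(variants, selector)
    gene_pos = _gene_positive(variants, gene)
    out: dict[tuple[int, int], CooccurrenceResult | None] = {}
    for lo, hi in age_bins:
        members = [
            s.sample_id for s in samples
            if s.age is not None and lo <= s.age <= hi
        ]
        if not members:
            out[(lo, hi)] = None
            continue
        a, b, c, d = two_by_two(members, pten_pos, gene_pos)
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            out[(lo, hi)] = None
            continue
        out[(lo, hi)] = fisher_cooccurrence(a, b, c, d)
    return out


def exclusive_group_rates(
    samples: list[SampleRecord],
    variants: list[VariantRecord],
    genes: tuple[str, str, str] = ("APC", "KRAS", "TP53"),
) -> dict[str, tuple[int, int]]:
    """PTEN alteration counts within the 8-way presence/absence partition of
    three driver genes.  Keys are labels like ``"APC+KRAS"`` or ``"none"``;
    values are (n samples in group, n PTEN-altered)."""
    pten_pos = _pten_positive(variants, "all")
    gene_pos = {g: _gene_positive(variants, g) for g in genes}
    out: dict[str, tuple[int, int]] = {}
    for s in samples:
        present = [g for g in genes if s.sample_id in gene_pos[g]]
        label = "+".join(present) if present else "none"
        n, k = out.get(label, (0, 0))
        out[label] = (n + 1, k + (s.sample_id in pten_pos))
    return out


def group_rate_significance_matrix(
    group_rates: dict[str, tuple[int, int]]
) -> dict[tuple[str, str], float]:
    """Pairwise two-proportion tests of PTEN alteration rate between groups,
    BH-adjusted; returns q-values keyed by group-label pair."""
    labels = sorted(group_rates)
    pairs, ps = [], []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            na, ka = group_rates[la]
            nb, kb = group_rates[lb]
            if na == 0 or nb == 0:
                continue
            pairs.append((la, lb))
            ps.append(compare_proportions(ka, na, kb, nb))
    qs = fdr_adjust(ps)
    return dict(zip(pairs, qs))
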