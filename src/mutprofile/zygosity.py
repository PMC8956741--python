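"""Loss-of-heterozygosity classification and mutation-multiplicity skew.

Samples carrying PTEN point/indel mutations with allele copy-number data are
sorted into three zygosity classes: only the mutated allele present
(interpreted as LOH), mutated plus wild-type allele, or multiple distinct
mutated alleles.  The multiplicity analysis compares the observed frequency
of samples with 0, 1, or >1 mutations against the expectation under a
Poisson null with the cohort's empirical rate, reporting log2(obs/exp) and
an exact binomial p per category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mutprofile.datamodel import NO_CODON_CLASSES, VariantRecord
from mutprofile.hotspots import binomial_tail

LOH_CLASSES = ("mut_only", "mut_plus_wt", "multi_mut")


@dataclass
class LOHCall:
    sample_id: str
    loh_class: str          # mut_only | mut_plus_wt | multi_mut


def _point_mutations(variants: list[VariantRecord], gene: str = "PTEN"):
    return [
        v for v in variants
        if v.gene == gene and v.variant_class not in NO_CODON_CLASSES
    ]


def classify_loh(sample_variants: list[VariantRecord]) -> LOHCall | None:
    """Zygosity class for one sample's PTEN point/indel mutations.

    Two or more distinct mutations -> multi_mut; a single mutation with
    total copy number equal to the mutated-allele copy number -> mut_only
    (LOH); otherwise a wild-type allele remains -> mut_plus_wt.  Returns
    ``None`` (undetermined) when no mutation has copy-number data.
    """
    muts = _point_mutations(sample_variants)
    if not muts:
        return None
    sid = muts[0].sample_id
    distinct = {(v.hgvs_c, v.hgvs_p, v.codon, v.variant_class) for v in muts}
    if len(distinct) >= 2:
        return LOHCall(sid, "multi_mut")
    with_cn = [
        v for v in muts
        if v.mut_allele_cn is not None and v.total_cn is not None
    ]
    if not with_cn:
        return None
    v = with_cn[0]
    if v.total_cn == v.mut_allele_cn:
        return LOHCall(sid, "mut_only")
    return LOHCall(sid, "mut_plus_wt")


def classify_loh_all(
    variants: list[VariantRecord], gene: str = "PTEN"
) -> dict[str, LOHCall]:
    by_sample: dict[str, list[VariantRecord]] = {}
    for v in _point_mutations(variants, gene):
        by_sample.setdefault(v.sample_id, []).append(v)
    out = {}
    for sid, vs in by_sample.items():
        call = classify_loh(vs)
        if call is not None:
            out[sid] = call
    return out


def loh_matrix(variants: list[VariantRecord], gene: str = "PTEN") -> pd.DataFrame:
    """Percentage matrix of mutations over (total_cn rows x mut_allele_cn
    columns); cells sum to 100 per matrix."""
    rows = [
        (v.total_cn, v.mut_allele_cn)
        for v in _point_mutations(variants, gene)
        if v.total_cn is not None and v.mut_allele_cn is not None
    ]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["total_cn", "mut_allele_cn"])
    tab = pd.crosstab(df["total_cn"], df["mut_allele_cn"])
    return 100.0 * tab / tab.values.sum()


@dataclass
class MultiplicitySkew:
    category: str           # "0" | "1" | ">1"
    observed: int
    obs_freq: float
    exp_freq: float
    log2_ratio: float | None
    p_value: float | None


def multiplicity_skew(
    mutation_counts: list[int] | np.ndarray,
) -> list[MultiplicitySkew]:
    """Observed vs Poisson-expected frequencies of 0 / 1 / >1 mutations.

    The null rate is the cohort's empirical mean count; the per-category
    p-value is a two-sided exact binomial test of the observed category
    count against its Poisson-expected probability.
    """
    counts = np.asarray(mutation_counts, dtype=int)
    n = len(counts)
    if n == 0:
        raise ValueError("empty cohort")
    lam = counts.sum() / n
    exp = {
        "0": math.exp(-lam),
        "1": lam * math.exp(-lam),
    }
    exp[">1"] = max(1.0 - exp["0"] - exp["1"], 0.0)
    obs = {
        "0": int((counts == 0).sum()),
        "1": int((counts == 1).sum()),
        ">1": int((counts > 1).sum()),
    }
    out = []
    for cat in ("0", "1", ">1"):
        e, o = exp[cat], obs[cat]
        obs_freq = o / n
        if e <= 0.0:
            out.append(MultiplicitySkew(cat, o, obs_freq, e, None, None))
            continue
        ratio = obs_freq / e
        log2r = math.log2(ratio) if ratio > 0 else -math.inf
        p = float(stats.binomtest(o, n, e, alternative="two-sided").pvalue)
        out.append(MultiplicitySkew(cat, o, obs_freq, e, log2r, p))
    return out


@dataclass
class PairCooccurrence:
    n_a: int
    n_b: int
    k: int
    p0: float
    p_value: float
    neglog10_p: float


def pairwise_hotspot_cooccurrence(
    n_a: int, n_b: int, k: int, n: int
) -> PairCooccurrence:
    """Binomial co-occurrence test for two hotspot mutations.

    Under independence the per-sample co-occurrence probability is
    p0 = (nA/n)(nB/n); the p-value is the exact upper binomial tail
    P(X >= k) with X ~ Binomial(n, p0).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n_a == 0 or n_b == 0:
        return PairCooccurrence(n_a, n_b, k, 0.0, 1.0, 0.0)
    p0 = (n_a / n) * (n_b / n)
    p = binomial_tail(k, n, p0)
    nlp = float(-np.log10(p)) if p > 0 else np.inf
    return PairCooccurrence(n_a, n_b, k, p0, p, max(nlp, 0.0))


def hotspot_zygosity_profile(
    variants: list[VariantRecord],
    hotspot_labels: dict[str, set[str]],
    gene: str = "PTEN",
) -> pd.DataFrame:
    """Cross-tabulation of named hotspot mutations against zygosity class.

    ``hotspot_labels`` maps a display label (e.g. ``"R130*"``) to the set of
    hgvs_p strings it covers.  Rows are labels, columns LOH classes; values
    are sample counts.
    """
    calls = classify_loh_all(variants, gene)
    rows = []
    for label, hgvs_set in hotspot_labels.items():
        carriers = {
            v.sample_id for v in variants
            if v.gene == gene and v.hgvs_p in hgvs_set
        }
        row = {"label": label}
        for cls in LOH_CLASSES:
            row[cls] = sum(
                1 for sid in carriers
                if sid in calls and calls[sid].loh_class == cls
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("label") if rows else pd.DataFrame()
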