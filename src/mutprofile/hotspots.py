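"""Single-residue hotspot calling and sliding-window enrichment.

A codon is a hotspot when its mutation count, combining all substitutions
observed at that position, exceeds the uniform-placement binomial null
(per-site probability 1/L over the L = 403 residues) at the tightened
significance level alpha = 0.005, computed as an exact binomial tail with no
normal approximation.  "Strongly preferred" (major) hotspots additionally
carry more than 3% of the cohort's mutations; "recurrent" sites have count
> 6.  A second pass scans 5-residue sliding windows (stride 1) over the
non-hotspot mutations, reporting -log10 p against the Binomial(N, w/L) null;
the significance threshold on that scale is -log10(0.005) ~ 2.30.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mutprofile.datamodel import (
    NO_CODON_CLASSES,
    PTEN_LENGTH,
    TRUNCATING_CLASSES,
    ThresholdConfig,
    VariantRecord,
)

CLASS_FILTERS = {
    "all-point": None,
    "missense+inframe": {"missense", "inframe_indel"},
    "truncating": TRUNCATING_CLASSES,
}


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p0)."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    return float(stats.binom.sf(k - 1, n, p0))


def tally_codon_counts(
    variants: list[VariantRecord],
    cohort: str | None = None,
    class_filter: str = "all-point",
    gene: str = "PTEN",
    cohort_by_sample: dict[str, str] | None = None,
) -> dict[int, int]:
    """Mutation count per codon, excluding classes with no codon.

    ``cohort`` restricts to variants whose sample belongs to that cohort
    (requires ``cohort_by_sample``); ``None`` pools all samples.
    """
    if class_filter not in CLASS_FILTERS:
        raise ValueError(f"unknown class_filter {class_filter!r}")
    allowed = CLASS_FILTERS[class_filter]
    counts: dict[int, int] = {}
    for v in variants:
        if v.gene != gene or v.codon is None:
            continue
        if v.variant_class in NO_CODON_CLASSES:
            continue
        if allowed is not None and v.variant_class not in allowed:
            continue
        if cohort is not None:
            if cohort_by_sample is None:
                raise ValueError("cohort filtering requires cohort_by_sample")
            if cohort_by_sample.get(v.sample_id) != cohort:
                continue
        counts[v.codon] = counts.get(v.codon, 0) + 1
    return counts


@dataclass
class HotspotCall:
    codon: int
    count: int
    p0: float
    p_value: float
    significant: bool
    share: float
    major: bool
    recurrent: bool
    cohort: str | None = None
    class_breakdown: dict = field(default_factory=dict)


def call_codon_hotspots(
    counts: dict[int, int],
    n_total: int | None = None,
    length: int = PTEN_LENGTH,
    thr: ThresholdConfig | None = None,
    cohort: str | None = None,
    min_count: int = 2,
) -> list[HotspotCall]:
    """Per-codon exact binomial hotspot test.

    Significance requires both p < alpha and count >= ``min_count`` — with
    tiny cohorts a single mutation can already beat alpha under the uniform
    null, a degenerate call the count guard suppresses.  No multiple-testing
    correction is applied; the globally tightened alpha stands in for it.
    """
    thr = thr or ThresholdConfig()
    if n_total is None:
        n_total = sum(counts.values())
    if n_total == 0:
        return []
    p0 = 1.0 / length
    calls = []
    for codon in sorted(counts):
        k = counts[codon]
        if k == 0:
            continue
        p = binomial_tail(k, n_total, p0)
        share = k / n_total
        calls.append(
            HotspotCall(
                codon=codon, count=k, p0=p0, p_value=p,
                significant=(p < thr.alpha and k >= min_count),
                share=share,
                major=share > thr.major_hotspot_share,
                recurrent=k > thr.hotspot_min_count,
                cohort=cohort,
            )
        )
    return calls


def flag_major_hotspots(
    calls: list[HotspotCall],
    cohort_total: int,
    thr: ThresholdConfig | None = None,
) -> list[HotspotCall]:
    """Recompute share / major / recurrent flags against ``cohort_total``."""
    thr = thr or ThresholdConfig()
    if cohort_total <= 0:
        raise ValueError("cohort_total must be positive")
    for c in calls:
        c.share = c.count / cohort_total
        c.major = c.share > thr.major_hotspot_share
        c.recurrent = c.count > thr.hotspot_min_count
    return calls


@dataclass
class WindowEnrichment:
    start: int
    end: int
    count: int
    p_value: float
    neglog10_p: float
    significant: bool


def window_enrichment_scan(
    counts_nonhotspot: dict[int, int],
    n_nonhotspot: int | None = None,
    length: int = PTEN_LENGTH,
    thr: ThresholdConfig | None = None,
) -> list[WindowEnrichment]:
    """Sliding-window binomial enrichment over non-hotspot mutations.

    Windows of ``window_len`` consecutive residues, stride 1, tiling
    1..L-w+1; window null probability w/L.  Significant iff
    -log10 p > -log10(alpha).
    """
    thr = thr or ThresholdConfig()
    w = thr.window_len
    if length < w:
        raise ValueError("sequence shorter than window")
    if n_nonhotspot is None:
        n_nonhotspot = sum(counts_nonhotspot.values())
    track = np.zeros(length + 1)
    for codon, k in counts_nonhotspot.items():
        if 1 <= codon <= length:
            track[codon] = k
    p0 = w / length
    threshold = -np.log10(thr.alpha)
    out = []
    window_sums = np.convolve(track[1:], np.ones(w), mode="valid")
    for i, kw in enumerate(window_sums):
        start = i + 1
        p = binomial_tail(int(kw), n_nonhotspot, p0) if n_nonhotspot else 1.0
        nlp = float(-np.log10(p)) if p > 0 else np.inf
        out.append(
            WindowEnrichment(
                start=start, end=start + w - 1, count=int(kw), p_value=p,
                neglog10_p=max(nlp, 0.0), significant=nlp > threshold,
            )
        )
    return out


def nonhotspot_counts(
    counts: dict[int, int],
    thr: ThresholdConfig | None = None,
    length: int = PTEN_LENGTH,
) -> dict[int, int]:
    """Two-pass helper: drop codons that are significant hotspots in the
    same cohort, leaving the non-hotspot mutation track."""
    calls = call_codon_hotspots(counts, length=length, thr=thr)
    hot = {c.codon for c in calls if c.significant}
    return {codon: k for codon, k in counts.items() if codon not in hot}


def significance_threshold_neglog10(alpha: float = 0.005) -> float:
    """The window-track significance threshold on the -log10 scale."""
    return float(-np.log10(alpha))


def saturation_curve(
    variants: list[VariantRecord],
    sizes: list[int],
    reps: int = 20,
    seed: int = 0,
    length: int = PTEN_LENGTH,
    thr: ThresholdConfig | None = None,
) -> dict[int, float]:
    """Expected significant-hotspot count under mutation subsampling.

    For each subsample size, draws ``reps`` subsets of mutations without
    replacement, calls hotspots on each, and averages the number of
    significant codons — an estimate of how hotspot discovery scales with
    cohort size.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    eligible = [
        v for v in variants
        if v.codon is not None and v.variant_class not in NO_CODON_CLASSES
    ]
    codons = np.array([v.codon for v in eligible])
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for size in sizes:
        if size > len(codons):
            raise ValueError(f"subsample size {size} exceeds {len(codons)} mutations")
        if size == 0:
            out[0] = 0.0
            continue
        tot = 0
        for _ in range(reps):
            sub = rng.choice(codons, size=size, replace=False)
            vals, cnts = np.unique(sub, return_counts=True)
            calls = call_codon_hotspots(
                dict(zip(vals.tolist(), cnts.tolist())), length=length, thr=thr
            )
            tot += sum(c.significant for c in calls)
        out[size] = tot / reps
    return out
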