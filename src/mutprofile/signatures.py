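"""Mutational-signature compatibility labeling.

Single-base substitutions are classified into the 96 pyrimidine-centric
trinucleotide channels used by COSMIC SBS signatures.  A mutation is
"compatible" with a signature when its channel carries at least a fraction
theta (default 0.05) of that signature's probability mass; 1-bp insertions or
deletions in homopolymer runs of length >= 4 are compatible with the grouped
homopolymer-indel signatures ID1/ID2/ID5/ID7, designated IDT.

Labels are per-mutation compatibility calls with a fixed biological-context
priority (POLE-associated signatures in POLE-mutant samples, then
MMR-deficiency signatures in hypermutated MSI-like tumors, then clock-like
SBS1, then IDT, else "other") -- not a fitted signature deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mutprofile.datamodel import (
    NO_CODON_CLASSES,
    SampleRecord,
    ThresholdConfig,
    VariantRecord,
)

PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: canonical COSMIC ordering of the 96 channels
CHANNELS: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}"
    for sub in PYRIMIDINE_SUBS
    for f5 in BASES
    for f3 in BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

#: homopolymer-indel signatures grouped as "IDT" (total)
IDT_SIGNATURES = frozenset({"ID1", "ID2", "ID5", "ID7"})
POLE_SIGNATURES = ("SBS10a", "SBS10b", "SBS28")


def snv_channel(ref: str, alt: str, context5: str, context3: str) -> str:
    """The 96-channel label of an SNV, normalized to a pyrimidine reference.

    If the reference base is a purine, all four bases are reverse-complemented
    (the 5' and 3' contexts swap) before classification, so the operation is
    idempotent on already-normalized input.
    """
    bases = (ref, alt, context5, context3)
    for b in bases:
        if b not in _COMPLEMENT:
            raise ValueError(f"ambiguous or invalid base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt bases are identical")
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context5, context3 = _COMPLEMENT[context3], _COMPLEMENT[context5]
    return f"{context5}[{ref}>{alt}]{context3}"


def homopolymer_run(cds: str, position: int, base: str) -> int:
    """Length of the maximal run of ``base`` containing 0-based ``position``.

    ``position`` addresses the run site in the reference coding sequence; for
    a 1-bp deletion it is the deleted base, for an insertion the reference
    base at the insertion point.
    """
    if not 0 <= position < len(cds):
        raise ValueError(f"position {position} outside sequence of length {len(cds)}")
    if cds[position] != base:
        return 0
    lo = position
    while lo > 0 and cds[lo - 1] == base:
        lo -= 1
    hi = position
    while hi + 1 < len(cds) and cds[hi + 1] == base:
        hi += 1
    return hi - lo + 1


@dataclass
class SignatureCatalog:
    """Per-signature 96-channel probability vectors plus indel-signature ids.

    ``probabilities`` is a DataFrame indexed by the 96 channel labels in
    canonical order, one column per SBS signature.  Each column sums to 1
    within 1e-6.
    """

    probabilities: pd.DataFrame
    id_signatures: frozenset = IDT_SIGNATURES
    theta: float = 0.05

    def __post_init__(self) -> None:
        probs = self.probabilities
        if list(probs.index) != list(CHANNELS):
            if set(probs.index) != set(CHANNELS):
                bad = sorted(set(probs.index) - set(CHANNELS))[:5]
                raise ValueError(f"unknown channel labels, e.g. {bad}")
            self.probabilities = probs = probs.loc[list(CHANNELS)]
        if (probs.values < 0).any():
            raise ValueError("negative channel probability")
        sums = probs.sum(axis=0)
        off = sums[(sums - 1.0).abs() > 1e-6]
        if len(off):
            raise ValueError(
                f"signature vectors must sum to 1 +/- 1e-6; offending: "
                f"{dict(off.round(4))}"
            )

    @property
    def signature_ids(self) -> list[str]:
        return list(self.probabilities.columns)

    def probability(self, signature: str, channel: str) -> float:
        return float(self.probabilities.at[channel, signature])

    def frequent_channels(self, signature: str) -> list[str]:
        """Channels carrying probability >= theta within ``signature``."""
        col = self.probabilities[signature]
        return list(col.index[col >= self.theta])

    def compatible(self, signature: str, channel: str) -> bool:
        return self.probability(signature, channel) >= self.theta


def read_signature_catalog(path, theta: float = 0.05) -> SignatureCatalog:
    """Read a COSMIC v3.1-layout SBS signature table.

    Expected layout: tab-separated, first column the 96 channel labels
    (``A[C>A]A`` style, any order), one column per signature.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise ValueError(f"expected 96 channel rows, found {df.shape[0]}")
    return SignatureCatalog(probabilities=df.astype(float), theta=theta)


def write_signature_catalog(catalog: SignatureCatalog, path) -> None:
    catalog.probabilities.to_csv(path, sep="\t", index_label="Type")


def _peaked(channels: dict[str, float]) -> np.ndarray:
    """A 96-vector with the given channel masses, remainder spread uniformly."""
    v = np.full(96, 0.0)
    for ch, p in channels.items():
        v[_CHANNEL_INDEX[ch]] = p
    rest = 1.0 - v.sum()
    if rest < -1e-12:
        raise ValueError("channel masses exceed 1")
    v += rest / 96.0
    return v / v.sum()


def toy_signature_catalog(theta: float = 0.05) -> SignatureCatalog:
    """A compact synthetic SBS catalog for simulation and tests.

    The vectors are stylized versions of the signatures active in colorectal
    cancer: SBS1 (5-methylcytosine deamination, C>T at NpCpG), the
    POLE-exonuclease signatures SBS10a (T[C>A]T dominant), SBS10b (T[C>T]T
    dominant) and SBS28 (T[T>G]T dominant), the MMR-deficiency signature
    SBS44, and a flat background SBS5-like component.  They are synthetic
    stand-ins, not COSMIC's measured vectors.
    """
    sbs1 = _peaked({f"{f5}[C>T]G": 0.22 for f5 in BASES})
    sbs10a = _peaked({"T[C>A]T": 0.45, "T[C>A]A": 0.15, "C[C>A]T": 0.10})
    sbs10b = _peaked({"T[C>T]T": 0.40, "G[C>T]T": 0.15, "C[C>T]T": 0.10})
    sbs28 = _peaked({"T[T>G]T": 0.55, "C[T>G]T": 0.10})
    sbs44 = _peaked({"C[C>T]T": 0.20, "C[C>T]C": 0.15, "A[C>T]T": 0.12})
    sbs5 = _peaked({})
    probs = pd.DataFrame(
        {
            "SBS1": sbs1,
            "SBS10a": sbs10a,
            "SBS10b": sbs10b,
            "SBS28": sbs28,
            "SBS44": sbs44,
            "SBS5": sbs5,
        },
        index=list(CHANNELS),
    )
    return SignatureCatalog(probabilities=probs, theta=theta)


def indel_idt_eligible(
    variant: VariantRecord, cds: str | None, min_run: int
) -> bool:
    """Whether a variant is a 1-bp homopolymer indel eligible for IDT.

    Eligibility requires |indel_len| == 1 and a run of the inserted/deleted
    base of length >= ``min_run``.  When the coding sequence is unavailable
    the run length cannot be recomputed; generated variants carry the run in
    their cDNA description and are handled by the caller.
    """
    if abs(variant.indel_len) != 1 or variant.ref_base is None:
        return False
    if cds is None:
        return False
    pos = _cds_position(variant)
    if pos is None or not 0 <= pos < len(cds):
        return False
    return homopolymer_run(cds, pos, variant.ref_base) >= min_run


_CDNA_POS_PREFIXES = ("c.",)


def _cds_position(variant: VariantRecord) -> int | None:
    """0-based CDS position parsed from an hgvs_c like ``c.389G>A`` or
    ``c.389delA``; ``None`` when unavailable."""
    h = variant.hgvs_c
    if not h or not h.startswith(_CDNA_POS_PREFIXES):
        return None
    digits = ""
    for ch in h[2:]:
        if ch.isdigit():
            digits += ch
        else:
            break
    return int(digits) - 1 if digits else None


def assign_signature(
    variant: VariantRecord,
    sample: SampleRecord,
    catalog: SignatureCatalog,
    thr: ThresholdConfig | None = None,
    cds: str | None = None,
) -> str:
    """Assign a signature-compatibility label to one mutation.

    Priority order (documented interpretation of context-priority matching):

    1. POLE-mutant sample and SNV compatible with SBS10a/SBS10b/SBS28 ->
       that signature (ties broken by highest channel probability);
    2. MT-H cohort sample: IDT-eligible indel -> ``IDT``; SNV compatible
       with SBS44 -> ``SBS44``;
    3. SNV compatible with SBS1 -> ``SBS1``;
    4. IDT-eligible indel in any cohort -> ``IDT``;
    5. otherwise ``other``.

    Non-point, non-indel classes (deletions, amplifications, rearrangements)
    are labeled ``not-applicable``.
    """
    thr = thr or ThresholdConfig()
    if variant.variant_class in NO_CODON_CLASSES:
        return "not-applicable"

    idt_ok = indel_idt_eligible(variant, cds, thr.homopolymer_min_run)

    channel = None
    if variant.is_snv:
        channel = snv_channel(
            variant.ref_base, variant.alt_base, variant.context5 or "N",
            variant.context3 or "N",
        ) if variant.context5 in BASES and variant.context3 in BASES else None

    if channel is not None and sample.pole_mutant:
        pole_hits = [
            s for s in POLE_SIGNATURES
            if s in catalog.signature_ids and catalog.compatible(s, channel)
        ]
        if pole_hits:
            return max(pole_hits, key=lambda s: catalog.probability(s, channel))

    if sample.cohort == "MT-H":
        if idt_ok:
            return "IDT"
        if (
            channel is not None
            and "SBS44" in catalog.signature_ids
            and catalog.compatible("SBS44", channel)
        ):
            return "SBS44"

    if channel is not None and "SBS1" in catalog.signature_ids:
        if catalog.compatible("SBS1", channel):
            return "SBS1"

    if idt_ok:
        return "IDT"
    return "other"


def label_variants(
    variants: list[VariantRecord],
    samples: list[SampleRecord],
    catalog: SignatureCatalog,
    thr: ThresholdConfig | None = None,
    cds: str | None = None,
) -> list[VariantRecord]:
    """Assign ``signature_label`` in place for every variant; returns input."""
    by_id = {s.sample_id: s for s in samples}
    for v in variants:
        sample = by_id.get(v.sample_id)
        if sample is None:
            raise ValueError(f"variant for unknown sample {v.sample_id!r}")
        v.signature_label = assign_signature(v, sample, catalog, thr, cds)
    return variants
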