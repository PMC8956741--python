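"""Synthetic CRC cohort generator with full ground truth.

Generates labeled sample tables (cohort, MSI status, bimodal TMB, age, sex,
subsite, POLE status), PTEN variant tables (planted hotspots plus
signature-driven background SNVs and homopolymer indels over a toy coding
sequence), allele copy numbers realizing configured LOH probabilities, and
co-mutation indicators for APC/KRAS/TP53/SMAD4/PIK3CA drawn from 2x2
distributions with configured marginal rates and odds ratios.

Defaults emulate the published composition of a large CRC profiling cohort:
cohort shares ~0.945/0.047/0.007 (MT-L/MT-H/MSS-htmb), TMB log-normal with
medians ~4 and ~50 mut/Mb, cohort median ages 59/64/55, PTEN alteration
prevalences 7.6%/25%/45%, deletion shares 41%/0%/2%, and signature mixtures
dominated by unattributable background in MT-L, homopolymer indels (IDT) in
MT-H, and POLE signatures in MSS-htmb.  Every stochastic choice is recorded
in a :class:`TruthBundle` so recovery tests can compare estimate to truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from mutprofile.datamodel import SampleRecord, VariantRecord
from mutprofile.io import ensure_dir, write_samples, write_variants
from mutprofile.signatures import (
    BASES,
    CHANNELS,
    SignatureCatalog,
    toy_signature_catalog,
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]

COHORT_NAMES = ("MT-L", "MT-H", "MSS-htmb")


class ConfigError(ValueError):
    """Infeasible or inconsistent generator configuration."""


def _translate(codon: str) -> str:
    """One-letter amino acid, '*' for stop."""
    if codon in _CODON_TABLE.stop_codons:
        return "*"
    return _CODON_TABLE.forward_table[codon]


@dataclass
class PlantedHotspot:
    codon: int
    variant_class: str       # missense | nonsense | frameshift
    share: float             # fraction of point mutations placed here


@dataclass
class GeneratorConfig:
    n_samples: int = 2000
    cohort_shares: dict = field(default_factory=lambda: {
        "MT-L": 0.9446, "MT-H": 0.0483, "MSS-htmb": 0.0071,
    })
    # log-normal TMB: (median, sigma, lower bound, upper bound)
    tmb_params: dict = field(default_factory=lambda: {
        "MT-L": (4.0, 0.8, 0.0, 16.0),
        "MT-H": (50.0, 0.45, 16.0, 100.0),
        "MSS-htmb": (30.0, 0.5, 16.0, 300.0),
    })
    # normal age: (median, sd)
    age_params: dict = field(default_factory=lambda: {
        "MT-L": (59.0, 12.9), "MT-H": (64.0, 12.9), "MSS-htmb": (55.0, 12.9),
    })
    male_fraction: float = 0.55
    colon_fraction: float = 0.84
    # fraction of samples annotated (vs TMB-only) for MSI status
    annotated_fraction: float = 0.9
    pole_fraction: dict = field(default_factory=lambda: {
        "MT-L": 0.01, "MT-H": 0.05, "MSS-htmb": 0.54,
    })
    # PTEN alteration prevalence per cohort; Poisson event rate is
    # lambda = -ln(1 - prevalence) so P(>=1 event) matches the prevalence
    pten_prevalence: dict = field(default_factory=lambda: {
        "MT-L": 0.0756, "MT-H": 0.2495, "MSS-htmb": 0.4527,
    })
    # share of alteration events that are deep deletions
    deletion_share: dict = field(default_factory=lambda: {
        "MT-L": 0.41, "MT-H": 0.0, "MSS-htmb": 0.02,
    })
    planted_hotspots: list = field(default_factory=lambda: [
        PlantedHotspot(130, "missense", 0.07),
        PlantedHotspot(130, "nonsense", 0.05),
        PlantedHotspot(173, "missense", 0.06),
        PlantedHotspot(233, "nonsense", 0.06),
        PlantedHotspot(319, "frameshift", 0.04),
    ])
    # per-cohort mixture over signature processes for background mutations;
    # "POLE" splits evenly over SBS10a/SBS10b/SBS28 and applies only in
    # POLE-mutant samples (its mass is redistributed to "other" elsewhere)
    signature_mixture: dict = field(default_factory=lambda: {
        "MT-L": {"SBS1": 0.15, "IDT": 0.05, "POLE": 0.02, "SBS44": 0.03,
                 "other": 0.75},
        "MT-H": {"SBS1": 0.15, "IDT": 0.51, "POLE": 0.0, "SBS44": 0.10,
                 "other": 0.24},
        "MSS-htmb": {"SBS1": 0.12, "IDT": 0.0, "POLE": 0.60, "SBS44": 0.0,
                     "other": 0.28},
    })
    loh_probability: dict = field(default_factory=lambda: {
        "MT-L": 0.60, "MT-H": 0.15, "MSS-htmb": 0.10,
    })
    # partner-gene marginal mutation rates and odds ratios vs PTEN status
    comutation_rates: dict = field(default_factory=lambda: {
        "APC": 0.79, "KRAS": 0.51, "TP53": 0.77, "SMAD4": 0.21,
        "PIK3CA": 0.195,
    })
    comutation_odds_ratios: dict = field(default_factory=lambda: {
        "APC": 1.3, "KRAS": 1.5, "TP53": 0.5, "SMAD4": 1.5, "PIK3CA": 2.0,
    })
    homopolymer_min_run: int = 4
    rng_seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.cohort_shares.values()) - 1.0) > 1e-6:
            raise ConfigError("cohort shares must sum to 1")
        for c, (m, s, lo, hi) in self.tmb_params.items():
            if not lo < m < hi and not (lo <= m):
                raise ConfigError(f"TMB distribution for {c} infeasible")
        if self.tmb_params["MSS-htmb"][3] <= 16.0:
            raise ConfigError("MSS-htmb TMB mass must reach >= 16")
        hs_share = sum(h.share for h in self.planted_hotspots)
        if hs_share > 1.0:
            raise ConfigError("planted hotspot shares exceed 1")
        for c, mix in self.signature_mixture.items():
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ConfigError(f"signature mixture for {c} must sum to 1")
        for g, r in self.comutation_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"marginal rate for {g} outside [0,1]")
        for g, or_ in self.comutation_odds_ratios.items():
            if or_ <= 0:
                raise ConfigError(f"odds ratio for {g} must be positive")


@dataclass
class TruthBundle:
    """Ground truth of one generated cohort."""

    cohort_by_sample: dict = field(default_factory=dict)
    signature_by_variant: list = field(default_factory=list)
    planted_hotspot_codons: list = field(default_factory=list)
    loh_class_by_sample: dict = field(default_factory=dict)
    log_or_by_gene: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "cohort_by_sample": self.cohort_by_sample,
                "signature_by_variant": self.signature_by_variant,
                "planted_hotspot_codons": self.planted_hotspot_codons,
                "loh_class_by_sample": self.loh_class_by_sample,
                "log_or_by_gene": self.log_or_by_gene,
                "notes": self.notes,
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# Toy coding sequence
# ---------------------------------------------------------------------------

_CDS_SEED = 20220325  # fixed: the toy CDS is a study condition, not a dial


def toy_cds(n_codons: int = 403) -> str:
    """A deterministic 3*n_codons-nt toy coding sequence.

    Random sense codons with A- and T-homopolymer tracts embedded (runs of
    6) so that homopolymer-indel signatures have placement sites; no
    internal stop codons.  Not the real PTEN transcript — any analysis
    needing the real sequence can supply it by path.
    """
    rng = np.random.default_rng(_CDS_SEED)
    sense = sorted(set(_CODON_TABLE.forward_table) - set(_CODON_TABLE.stop_codons))
    codons = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
    codons[0] = "ATG"
    # embed homopolymer tracts: Lys-Lys (AAAAAA) and Phe-Phe (TTTTTT)
    for start in (40, 160, 290):
        codons[start] = codons[start + 1] = "AAA"
    for start in (90, 220, 350):
        codons[start] = codons[start + 1] = "TTT"
    # arginine CGA codons at the canonical hotspot positions support both
    # missense (CGA>CAA, R>Q) and nonsense (CGA>TGA) single-base changes
    for hotspot_codon in (130, 173, 233):
        if hotspot_codon <= n_codons:
            codons[hotspot_codon - 1] = "CGA"
    if n_codons >= 319:
        codons[318] = "ACT"  # Thr at the frameshift hotspot
    return "".join(codons)


def _channel_site_index(cds: str) -> dict[str, list[tuple[int, str]]]:
    """Map each of the 96 channels to its (position, strand) match sites.

    A site is a CDS position 1..L-2 (0-based) whose trinucleotide context
    matches the channel on the coding (``+``) or reverse-complement (``-``)
    strand.
    """
    index: dict[str, list[tuple[int, str]]] = {c: [] for c in CHANNELS}
    L = len(cds)
    for i in range(1, L - 1):
        ref = cds[i]
        f5, f3 = cds[i - 1], cds[i + 1]
        if ref in ("C", "T"):
            for alt in BASES:
                if alt == ref:
                    continue
                index[f"{f5}[{ref}>{alt}]{f3}"].append((i, "+"))
        else:
            rc_ref = _COMPLEMENT[ref]
            rc5, rc3 = _COMPLEMENT[f3], _COMPLEMENT[f5]
            for rc_alt in BASES:
                if rc_alt == rc_ref:
                    continue
                index[f"{rc5}[{rc_ref}>{rc_alt}]{rc3}"].append((i, "-"))
    return index


def _homopolymer_runs(cds: str, min_run: int) -> list[tuple[int, int, str]]:
    """(start, length, base) of maximal runs with length >= min_run."""
    runs = []
    i = 0
    while i < len(cds):
        j = i
        while j + 1 < len(cds) and cds[j + 1] == cds[i]:
            j += 1
        if j - i + 1 >= min_run:
            runs.append((i, j - i + 1, cds[i]))
        i = j + 1
    return runs


def solve_2x2(p1: float, p2: float, odds_ratio: float) -> float:
    """The joint probability p11 with given marginals and odds ratio.

    Plackett's solution: for psi != 1,
    p11 = (S - sqrt(S^2 - 4 psi (psi - 1) p1 p2)) / (2 (psi - 1))
    with S = 1 + (p1 + p2)(psi - 1); for psi = 1, p11 = p1 p2.
    """
    psi = odds_ratio
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ConfigError("marginals must lie in [0,1]")
    if psi <= 0:
        raise ConfigError("odds ratio must be positive")
    if abs(psi - 1.0) < 1e-12:
        return p1 * p2
    S = 1.0 + (p1 + p2) * (psi - 1.0)
    disc = S * S - 4.0 * psi * (psi - 1.0) * p1 * p2
    if disc < 0:
        raise ConfigError("infeasible (marginals, odds ratio) pair")
    p11 = (S - math.sqrt(disc)) / (2.0 * (psi - 1.0))
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if not lo - 1e-9 <= p11 <= hi + 1e-9:
        raise ConfigError("infeasible (marginals, odds ratio) pair")
    return min(max(p11, lo), hi)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Seed-stream splitting: one independent stream per named stage."""
    import zlib

    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# Samples
# ---------------------------------------------------------------------------

def _truncated_lognormal(
    rng, median: float, sigma: float, lo: float, hi: float, size: int
) -> np.ndarray:
    mu = math.log(median)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mu, sigma, size=max(size - filled, 16) * 4)
        ok = draw[(draw >= lo) & (draw < hi)]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
        if len(ok) == 0 and sigma == 0:
            raise ConfigError("empty truncation region for TMB distribution")
    return out


def generate_samples(
    cfg: GeneratorConfig, seed: int | None = None
) -> tuple[list[SampleRecord], TruthBundle]:
    """Draw the sample table; deterministic for fixed config and seed."""
    cfg.validate()
    seed = cfg.rng_seed if seed is None else seed
    rng = _stage_rng(seed, "samples")
    truth = TruthBundle()
    shares = np.array([cfg.cohort_shares[c] for c in COHORT_NAMES])
    n_per = rng.multinomial(cfg.n_samples, shares / shares.sum())

    samples: list[SampleRecord] = []
    idx = 0
    for cohort, n in zip(COHORT_NAMES, n_per):
        if n == 0:
            continue
        median, sigma, lo, hi = cfg.tmb_params[cohort]
        tmb = _truncated_lognormal(rng, median, sigma, lo, hi, n)
        age_med, age_sd = cfg.age_params[cohort]
        ages = np.clip(np.round(rng.normal(age_med, age_sd, n)), 18, 95)
        sexes = np.where(rng.random(n) < cfg.male_fraction, "M", "F")
        subsites = np.where(rng.random(n) < cfg.colon_fraction, "colon", "rectum")
        annotated = rng.random(n) < cfg.annotated_fraction
        pole = rng.random(n) < cfg.pole_fraction[cohort]
        for i in range(n):
            sid = f"S{idx:06d}"
            idx += 1
            if cohort == "MT-H":
                msi = "MSI-H" if annotated[i] else "unknown"
            elif cohort == "MSS-htmb":
                msi = "MSS"   # this cohort is defined by an MSS annotation
            else:
                msi = "MSS" if annotated[i] else "unknown"
            s = SampleRecord(
                sample_id=sid, msi_status=msi, tmb=float(round(tmb[i], 2)),
                age=int(ages[i]), sex=str(sexes[i]), subsite=str(subsites[i]),
                pole_mutant=bool(pole[i]), cohort="unassigned",
            )
            s.validate()
            samples.append(s)
            truth.cohort_by_sample[sid] = cohort
    return samples, truth


# ---------------------------------------------------------------------------
# PTEN mutations
# ---------------------------------------------------------------------------

def _snv_record(
    sample_id: str, cds: str, pos: int, strand: str, channel: str
) -> VariantRecord | None:
    """Build an SNV record at 0-based CDS position ``pos``; None if silent."""
    inner = channel[2:5]          # e.g. "C>T"
    ch_ref, ch_alt = inner[0], inner[2]
    if strand == "+":
        ref, alt = ch_ref, ch_alt
    else:
        ref, alt = _COMPLEMENT[ch_ref], _COMPLEMENT[ch_alt]
    codon_idx = pos // 3
    codon = cds[codon_idx * 3: codon_idx * 3 + 3]
    off = pos - codon_idx * 3
    alt_codon = codon[:off] + alt + codon[off + 1:]
    aa_ref, aa_alt = _translate(codon), _translate(alt_codon)
    if aa_ref == aa_alt:
        return None
    vclass = "nonsense" if aa_alt == "*" else "missense"
    return VariantRecord(
        sample_id=sample_id, gene="PTEN", variant_class=vclass,
        hgvs_c=f"c.{pos + 1}{ref}>{alt}",
        hgvs_p=f"p.{aa_ref}{codon_idx + 1}{aa_alt if aa_alt != '*' else '*'}",
        codon=codon_idx + 1, ref_base=ref, alt_base=alt,
        context5=cds[pos - 1] if pos > 0 else None,
        context3=cds[pos + 1] if pos + 1 < len(cds) else None,
    )


def _hotspot_record(
    sample_id: str, cds: str, hs: PlantedHotspot, rng
) -> VariantRecord:
    codon_idx = hs.codon - 1
    if hs.variant_class == "frameshift":
        pos = codon_idx * 3
        return VariantRecord(
            sample_id=sample_id, gene="PTEN", variant_class="frameshift",
            hgvs_c=f"c.{pos + 1}del",
            hgvs_p=f"p.{_translate(cds[pos:pos + 3])}{hs.codon}fs",
            codon=hs.codon, ref_base=cds[pos], alt_base=None, indel_len=-1,
            context5=cds[pos - 1] if pos > 0 else None,
            context3=cds[pos + 1] if pos + 1 < len(cds) else None,
        )
    # enumerate all single-base substitutions at the codon with the wanted
    # consequence, draw one uniformly
    options = []
    codon = cds[codon_idx * 3: codon_idx * 3 + 3]
    for off in range(3):
        pos = codon_idx * 3 + off
        ref = cds[pos]
        for alt in BASES:
            if alt == ref:
                continue
            alt_codon = codon[:off] + alt + codon[off + 1:]
            aa_ref, aa_alt = _translate(codon), _translate(alt_codon)
            want = "nonsense" if hs.variant_class == "nonsense" else "missense"
            got = (
                "nonsense" if aa_alt == "*"
                else "silent" if aa_alt == aa_ref else "missense"
            )
            if got == want:
                options.append((pos, ref, alt, aa_ref, aa_alt))
    if not options:
        raise ConfigError(
            f"no single-base change at codon {hs.codon} yields "
            f"{hs.variant_class} on the supplied CDS"
        )
    pos, ref, alt, aa_ref, aa_alt = options[rng.integers(len(options))]
    return VariantRecord(
        sample_id=sample_id, gene="PTEN", variant_class=hs.variant_class,
        hgvs_c=f"c.{pos + 1}{ref}>{alt}",
        hgvs_p=f"p.{aa_ref}{hs.codon}{aa_alt}",
        codon=hs.codon, ref_base=ref, alt_base=alt,
        context5=cds[pos - 1] if pos > 0 else None,
        context3=cds[pos + 1] if pos + 1 < len(cds) else None,
    )


def generate_pten_mutations(
    samples: list[SampleRecord],
    cfg: GeneratorConfig,
    truth: TruthBundle,
    catalog: SignatureCatalog | None = None,
    cds: str | None = None,
    seed: int | None = None,
) -> list[VariantRecord]:
    """Draw PTEN alteration events for every sample.

    Event counts are Poisson with rate -ln(1 - prevalence); each event is a
    deep deletion (configured share), a planted hotspot (configured shares
    of point events), or a background mutation from the cohort's signature
    mixture: IDT events are 1-bp deletions in homopolymer runs, SNVs sample
    a channel proportional to signature probability times the count of
    matching trinucleotides in the CDS.
    """
    cfg.validate()
    seed = cfg.rng_seed if seed is None else seed
    rng = _stage_rng(seed, "mutations")
    catalog = catalog or toy_signature_catalog()
    cds = cds or toy_cds()
    site_index = _channel_site_index(cds)
    runs = _homopolymer_runs(cds, cfg.homopolymer_min_run)
    needs_idt = any(
        mix.get("IDT", 0) > 0 for mix in cfg.signature_mixture.values()
    )
    if needs_idt and not runs:
        raise ConfigError(
            f"CDS has no homopolymer run >= {cfg.homopolymer_min_run} "
            "for IDT placement"
        )
    sig_vec = {s: catalog.probabilities[s].to_numpy()
               for s in catalog.signature_ids}
    site_counts = np.array([len(site_index[c]) for c in CHANNELS], dtype=float)

    hs_total = sum(h.share for h in cfg.planted_hotspots)
    hs_probs = (
        np.array([h.share for h in cfg.planted_hotspots]) / hs_total
        if hs_total > 0 else None
    )
    truth.planted_hotspot_codons = sorted(
        {h.codon for h in cfg.planted_hotspots}
    )

    pole_members = {"SBS10a", "SBS10b", "SBS28"}

    variants: list[VariantRecord] = []
    for s in samples:
        cohort = truth.cohort_by_sample[s.sample_id]
        prev = cfg.pten_prevalence[cohort]
        lam = -math.log(1.0 - prev) if prev < 1.0 else 10.0
        n_events = rng.poisson(lam)
        if n_events == 0:
            continue
        mix = dict(cfg.signature_mixture[cohort])
        if not s.pole_mutant:
            # POLE signatures operate only in POLE-mutant tumors
            mix["other"] = mix.get("other", 0.0) + mix.pop("POLE", 0.0)
        mix_names = list(mix)
        mix_p = np.array([mix[m] for m in mix_names])
        mix_p = mix_p / mix_p.sum()
        for _ in range(n_events):
            if rng.random() < cfg.deletion_share[cohort]:
                variants.append(VariantRecord(
                    sample_id=s.sample_id, gene="PTEN",
                    variant_class="deep_deletion",
                ))
                truth.signature_by_variant.append("deletion")
                continue
            if hs_probs is not None and rng.random() < hs_total:
                hs = cfg.planted_hotspots[rng.choice(len(hs_probs), p=hs_probs)]
                variants.append(_hotspot_record(s.sample_id, cds, hs, rng))
                truth.signature_by_variant.append("hotspot")
                continue
            proc = mix_names[rng.choice(len(mix_p), p=mix_p)]
            if proc == "IDT":
                start, length, base = runs[rng.integers(len(runs))]
                pos = start + int(rng.integers(length))
                variants.append(VariantRecord(
                    sample_id=s.sample_id, gene="PTEN",
                    variant_class="frameshift",
                    hgvs_c=f"c.{pos + 1}del",
                    hgvs_p=f"p.{_translate(cds[(pos // 3) * 3:(pos // 3) * 3 + 3])}"
                           f"{pos // 3 + 1}fs",
                    codon=pos // 3 + 1, ref_base=base, alt_base=None,
                    indel_len=-1,
                    context5=cds[pos - 1] if pos > 0 else None,
                    context3=cds[pos + 1] if pos + 1 < len(cds) else None,
                ))
                truth.signature_by_variant.append("IDT")
                continue
            if proc == "POLE":
                sig = ("SBS10a", "SBS10b", "SBS28")[rng.integers(3)]
            elif proc == "other":
                sig = "SBS5"
            else:
                sig = proc
            weights = sig_vec[sig] * site_counts
            tot = weights.sum()
            if tot <= 0:
                missing = [
                    CHANNELS[i] for i in np.nonzero(sig_vec[sig] > 0)[0]
                    if site_counts[i] == 0
                ]
                raise ConfigError(
                    f"CDS lacks sites for channels of {sig}: {missing[:5]}"
                )
            rec = None
            for _attempt in range(50):   # reject silent changes
                ch_i = rng.choice(96, p=weights / tot)
                sites = site_index[CHANNELS[ch_i]]
                pos, strand = sites[rng.integers(len(sites))]
                rec = _snv_record(s.sample_id, cds, pos, strand, CHANNELS[ch_i])
                if rec is not None:
                    break
            if rec is None:
                continue
            variants.append(rec)
            truth.signature_by_variant.append(proc)
    return variants


# ---------------------------------------------------------------------------
# Copy number / LOH
# ---------------------------------------------------------------------------

def generate_copy_number(
    variants: list[VariantRecord],
    cfg: GeneratorConfig,
    truth: TruthBundle,
    seed: int | None = None,
) -> list[VariantRecord]:
    """Fill mut_allele_cn/total_cn per sample realizing the LOH probability.

    Samples with >= 2 distinct point mutations are the multi-mutation class
    (each allele at copy number 1 of total 2); single-mutation samples lose
    the wild-type allele with the cohort's LOH probability.
    """
    cfg.validate()
    seed = cfg.rng_seed if seed is None else seed
    rng = _stage_rng(seed, "copynumber")
    by_sample: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if v.gene == "PTEN" and v.variant_class not in (
            "deep_deletion", "amplification", "rearrangement"
        ):
            by_sample.setdefault(v.sample_id, []).append(v)
    for sid, muts in by_sample.items():
        cohort = truth.cohort_by_sample[sid]
        distinct = {(m.hgvs_c, m.hgvs_p) for m in muts}
        if len(distinct) >= 2:
            cls = "multi_mut"
            for m in muts:
                m.mut_allele_cn, m.total_cn = 1, 2
        elif rng.random() < cfg.loh_probability[cohort]:
            cls = "mut_only"
            for m in muts:
                m.mut_allele_cn, m.total_cn = 1, 1
        else:
            cls = "mut_plus_wt"
            for m in muts:
                m.mut_allele_cn, m.total_cn = 1, 2
        truth.loh_class_by_sample[sid] = cls
    return variants


# ---------------------------------------------------------------------------
# Co-mutations
# ---------------------------------------------------------------------------

def generate_comutations(
    samples: list[SampleRecord],
    variants: list[VariantRecord],
    cfg: GeneratorConfig,
    truth: TruthBundle,
    seed: int | None = None,
) -> list[VariantRecord]:
    """Partner-gene mutation indicators with configured marginals and ORs.

    For each gene the joint cell probability p11 is solved from the
    (marginal, odds ratio) pair against the cohort's configured PTEN
    prevalence; gene status is then drawn from the conditional probabilities
    given the sample's realized PTEN status.
    """
    cfg.validate()
    seed = cfg.rng_seed if seed is None else seed
    rng = _stage_rng(seed, "comutations")
    pten_pos = {v.sample_id for v in variants if v.gene == "PTEN"}
    out: list[VariantRecord] = []
    for gene in sorted(cfg.comutation_rates):
        p2 = cfg.comutation_rates[gene]
        psi = cfg.comutation_odds_ratios[gene]
        truth.log_or_by_gene[gene] = math.log(psi)
        if p2 == 0.0:
            continue
        for s in samples:
            cohort = truth.cohort_by_sample[s.sample_id]
            p1 = cfg.pten_prevalence[cohort]
            p11 = solve_2x2(p1, p2, psi)
            if s.sample_id in pten_pos:
                p_gene = p11 / p1 if p1 > 0 else p2
            else:
                p_gene = (p2 - p11) / (1.0 - p1) if p1 < 1 else p2
            if rng.random() < p_gene:
                out.append(VariantRecord(
                    sample_id=s.sample_id, gene=gene,
                    variant_class="missense",
                ))
    variants.extend(out)
    return variants


# ---------------------------------------------------------------------------
# One-call generation and fixture bundles
# ---------------------------------------------------------------------------

def generate_cohort(
    cfg: GeneratorConfig | None = None,
    seed: int | None = None,
    catalog: SignatureCatalog | None = None,
    cds: str | None = None,
) -> tuple[list[SampleRecord], list[VariantRecord], TruthBundle]:
    """Full generation pipeline: samples, PTEN mutations, copy number,
    co-mutations."""
    cfg = cfg or GeneratorConfig()
    samples, truth = generate_samples(cfg, seed)
    variants = generate_pten_mutations(samples, cfg, truth, catalog, cds, seed)
    generate_copy_number(variants, cfg, truth, seed)
    generate_comutations(samples, variants, cfg, truth, seed)
    return samples, variants, truth


def write_fixture_bundle(
    samples: list[SampleRecord],
    variants: list[VariantRecord],
    truth: TruthBundle,
    out_dir,
) -> dict[str, Path]:
    """Write samples.tsv / variants.tsv / truth.json into ``out_dir``."""
    d = ensure_dir(out_dir)
    paths = {
        "samples": d / "samples.tsv",
        "variants": d / "variants.tsv",
        "truth": d / "truth.json",
    }
    write_samples(samples, paths["samples"])
    write_variants(variants, paths["variants"])
    paths["truth"].write_text(truth.to_json())
    return paths
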