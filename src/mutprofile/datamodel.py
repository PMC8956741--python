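"""Domain types and the threshold registry.

Coordinates are protein residues, 1-based on the 403-aa PTEN protein; cDNA
positions follow the NM_000314 reference transcript; intervals are inclusive
on both ends.  Missing values are ``None`` in memory and empty fields on disk,
never numeric sentinels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from typing import Iterable

PTEN_LENGTH = 403

MSI_STATUSES = {"MSI-H", "MSS", "unknown"}
COHORTS = {"MT-L", "MT-H", "MSS-htmb", "excluded", "unassigned"}
VARIANT_CLASSES = {
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "splice",
    "deep_deletion",
    "amplification",
    "rearrangement",
}
#: classes with no single affected codon
NO_CODON_CLASSES = {"deep_deletion", "amplification", "rearrangement"}
#: protein-truncating point/indel classes
TRUNCATING_CLASSES = {"nonsense", "frameshift", "splice"}

_HGVS_P_RE = re.compile(r"p\.\(?(?:[A-Z][a-z]{2}|[A-Z*])(\d+)")


def parse_codon_from_hgvs_p(hgvs_p: str | None) -> int | None:
    """Extract the (first) affected codon number from an HGVS p. string.

    Handles one- and three-letter amino acid codes, e.g. ``p.R130Q``,
    ``p.Arg130Gln``, ``p.T319fs``, ``p.R233*``.  Returns ``None`` when the
    string is empty or carries no codon (splice-only annotations).
    """
    if not hgvs_p:
        return None
    m = _HGVS_P_RE.search(hgvs_p)
    return int(m.group(1)) if m else None


@dataclass
class SampleRecord:
    """One tumor/patient."""

    sample_id: str
    msi_status: str = "unknown"          # MSI-H | MSS | unknown
    tmb: float | None = None             # mutations per megabase
    age: int | None = None
    sex: str | None = None               # F | M | None
    subsite: str | None = None           # colon | rectum | None
    pole_mutant: bool = False
    cohort: str = "unassigned"

    def validate(self) -> None:
        if self.msi_status not in MSI_STATUSES:
            raise ValueError(f"invalid msi_status {self.msi_status!r}")
        if self.tmb is not None and self.tmb < 0:
            raise ValueError("tmb must be >= 0")
        if self.age is not None and self.age < 0:
            raise ValueError("age must be >= 0")
        if self.cohort not in COHORTS:
            raise ValueError(f"invalid cohort {self.cohort!r}")


@dataclass
class VariantRecord:
    """One alteration in PTEN or a co-mutated gene."""

    sample_id: str
    gene: str
    variant_class: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    codon: int | None = None
    ref_base: str | None = None
    alt_base: str | None = None
    context5: str | None = None
    context3: str | None = None
    indel_len: int = 0
    mut_allele_cn: int | None = None
    total_cn: int | None = None
    signature_label: str | None = None
    lof_call: str | None = None          # LoF | WT-like | NA

    def __post_init__(self) -> None:
        if self.codon is None and self.hgvs_p:
            self.codon = parse_codon_from_hgvs_p(self.hgvs_p)

    @property
    def is_snv(self) -> bool:
        return (
            self.ref_base is not None
            and self.alt_base is not None
            and self.indel_len == 0
            and self.variant_class not in NO_CODON_CLASSES
        )

    def validate(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"unknown variant_class {self.variant_class!r}; "
                f"allowed: {sorted(VARIANT_CLASSES)}"
            )
        if self.variant_class in NO_CODON_CLASSES and self.codon is not None:
            raise ValueError(f"{self.variant_class} must not carry a codon")
        if self.is_snv and self.ref_base == self.alt_base:
            raise ValueError("SNV with ref_base == alt_base")
        if (
            self.mut_allele_cn is not None
            and self.total_cn is not None
            and self.mut_allele_cn > self.total_cn
        ):
            raise ValueError("mut_allele_cn > total_cn")
        if self.codon is not None and not 1 <= self.codon <= PTEN_LENGTH:
            if self.gene == "PTEN":
                raise ValueError(f"PTEN codon {self.codon} outside 1..{PTEN_LENGTH}")


@dataclass(frozen=True)
class ThresholdConfig:
    """Registry of every tunable statistical threshold.

    Defaults follow the analysis conventions: a globally tightened
    significance level of 0.005 (in place of per-family multiple-testing
    correction), TMB cutpoints 16 and 100 mut/Mb for cohort assignment, a
    5-residue sliding window, a 5 angstrom all-atom contact distance, a 3%
    share for "strongly preferred" hotspots, count > 6 for recurrent sites,
    deep-mutational-scanning cuts of -1.1 (lipid phosphatase fitness) and
    0.4 (VAMP-seq abundance), and truncation considered damaging through
    codon 352.
    """

    alpha: float = 0.005
    tmb_low: float = 16.0
    tmb_very_high: float = 100.0
    window_len: int = 5
    contact_dist: float = 5.0
    major_hotspot_share: float = 0.03
    hotspot_min_count: int = 6
    lpa_cut: float = -1.1
    abundance_cut: float = 0.4
    trunc_last_codon: int = 352
    homopolymer_min_run: int = 4
    frequent_channel_theta: float = 0.05
    population_freq_max: float = 1e-5
    n_perm: int = 10000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in (
            "tmb_low", "tmb_very_high", "window_len", "contact_dist",
            "major_hotspot_share", "hotspot_min_count", "abundance_cut",
            "trunc_last_codon", "homopolymer_min_run",
            "frequent_channel_theta", "n_perm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# Domain / motif annotation of the PTEN protein
# ---------------------------------------------------------------------------

#: structural domains, residue intervals inclusive
DOMAINS = {
    "PBD": (6, 15),
    "phosphatase": (14, 185),
    "C2": (190, 350),
    "C-tail": (351, 403),
}

#: functional motifs and loops
MOTIFS = {
    "R-loop": (35, 49),
    "ATP-A": (60, 73),
    "WPD-loop": (88, 98),
    "P-loop": (123, 131),
    "ATP-B": (122, 136),
    "TI-loop": (160, 171),
    "M1": (169, 180),
    "M2": (250, 259),
    "CBR3": (260, 269),
    "M3": (264, 276),
    "internal-loop": (286, 309),
    "M4": (321, 334),
    "Calpha2": (321, 342),
    "PDZ-BD": (401, 403),
}

ACTIVE_SITE = frozenset({92, 93, 124, 125, 126, 129, 130, 171})


@dataclass(frozen=True)
class DomainMap:
    """Named residue intervals of PTEN; overlapping features are all returned."""

    domains: dict = field(default_factory=lambda: dict(DOMAINS))
    motifs: dict = field(default_factory=lambda: dict(MOTIFS))
    active_site: frozenset = ACTIVE_SITE
    length: int = PTEN_LENGTH

    def lookup(self, residue: int) -> set[str]:
        """Every domain/motif feature containing ``residue`` (1-based)."""
        if not 1 <= residue <= self.length:
            raise ValueError(f"residue {residue} outside 1..{self.length}")
        hits = {
            name
            for name, (lo, hi) in {**self.domains, **self.motifs}.items()
            if lo <= residue <= hi
        }
        if residue in self.active_site:
            hits.add("active-site")
        return hits

    def domain_of(self, residue: int) -> str | None:
        """The structural domain containing ``residue`` (first match in
        N-to-C order), or ``None`` for inter-domain residues."""
        if not 1 <= residue <= self.length:
            raise ValueError(f"residue {residue} outside 1..{self.length}")
        for name, (lo, hi) in self.domains.items():
            if lo <= residue <= hi:
                return name
        return None


def load_domain_annotation() -> DomainMap:
    """Bundled PTEN domain/motif annotation."""
    return DomainMap()


def check_unique_sample_ids(samples: Iterable[SampleRecord]) -> None:
    seen: set[str] = set()
    for s in samples:
        if s.sample_id in seen:
            raise ValueError(f"duplicate sample_id {s.sample_id!r}")
        seen.add(s.sample_id)
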