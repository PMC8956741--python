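"""Readers and writers for the tab-separated interchange formats.

Sample and variant tables are plain TSV with a header row; the variant table
is MAF-like (one alteration per row).  Missing values are empty fields.  All
readers validate the record invariants on ingest so downstream modules can
assume well-formed inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from mutprofile.datamodel import (
    SampleRecord,
    VariantRecord,
    check_unique_sample_ids,
)

SAMPLE_COLUMNS = [
    "sample_id", "msi_status", "tmb", "age", "sex", "subsite",
    "pole_mutant", "cohort",
]
VARIANT_COLUMNS = [
    "sample_id", "gene", "variant_class", "hgvs_c", "hgvs_p", "codon",
    "ref_base", "alt_base", "context5", "context3", "indel_len",
    "mut_allele_cn", "total_cn", "signature_label", "lof_call",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table missing required column(s): {missing}")


def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    try:
        return float(x)
    except (TypeError, ValueError):
        return None


def _opt_int(x) -> int | None:
    f = _opt_float(x)
    return int(f) if f is not None else None


def _opt_str(x) -> str | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    return str(x)


def read_samples(path) -> list[SampleRecord]:
    """Read a sample table; unparseable numerics become missing values."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["sample_id", "msi_status", "tmb"], "sample")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            SampleRecord(
                sample_id=str(d["sample_id"]),
                msi_status=_opt_str(d["msi_status"]) or "unknown",
                tmb=_opt_float(d["tmb"]),
                age=_opt_int(d.get("age")),
                sex=_opt_str(d.get("sex")),
                subsite=_opt_str(d.get("subsite")),
                pole_mutant=_opt_str(d.get("pole_mutant")) in ("True", "true", "1"),
                cohort=_opt_str(d.get("cohort")) or "unassigned",
            )
        )
    check_unique_sample_ids(records)
    for r in records:
        r.validate()
    return records


def write_samples(samples: list[SampleRecord], path) -> None:
    rows = []
    for s in samples:
        rows.append({
            "sample_id": s.sample_id,
            "msi_status": s.msi_status,
            "tmb": "" if s.tmb is None else s.tmb,
            "age": "" if s.age is None else s.age,
            "sex": s.sex or "",
            "subsite": s.subsite or "",
            "pole_mutant": s.pole_mutant,
            "cohort": s.cohort,
        })
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants(path) -> list[VariantRecord]:
    """Read a MAF-like variant table; codon is parsed from hgvs_p if absent."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["sample_id", "gene", "variant_class"], "variant")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        rec = VariantRecord(
            sample_id=str(d["sample_id"]),
            gene=str(d["gene"]),
            variant_class=str(d["variant_class"]),
            hgvs_c=_opt_str(d.get("hgvs_c")) or "",
            hgvs_p=_opt_str(d.get("hgvs_p")) or "",
            codon=_opt_int(d.get("codon")),
            ref_base=_opt_str(d.get("ref_base")),
            alt_base=_opt_str(d.get("alt_base")),
            context5=_opt_str(d.get("context5")),
            context3=_opt_str(d.get("context3")),
            indel_len=_opt_int(d.get("indel_len")) or 0,
            mut_allele_cn=_opt_int(d.get("mut_allele_cn")),
            total_cn=_opt_int(d.get("total_cn")),
            signature_label=_opt_str(d.get("signature_label")),
            lof_call=_opt_str(d.get("lof_call")),
        )
        rec.validate()
        records.append(rec)
    return records


def write_variants(variants: list[VariantRecord], path) -> None:
    rows = []
    for v in variants:
        rows.append({
            "sample_id": v.sample_id,
            "gene": v.gene,
            "variant_class": v.variant_class,
            "hgvs_c": v.hgvs_c,
            "hgvs_p": v.hgvs_p,
            "codon": "" if v.codon is None else v.codon,
            "ref_base": v.ref_base or "",
            "alt_base": v.alt_base or "",
            "context5": v.context5 or "",
            "context3": v.context3 or "",
            "indel_len": v.indel_len,
            "mut_allele_cn": "" if v.mut_allele_cn is None else v.mut_allele_cn,
            "total_cn": "" if v.total_cn is None else v.total_cn,
            "signature_label": v.signature_label or "",
            "lof_call": v.lof_call or "",
        })
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Function-score table (deep mutational scanning + clinical labels)
# ---------------------------------------------------------------------------

@dataclass
class FunctionScoreRow:
    key: tuple                       # (codon, alt_aa) or variant string
    lpa_score: float | None = None   # lipid-phosphatase fitness score
    abundance_score: float | None = None  # VAMP-seq score
    abundance_source: str = "missing"     # primary | secondary | missing
    clinical_label: str = "missing"       # damaging | benign | conflicting | missing
    dne_curated: bool = False
    population_freq: float | None = None

    @property
    def frequent_in_population(self) -> bool:
        return self.population_freq is not None and self.population_freq >= 1e-5


class FunctionScoreTable:
    """Per-substitution functional scores, keyed by (codon, alt amino acid).

    Secondary-source abundance scores are used only where the primary assay
    provides none, mirroring the gap-filling convention of the published
    abundance reanalysis.
    """

    def __init__(self, rows: list[FunctionScoreRow]):
        self._rows: dict[tuple, FunctionScoreRow] = {}
        for r in rows:
            if r.key in self._rows:
                raise ValueError(f"duplicate function-score key {r.key!r}")
            if r.abundance_source == "secondary" and r.abundance_score is None:
                raise ValueError(f"secondary source without score at {r.key!r}")
            self._rows[r.key] = r

    def __len__(self) -> int:
        return len(self._rows)

    def get(self, codon: int, alt_aa: str) -> FunctionScoreRow | None:
        return self._rows.get((codon, alt_aa))

    def rows(self) -> list[FunctionScoreRow]:
        return list(self._rows.values())


def read_function_scores(path) -> FunctionScoreTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["codon", "alt_aa"], "function-score")
    rows = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        lpa = _opt_float(d.get("lpa_score"))
        primary = _opt_float(d.get("abundance_score"))
        secondary = _opt_float(d.get("abundance_score_secondary"))
        if primary is not None:
            abundance, source = primary, "primary"
        elif secondary is not None:
            abundance, source = secondary, "secondary"
        else:
            abundance, source = None, "missing"
        rows.append(
            FunctionScoreRow(
                key=(int(d["codon"]), str(d["alt_aa"])),
                lpa_score=lpa,
                abundance_score=abundance,
                abundance_source=source,
                clinical_label=_opt_str(d.get("clinical_label")) or "missing",
                dne_curated=_opt_str(d.get("dne_curated")) in ("True", "true", "1"),
                population_freq=_opt_float(d.get("population_freq")),
            )
        )
    return FunctionScoreTable(rows)


def write_function_scores(table: FunctionScoreTable, path) -> None:
    rows = []
    for r in table.rows():
        rows.append({
            "codon": r.key[0],
            "alt_aa": r.key[1],
            "lpa_score": "" if r.lpa_score is None else r.lpa_score,
            "abundance_score": (
                r.abundance_score if r.abundance_source == "primary" else ""
            ),
            "abundance_score_secondary": (
                r.abundance_score if r.abundance_source == "secondary" else ""
            ),
            "clinical_label": r.clinical_label,
            "dne_curated": r.dne_curated,
            "population_freq": "" if r.population_freq is None else r.population_freq,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
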