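"""Reference summary counts from a large published CRC profiling cohort.

A comprehensive genomic-profiling series of 34,129 colorectal tumors
(access-restricted at the patient level; only summary counts are public)
provides the worked example for the cohort summarizer.  The constants below
are those published summary counts; :func:`build_reference_fixture` expands
them into in-memory sample/variant tables whose per-cohort margins realize
the counts exactly, so the summarizer's output can be checked against the
published percentages.
"""

from __future__ import annotations

from mutprofile.datamodel import SampleRecord, VariantRecord

#: overall cohort
TOTAL_SAMPLES = 34_129
TOTAL_PTEN_ALTERED = 2_966

#: per-analysis-cohort counts: n, n altered, n single-mutation, n multi-mutation
COHORT_COUNTS = {
    "MT-L": {"n": 32_233, "altered": 2_438, "single": 2_301, "multi": 137},
    "MT-H": {"n": 1_603, "altered": 400, "single": 211, "multi": 189},
    "MSS-htmb": {"n": 243, "altered": 110, "single": 43, "multi": 67},
}

#: clinical composition of the full series
COMPOSITION = {
    "subsite": {"colon": 28_582, "rectum": 5_547},
    "sex": {"F": 15_308, "M": 18_799},
    "msi": {"MSI-H": 1_443, "MSS": 29_442, "unknown": 3_244},
}


def build_reference_fixture() -> tuple[list[SampleRecord], list[VariantRecord]]:
    """Sample and variant tables realizing the published per-cohort counts.

    Samples are assigned cohorts directly (the stratification inputs behind
    the published assignment are not public); altered samples carry one or
    two generic PTEN missense records as needed for the single/multiple
    breakdown.  Intended for summary-level checks, not per-variant analyses.
    """
    samples: list[SampleRecord] = []
    variants: list[VariantRecord] = []
    idx = 0
    for cohort, c in COHORT_COUNTS.items():
        n, single, multi = c["n"], c["single"], c["multi"]
        assert single + multi == c["altered"]
        for i in range(n):
            sid = f"R{idx:06d}"
            idx += 1
            samples.append(SampleRecord(sample_id=sid, cohort=cohort))
            n_mut = 1 if i < single else 2 if i < single + multi else 0
            for j in range(n_mut):
                variants.append(VariantRecord(
                    sample_id=sid, gene="PTEN", variant_class="missense",
                    hgvs_p=f"p.R{130 + 43 * j}Q", codon=130 + 43 * j,
                ))
    # samples excluded from the analysis cohorts (very high TMB with unknown
    # MSI, or unevaluable) make up the remainder of the full series; the
    # altered count among them is the difference between the overall altered
    # total and the per-cohort altered sums
    altered_in_cohorts = sum(c["altered"] for c in COHORT_COUNTS.values())
    excluded_altered = TOTAL_PTEN_ALTERED - altered_in_cohorts
    while idx < TOTAL_SAMPLES:
        sid = f"R{idx:06d}"
        samples.append(SampleRecord(sample_id=sid, cohort="excluded"))
        if excluded_altered > 0:
            variants.append(VariantRecord(
                sample_id=sid, gene="PTEN", variant_class="missense",
                hgvs_p="p.R130Q", codon=130,
            ))
            excluded_altered -= 1
        idx += 1
    return samples, variants
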