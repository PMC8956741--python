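"""Domain types, parsing, domain annotation, and TSV round-trips."""

import pytest

from mutprofile.datamodel import (
    SampleRecord,
    ThresholdConfig,
    VariantRecord,
    load_domain_annotation,
    parse_codon_from_hgvs_p,
)
from mutprofile.io import (
    FormatError,
    FunctionScoreRow,
    FunctionScoreTable,
    read_function_scores,
    read_samples,
    read_variants,
    write_function_scores,
    write_samples,
    write_variants,
)
from mutprofile.signatures import (
    read_signature_catalog,
    toy_signature_catalog,
    write_signature_catalog,
)


@pytest.mark.parametrize("hgvs,codon", [
    ("p.R130Q", 130),
    ("p.T319fs", 319),
    ("p.R233*", 233),
    ("p.Arg130Gln", 130),
    ("p.(L70V)", 70),
    ("", None),
])
def test_hgvs_codon_parsing(hgvs, codon):
    assert parse_codon_from_hgvs_p(hgvs) == codon


def test_variant_codon_filled_from_hgvs():
    v = VariantRecord(sample_id="s", gene="PTEN", variant_class="missense",
                      hgvs_p="p.R130Q")
    assert v.codon == 130
    v2 = VariantRecord(sample_id="s", gene="PTEN",
                       variant_class="deep_deletion")
    assert v2.codon is None


def test_variant_invariants():
    with pytest.raises(ValueError, match="unknown variant_class"):
        VariantRecord(sample_id="s", gene="PTEN",
                      variant_class="nonsense_mediated").validate()
    with pytest.raises(ValueError, match="mut_allele_cn"):
        VariantRecord(sample_id="s", gene="PTEN", variant_class="missense",
                      codon=10, mut_allele_cn=3, total_cn=2).validate()
    with pytest.raises(ValueError, match="ref_base == alt_base"):
        VariantRecord(sample_id="s", gene="PTEN", variant_class="missense",
                      codon=10, ref_base="C", alt_base="C").validate()


def test_threshold_config_validation():
    with pytest.raises(ValueError):
        ThresholdConfig(alpha=0.0)
    with pytest.raises(ValueError, match="unknown threshold"):
        ThresholdConfig.from_dict({"p_cutoff": 0.05})
    assert ThresholdConfig.from_dict({"alpha": 0.01}).alpha == 0.01


class TestDomainMap:
    def test_residue_130_is_catalytic(self):
        dm = load_domain_annotation()
        feats = dm.lookup(130)
        assert {"phosphatase", "P-loop", "ATP-B", "active-site"} <= feats

    def test_residue_400_is_c_tail(self):
        dm = load_domain_annotation()
        assert "C-tail" in dm.lookup(400)
        assert dm.domain_of(400) == "C-tail"

    def test_out_of_range_errors(self):
        dm = load_domain_annotation()
        for residue in (0, 404, -5):
            with pytest.raises(ValueError):
                dm.lookup(residue)

    def test_overlapping_domains_all_returned(self):
        # PBD (6-15) and phosphatase (14-185) overlap at 14-15
        dm = load_domain_annotation()
        assert {"PBD", "phosphatase"} <= dm.lookup(14)


class TestSampleIO:
    def test_read_basic(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "sample_id\tmsi_status\ttmb\nA\tMSS\t4.5\nB\tMSI-H\t55\nC\tunknown\t\n"
        )
        recs = read_samples(p)
        assert len(recs) == 3
        assert recs[0].tmb == 4.5
        assert recs[2].tmb is None  # empty field -> missing

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("sample_id\tmsi_status\ttmb\nA\tMSS\t4\nA\tMSS\t5\n")
        with pytest.raises(ValueError, match="duplicate sample_id"):
            read_samples(p)

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("sample_id\tmsi_status\nA\tMSS\n")
        with pytest.raises(FormatError, match="tmb"):
            read_samples(p)

    def test_round_trip(self, tmp_path, small_cohort):
        samples, _, _ = small_cohort
        p = tmp_path / "rt.tsv"
        write_samples(samples, p)
        back = read_samples(p)
        assert back == samples


class TestVariantIO:
    def test_read_parses_codon_and_class(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "sample_id\tgene\tvariant_class\thgvs_p\n"
            "A\tPTEN\tmissense\tp.R130Q\n"
            "B\tPTEN\tdeep_deletion\t\n"
            "C\tPTEN\tframeshift\tp.T319fs\n"
        )
        recs = read_variants(p)
        assert [r.codon for r in recs] == [130, None, 319]

    def test_unknown_class_lists_allowed(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("sample_id\tgene\tvariant_class\nA\tPTEN\tINDEL\n")
        with pytest.raises(ValueError, match="missense"):
            read_variants(p)

    def test_round_trip(self, tmp_path, small_cohort):
        _, variants, _ = small_cohort
        p = tmp_path / "rt.tsv"
        write_variants(variants, p)
        assert read_variants(p) == variants


class TestSignatureCatalogIO:
    def test_round_trip(self, tmp_path, catalog):
        p = tmp_path / "sigs.tsv"
        write_signature_catalog(catalog, p)
        back = read_signature_catalog(p)
        assert back.signature_ids == catalog.signature_ids
        assert (back.probabilities - catalog.probabilities).abs().values.max() < 1e-12

    def test_wrong_row_count_rejected(self, tmp_path, catalog):
        p = tmp_path / "sigs.tsv"
        write_signature_catalog(catalog, p)
        lines = p.read_text().splitlines()
        p.write_text("\n".join(lines[:-3]) + "\n")
        with pytest.raises(ValueError, match="96"):
            read_signature_catalog(p)

    def test_unnormalized_vector_rejected(self, tmp_path, catalog):
        import pandas as pd
        from mutprofile.signatures import SignatureCatalog

        probs = catalog.probabilities.copy()
        probs["SBS1"] = probs["SBS1"] * 0.8
        with pytest.raises(ValueError, match="sum to 1"):
            SignatureCatalog(probabilities=probs)

    def test_degenerate_single_channel_signature(self):
        import numpy as np
        import pandas as pd
        from mutprofile.signatures import CHANNELS, SignatureCatalog

        v = np.zeros(96)
        v[0] = 1.0
        cat = SignatureCatalog(
            probabilities=pd.DataFrame({"X": v}, index=list(CHANNELS))
        )
        assert cat.frequent_channels("X") == [CHANNELS[0]]


class TestFunctionScores:
    def _write(self, tmp_path, body):
        p = tmp_path / "f.tsv"
        header = ("codon\talt_aa\tlpa_score\tabundance_score\t"
                  "abundance_score_secondary\tclinical_label\tdne_curated\t"
                  "population_freq\n")
        p.write_text(header + body)
        return p

    def test_basic_row(self, tmp_path):
        p = self._write(tmp_path, "130\tQ\t-4.0\t0.9\t\tdamaging\tFalse\t\n")
        t = read_function_scores(p)
        row = t.get(130, "Q")
        assert row.lpa_score == -4.0 and row.abundance_source == "primary"

    def test_duplicate_key_rejected(self, tmp_path):
        p = self._write(tmp_path,
                        "130\tQ\t-4.0\t\t\t\tFalse\t\n130\tQ\t-3.0\t\t\t\tFalse\t\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_function_scores(p)

    def test_secondary_fills_gap_only(self, tmp_path):
        p = self._write(tmp_path, "130\tQ\t\t\t0.3\t\tFalse\t\n")
        row = read_function_scores(p).get(130, "Q")
        assert row.abundance_score == 0.3
        assert row.abundance_source == "secondary"

    def test_secondary_without_score_invalid(self):
        with pytest.raises(ValueError, match="secondary"):
            FunctionScoreTable([
                FunctionScoreRow(key=(1, "A"), abundance_source="secondary")
            ])

    def test_round_trip(self, tmp_path):
        rows = [
            FunctionScoreRow(key=(130, "Q"), lpa_score=-4.0,
                             abundance_score=0.9, abundance_source="primary",
                             clinical_label="damaging"),
            FunctionScoreRow(key=(14, "V"), abundance_score=0.3,
                             abundance_source="secondary",
                             population_freq=2e-5),
        ]
        t = FunctionScoreTable(rows)
        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "rt.tsv")
            write_function_scores(t, path)
            back = read_function_scores(path)
        assert len(back) == 2
        r = back.get(14, "V")
        assert r.abundance_source == "secondary" and r.frequent_in_population
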