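"""Fisher co-occurrence, FDR adjustment, and odds-ratio recovery."""

import math

import numpy as np
import pytest

from oracles import bh_stepup, exact_fisher_two_sided, plackett_p11
from mutprofile.cooccurrence import (
    cooccurrence_by_age,
    cooccurrence_panel,
    exclusive_group_rates,
    fdr_adjust,
    fisher_cooccurrence,
    group_rate_significance_matrix,
)
from mutprofile.datamodel import SampleRecord, VariantRecord


class TestFisher:
    def test_independence(self):
        r = fisher_cooccurrence(10, 10, 10, 10)
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_strong_cooccurrence(self):
        r = fisher_cooccurrence(20, 5, 5, 20)
        assert r.odds_ratio == pytest.approx(16.0)
        assert r.p_value == pytest.approx(
            float(exact_fisher_two_sided(20, 5, 5, 20)), rel=1e-9
        )

    def test_zero_cell_correction(self):
        r = fisher_cooccurrence(0, 10, 10, 10)
        assert r.odds_ratio == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))

    def test_ci_contains_point_estimate(self):
        r = fisher_cooccurrence(12, 7, 3, 20)
        assert r.ci_low < r.odds_ratio < r.ci_high

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            fisher_cooccurrence(0, 0, 0, 0)

    def test_symmetry_under_row_and_column_swap(self):
        r1 = fisher_cooccurrence(12, 7, 3, 20)
        r2 = fisher_cooccurrence(20, 3, 7, 12)  # swap both rows and columns
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio)

    def test_or_inverts_when_margin_flipped(self):
        r1 = fisher_cooccurrence(12, 7, 3, 20)
        r2 = fisher_cooccurrence(7, 12, 20, 3)
        assert r1.odds_ratio == pytest.approx(1 / r2.odds_ratio)

    def test_matches_enumeration_oracle_all_small_tables(self):
        """Fisher p equals the exact hypergeometric enumeration for every
        2x2 table with total n <= 60 (sampled grid within the suite; the
        acceptance run covers the full set)."""
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(400):
            n = int(rng.integers(1, 61))
            cuts = sorted(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            r = fisher_cooccurrence(a, b, c, d)
            oracle = float(exact_fisher_two_sided(a, b, c, d))
            assert r.p_value == pytest.approx(oracle, rel=1e-7, abs=1e-12)
            checked += 1
        assert checked == 400


class TestFDR:
    def test_single_p(self):
        assert fdr_adjust([0.01])[0] == pytest.approx(0.01)

    def test_matches_stepup_oracle(self):
        ps = [0.01, 0.02, 0.03, 0.04]
        assert fdr_adjust(ps) == pytest.approx(bh_stepup(ps))
        ps2 = [0.9, 0.001, 0.04, 0.04, 0.2, 0.5]
        assert fdr_adjust(ps2) == pytest.approx(bh_stepup(ps2))

    def test_all_ones(self):
        assert list(fdr_adjust([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]

    def test_empty(self):
        assert len(fdr_adjust([])) == 0

    def test_monotone(self):
        rng = np.random.default_rng(1)
        ps = rng.random(50)
        qs = fdr_adjust(ps)
        order = np.argsort(ps)
        assert (np.diff(qs[order]) >= -1e-12).all()


def _panel_data(n, p_pten, p_gene, psi, rng, gene="PIK3CA"):
    """Direct 2x2 sampling used as ground truth for panel recovery."""
    p11 = plackett_p11(p_pten, p_gene, psi)
    samples, variants = [], []
    for i in range(n):
        sid = f"s{i}"
        samples.append(SampleRecord(sample_id=sid, cohort="MT-L"))
        u = rng.random()
        pten = u < p_pten
        if pten:
            p_g = p11 / p_pten
        else:
            p_g = (p_gene - p11) / (1 - p_pten)
        if pten:
            variants.append(VariantRecord(sample_id=sid, gene="PTEN",
                                          variant_class="missense",
                                          hgvs_p="p.R130Q"))
        if rng.random() < p_g:
            variants.append(VariantRecord(sample_id=sid, gene=gene,
                                          variant_class="missense"))
    return samples, variants


class TestPanel:
    @pytest.mark.parametrize("psi", [0.25, 1.0, 4.0])
    def test_recovers_configured_or(self, psi):
        """The 95% CI covers the generating odds ratio at near-nominal
        frequency across simulations (n=5000 each)."""
        rng = np.random.default_rng(int(psi * 100))
        covered = 0
        sims = 20
        for _ in range(sims):
            samples, variants = _panel_data(5000, 0.3, 0.1, psi, rng)
            panel = cooccurrence_panel(samples, variants, selector="all",
                                       genes=("PIK3CA",), cohorts=("MT-L",))
            r = panel[("MT-L", "PIK3CA")]
            covered += r.ci_low <= psi <= r.ci_high
        assert covered / sims >= 0.85

    def test_absent_gene_gives_corrected_or(self):
        rng = np.random.default_rng(5)
        samples, variants = _panel_data(200, 0.3, 0.0, 1.0, rng, gene="SMAD4")
        panel = cooccurrence_panel(samples, variants, genes=("SMAD4",),
                                   cohorts=("MT-L",))
        r = panel[("MT-L", "SMAD4")]
        assert r.a == 0 and r.c == 0
        assert r.odds_ratio > 0 and r.ci_high > r.ci_low

    def test_deletion_vs_point_selectors_differ(self):
        samples = [SampleRecord(sample_id=f"s{i}", cohort="MT-L")
                   for i in range(100)]
        variants = [VariantRecord(sample_id="s0", gene="PTEN",
                                  variant_class="deep_deletion"),
                    VariantRecord(sample_id="s1", gene="PTEN",
                                  variant_class="missense", hgvs_p="p.R130Q")]
        p_del = cooccurrence_panel(samples, variants, selector="deletion",
                                   genes=("KRAS",), cohorts=("MT-L",))
        p_pt = cooccurrence_panel(samples, variants, selector="point",
                                  genes=("KRAS",), cohorts=("MT-L",))
        assert p_del[("MT-L", "KRAS")].b == 1
        assert p_pt[("MT-L", "KRAS")].b == 1  # different sample counted


class TestByAge:
    def test_single_bin_equals_pooled(self):
        rng = np.random.default_rng(6)
        samples, variants = _panel_data(2000, 0.3, 0.1, 2.0, rng)
        for s in samples:
            s.age = 50
        by_age = cooccurrence_by_age(samples, variants, [(0, 100)])
        pooled = fisher_cooccurrence(
            *(by_age[(0, 100)].a, by_age[(0, 100)].b,
              by_age[(0, 100)].c, by_age[(0, 100)].d)
        )
        assert by_age[(0, 100)].p_value == pytest.approx(pooled.p_value)

    def test_age_invariant_or_covered_in_each_bin(self):
        rng = np.random.default_rng(7)
        samples, variants = _panel_data(8000, 0.3, 0.15, 2.0, rng)
        ages = rng.integers(40, 80, len(samples))
        for s, a in zip(samples, ages):
            s.age = int(a)
        bins = [(40, 59), (60, 79)]
        res = cooccurrence_by_age(samples, variants, bins)
        for b in bins:
            assert res[b].ci_low <= 2.0 <= res[b].ci_high

    def test_empty_bin_is_na(self):
        samples = [SampleRecord(sample_id="s0", cohort="MT-L", age=50)]
        variants = []
        res = cooccurrence_by_age(samples, variants, [(40, 59), (80, 99)])
        assert res[(80, 99)] is None

    def test_no_samples_in_any_bin_errors(self):
        with pytest.raises(ValueError):
            cooccurrence_by_age(
                [SampleRecord(sample_id="s0", cohort="MT-L")], [], [(40, 50)]
            )


class TestExclusiveGroups:
    def test_partition_covers_all_samples(self):
        samples = [SampleRecord(sample_id=f"s{i}", cohort="MT-L")
                   for i in range(50)]
        variants = [VariantRecord(sample_id="s0", gene="APC",
                                  variant_class="missense"),
                    VariantRecord(sample_id="s0", gene="KRAS",
                                  variant_class="missense"),
                    VariantRecord(sample_id="s1", gene="TP53",
                                  variant_class="missense")]
        groups = exclusive_group_rates(samples, variants)
        assert sum(n for n, _ in groups.values()) == 50
        assert groups["APC+KRAS"][0] == 1
        assert groups["TP53"][0] == 1
        assert groups["none"][0] == 48

    def test_significance_matrix_is_bh_adjusted(self):
        groups = {"A": (100, 50), "B": (100, 10), "C": (100, 12)}
        qmat = group_rate_significance_matrix(groups)
        assert set(qmat) == {("A", "B"), ("A", "C"), ("B", "C")}
        assert qmat[("A", "B")] < 0.005
        assert qmat[("B", "C")] > 0.05
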