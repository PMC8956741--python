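"""Synthetic-cohort generator: determinism, constraints, and distributional
recovery of the configured parameters."""

import math

import numpy as np
import pytest

from oracles import plackett_p11
from mutprofile.datamodel import check_unique_sample_ids
from mutprofile.io import read_samples, read_variants
from mutprofile.simulate import (
    ConfigError,
    GeneratorConfig,
    TruthBundle,
    generate_cohort,
    generate_comutations,
    generate_copy_number,
    generate_pten_mutations,
    generate_samples,
    solve_2x2,
    toy_cds,
    write_fixture_bundle,
)
from mutprofile.stratify import assign_cohort


def _single_cohort_cfg(cohort="MT-L", **overrides):
    shares = {"MT-L": 0.0, "MT-H": 0.0, "MSS-htmb": 0.0}
    shares[cohort] = 1.0
    base = dict(n_samples=500, cohort_shares=shares)
    base.update(overrides)
    return GeneratorConfig(**base)


class TestSolve2x2:
    def test_independence(self):
        assert solve_2x2(0.3, 0.1, 1.0) == pytest.approx(0.03)

    def test_matches_independent_derivation(self):
        for p1, p2, psi in [(0.3, 0.1, 4.0), (0.5, 0.5, 0.25),
                            (0.8, 0.2, 2.0), (0.1, 0.9, 0.5)]:
            p11 = solve_2x2(p1, p2, psi)
            assert p11 == pytest.approx(plackett_p11(p1, p2, psi), abs=1e-12)
            # the realized odds ratio of the solved cells equals psi
            p10, p01 = p1 - p11, p2 - p11
            p00 = 1 - p11 - p10 - p01
            assert (p11 * p00) / (p10 * p01) == pytest.approx(psi, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            solve_2x2(1.5, 0.1, 1.0)
        with pytest.raises(ConfigError):
            solve_2x2(0.5, 0.1, -2.0)


class TestSamples:
    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig(n_samples=300)
        s1, _ = generate_samples(cfg, seed=9)
        s2, _ = generate_samples(cfg, seed=9)
        assert s1 == s2

    def test_seed_changes_table(self):
        cfg = GeneratorConfig(n_samples=300)
        s1, _ = generate_samples(cfg, seed=9)
        s2, _ = generate_samples(cfg, seed=10)
        assert s1 != s2

    def test_mtl_only_has_low_tmb(self):
        samples, _ = generate_samples(_single_cohort_cfg("MT-L"), seed=1)
        assert all(s.tmb < 16 for s in samples)

    def test_generated_cohorts_match_assignment_rules(self):
        """Cohort labels drawn by the generator agree with the
        stratification rules applied to the generated MSI/TMB."""
        samples, truth = generate_samples(GeneratorConfig(n_samples=2000),
                                          seed=2)
        for s in samples:
            assert assign_cohort(s) == truth.cohort_by_sample[s.sample_id]

    def test_cohort_shares_recovered(self):
        """Multinomial 3-sigma check of the configured shares at n=10000."""
        cfg = GeneratorConfig(n_samples=10000)
        samples, truth = generate_samples(cfg, seed=3)
        n = len(samples)
        for cohort, share in cfg.cohort_shares.items():
            k = sum(1 for c in truth.cohort_by_sample.values() if c == cohort)
            se = math.sqrt(share * (1 - share) / n)
            assert abs(k / n - share) <= 3 * se + 1e-9

    def test_infeasible_tmb_config_rejected(self):
        with pytest.raises(ConfigError):
            cfg = GeneratorConfig(tmb_params={
                "MT-L": (4.0, 0.8, 0.0, 16.0),
                "MT-H": (50.0, 0.45, 16.0, 100.0),
                "MSS-htmb": (5.0, 0.5, 0.0, 10.0),  # mass below 16
            })
            cfg.validate()

    def test_unique_ids(self):
        samples, _ = generate_samples(GeneratorConfig(n_samples=1000), seed=4)
        check_unique_sample_ids(samples)


class TestPtenMutations:
    def test_zero_prevalence_no_variants(self):
        cfg = _single_cohort_cfg(
            "MT-L",
            pten_prevalence={"MT-L": 0.0, "MT-H": 0.25, "MSS-htmb": 0.45},
        )
        samples, truth = generate_samples(cfg, seed=5)
        variants = generate_pten_mutations(samples, cfg, truth, seed=5)
        assert variants == []

    def test_degenerate_hotspot_mixture(self):
        """Hotspot share 1.0 at codon 130 places every point mutation there."""
        from mutprofile.simulate import PlantedHotspot

        cfg = _single_cohort_cfg(
            "MT-L",
            deletion_share={"MT-L": 0.0, "MT-H": 0.0, "MSS-htmb": 0.0},
            planted_hotspots=[PlantedHotspot(130, "missense", 1.0)],
        )
        samples, truth = generate_samples(cfg, seed=6)
        variants = generate_pten_mutations(samples, cfg, truth, seed=6)
        assert variants and all(v.codon == 130 for v in variants)
        assert all(v.variant_class == "missense" for v in variants)

    def test_deletion_share_recovered(self):
        cfg = _single_cohort_cfg(
            "MT-L", n_samples=4000,
            pten_prevalence={"MT-L": 0.3, "MT-H": 0.25, "MSS-htmb": 0.45},
        )
        samples, truth = generate_samples(cfg, seed=7)
        variants = generate_pten_mutations(samples, cfg, truth, seed=7)
        dels = sum(1 for v in variants if v.variant_class == "deep_deletion")
        n = len(variants)
        se = math.sqrt(0.41 * 0.59 / n)
        assert abs(dels / n - 0.41) <= 3 * se

    def test_all_records_satisfy_invariants(self, small_cohort):
        _, variants, _ = small_cohort
        for v in variants:
            v.validate()

    def test_snv_contexts_match_cds(self, small_cohort, cds):
        """Generated SNV flanking contexts agree with the toy CDS."""
        _, variants, _ = small_cohort
        checked = 0
        for v in variants:
            if v.gene != "PTEN" or not v.is_snv or not v.hgvs_c:
                continue
            pos = int("".join(ch for ch in v.hgvs_c[2:] if ch.isdigit())) - 1
            assert cds[pos] == v.ref_base
            if pos > 0:
                assert cds[pos - 1] == v.context5
            checked += 1
        assert checked > 50


class TestCopyNumber:
    def _mutated(self, cfg, seed):
        samples, truth = generate_samples(cfg, seed=seed)
        variants = generate_pten_mutations(samples, cfg, truth, seed=seed)
        generate_copy_number(variants, cfg, truth, seed=seed)
        return variants, truth

    def test_loh_prob_one(self):
        cfg = _single_cohort_cfg(
            "MT-L",
            loh_probability={"MT-L": 1.0, "MT-H": 0.15, "MSS-htmb": 0.1},
        )
        variants, truth = self._mutated(cfg, 8)
        for cls in truth.loh_class_by_sample.values():
            assert cls in ("mut_only", "multi_mut")

    def test_loh_prob_zero(self):
        cfg = _single_cohort_cfg(
            "MT-L",
            loh_probability={"MT-L": 0.0, "MT-H": 0.15, "MSS-htmb": 0.1},
        )
        variants, truth = self._mutated(cfg, 8)
        for cls in truth.loh_class_by_sample.values():
            assert cls in ("mut_plus_wt", "multi_mut")

    def test_loh_fraction_recovered(self):
        cfg = _single_cohort_cfg(
            "MT-L", n_samples=6000,
            pten_prevalence={"MT-L": 0.3, "MT-H": 0.25, "MSS-htmb": 0.45},
            loh_probability={"MT-L": 0.6, "MT-H": 0.15, "MSS-htmb": 0.1},
        )
        _, truth = self._mutated(cfg, 9)
        singles = [c for c in truth.loh_class_by_sample.values()
                   if c != "multi_mut"]
        frac = singles.count("mut_only") / len(singles)
        se = math.sqrt(0.6 * 0.4 / len(singles))
        assert abs(frac - 0.6) <= 3 * se


class TestComutations:
    def _run(self, psi, n=5000, p_gene=0.3, seed=10):
        cfg = _single_cohort_cfg(
            "MT-L", n_samples=n,
            pten_prevalence={"MT-L": 0.3, "MT-H": 0.25, "MSS-htmb": 0.45},
            comutation_rates={"KRAS": p_gene},
            comutation_odds_ratios={"KRAS": psi},
        )
        samples, truth = generate_samples(cfg, seed=seed)
        variants = generate_pten_mutations(samples, cfg, truth, seed=seed)
        generate_comutations(samples, variants, cfg, truth, seed=seed)
        pten = {v.sample_id for v in variants if v.gene == "PTEN"}
        kras = {v.sample_id for v in variants if v.gene == "KRAS"}
        a = b = c = d = 0
        for s in samples:
            p, g = s.sample_id in pten, s.sample_id in kras
            a += p and g
            b += p and not g
            c += g and not p
            d += not p and not g
        return a, b, c, d

    def test_independence_or_near_one(self):
        a, b, c, d = self._run(1.0)
        or_ = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(math.log(or_)) <= 3 * se

    def test_or_four_recovered(self):
        a, b, c, d = self._run(4.0)
        or_ = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(math.log(or_) - math.log(4)) <= 3 * se

    def test_zero_marginal_gene_never_mutated(self):
        a, b, c, d = self._run(1.0, p_gene=0.0)
        assert a == 0 and c == 0

    def test_infeasible_pair_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(comutation_odds_ratios={"KRAS": -1.0}).validate()


class TestFixtureBundle:
    def test_round_trip(self, tmp_path):
        samples, variants, truth = generate_cohort(
            GeneratorConfig(n_samples=200), seed=12
        )
        paths = write_fixture_bundle(samples, variants, truth, tmp_path / "b")
        assert read_samples(paths["samples"]) == samples
        assert read_variants(paths["variants"]) == variants

    def test_byte_identical_for_same_seed(self, tmp_path):
        cfg = GeneratorConfig(n_samples=150)
        for d in ("x", "y"):
            s, v, t = generate_cohort(cfg, seed=13)
            write_fixture_bundle(s, v, t, tmp_path / d)
        for name in ("samples.tsv", "variants.tsv", "truth.json"):
            assert (tmp_path / "x" / name).read_bytes() == \
                   (tmp_path / "y" / name).read_bytes()

    def test_empty_cohort_valid_headers(self, tmp_path):
        paths = write_fixture_bundle([], [], TruthBundle(), tmp_path / "e")
        assert read_samples(paths["samples"]) == []
        assert read_variants(paths["variants"]) == []

    def test_seed_changes_variants_not_schema(self, tmp_path):
        cfg = GeneratorConfig(n_samples=300)
        s1, v1, t1 = generate_cohort(cfg, seed=1)
        s2, v2, t2 = generate_cohort(cfg, seed=2)
        assert v1 != v2
        p1 = write_fixture_bundle(s1, v1, t1, tmp_path / "a")
        p2 = write_fixture_bundle(s2, v2, t2, tmp_path / "b")
        h1 = p1["variants"].read_text().splitlines()[0]
        h2 = p2["variants"].read_text().splitlines()[0]
        assert h1 == h2


def test_toy_cds_is_stable_and_has_homopolymers():
    c1, c2 = toy_cds(), toy_cds()
    assert c1 == c2 and len(c1) == 1209
    assert "AAAA" in c1 and "TTTT" in c1
    assert c1.startswith("ATG")
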