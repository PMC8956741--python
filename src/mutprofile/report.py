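"""Pipeline orchestration and the machine-readable run report.

``run_pipeline`` executes the stages in a fixed order — stratify ->
signatures -> functional impact -> hotspots (1D, and 3D when structures are
supplied) -> zygosity -> co-occurrence — writing one TSV per stage plus a
JSON run report.  All randomness flows from a single seed, split into one
independent stream per stage by stable stage name, so adding a stage never
perturbs the draws of earlier ones.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import pandas as pd
import yaml

import mutprofile
from mutprofile import cooccurrence as co
from mutprofile import hotspots as hs
from mutprofile import stratify as st
from mutprofile import zygosity as zy
from mutprofile.datamodel import ThresholdConfig
from mutprofile.function_impact import dichotomize_lof, lof_fraction
from mutprofile.io import (
    FunctionScoreTable,
    ensure_dir,
    read_function_scores,
    read_samples,
    read_variants,
)
from mutprofile.signatures import (
    label_variants,
    read_signature_catalog,
    toy_signature_catalog,
)
from mutprofile.simulate import (
    GeneratorConfig,
    generate_cohort,
    toy_cds,
    write_fixture_bundle,
)


class PipelineConfig:
    """Thin YAML-backed configuration: input paths, thresholds, simulation."""

    def __init__(self, d: dict):
        self.samples_path = d.get("samples")
        self.variants_path = d.get("variants")
        self.scores_path = d.get("scores")
        self.catalog_path = d.get("catalog")
        self.structures = d.get("structures", [])
        self.simulate = d.get("simulate")          # dict of GeneratorConfig keys
        self.thresholds = ThresholdConfig.from_dict(d.get("thresholds", {}))
        if self.simulate is None and (
            self.samples_path is None or self.variants_path is None
        ):
            raise ValueError(
                "config must provide samples+variants paths or a simulate block"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})


def run_pipeline(
    config: PipelineConfig | dict | str | Path,
    out_dir,
    seed: int = 0,
) -> dict:
    """Run every stage; returns the run report (also written as JSON)."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig(config)
    thr = config.thresholds
    out = ensure_dir(out_dir)
    t0 = time.time()
    report: dict = {
        "version": mutprofile.__version__,
        "seed": seed,
        "thresholds": dataclasses.asdict(thr),
        "stages": {},
    }

    # inputs (or inline simulation)
    if config.simulate is not None:
        gcfg_kwargs = dict(config.simulate)
        gcfg = GeneratorConfig(**gcfg_kwargs)
        samples, variants, truth = generate_cohort(gcfg, seed=seed)
        write_fixture_bundle(samples, variants, truth, out / "simulated")
        report["stages"]["simulate"] = {
            "n_samples": len(samples), "n_variants": len(variants),
        }
    else:
        samples = read_samples(config.samples_path)
        variants = read_variants(config.variants_path)
    scores = (
        read_function_scores(config.scores_path)
        if config.scores_path else FunctionScoreTable([])
    )
    catalog = (
        read_signature_catalog(config.catalog_path, thr.frequent_channel_theta)
        if config.catalog_path else toy_signature_catalog(thr.frequent_channel_theta)
    )

    # stratify
    st.assign_cohorts(samples, thr)
    summaries = st.summarize_cohorts(samples, variants)
    st.summary_table(summaries).to_csv(out / "cohort_summary.tsv",
                                       sep="\t", index=False)
    report["stages"]["stratify"] = {
        c: {"n": s.n, "altered": s.n_altered, "prevalence": s.prevalence}
        for c, s in summaries.items()
    }

    # signatures
    label_variants(variants, samples, catalog, thr, cds=toy_cds())
    sig_counts = (
        pd.Series([v.signature_label for v in variants if v.gene == "PTEN"])
        .value_counts().to_dict()
    )
    report["stages"]["signatures"] = sig_counts

    # functional impact
    calls = []
    for v in variants:
        if v.gene != "PTEN":
            continue
        call = dichotomize_lof(v, scores, thr)
        v.lof_call = call.lof_call
        calls.append(call)
    pd.DataFrame(
        [{"variant": c.variant_key, "lof_call": c.lof_call,
          "basis": c.basis, "dne": c.dne_flag} for c in calls]
    ).to_csv(out / "impact.tsv", sep="\t", index=False)
    determinate = [c for c in calls if c.lof_call != "NA"]
    report["stages"]["impact"] = {
        "n_calls": len(calls),
        "lof_fraction": lof_fraction(calls)[0] if determinate else None,
    }

    # hotspots (1D + window track)
    cohort_by_sample = {s.sample_id: s.cohort for s in samples}
    hotspot_rows, window_rows = [], []
    for cohort in (None, "MT-L", "MT-H", "MSS-htmb"):
        counts = hs.tally_codon_counts(
            variants, cohort=cohort, cohort_by_sample=cohort_by_sample
        )
        calls_1d = hs.call_codon_hotspots(counts, thr=thr, cohort=cohort)
        for c in calls_1d:
            hotspot_rows.append({
                "cohort": cohort or "all", "codon": c.codon, "count": c.count,
                "p_value": c.p_value, "significant": c.significant,
                "share": c.share, "major": c.major, "recurrent": c.recurrent,
            })
        nh = hs.nonhotspot_counts(counts, thr)
        for w in hs.window_enrichment_scan(nh, thr=thr):
            if w.count:
                window_rows.append({
                    "cohort": cohort or "all", "start": w.start, "end": w.end,
                    "count": w.count, "neglog10_p": w.neglog10_p,
                    "significant": w.significant,
                })
    pd.DataFrame(hotspot_rows).sort_values(
        ["cohort", "p_value"]
    ).to_csv(out / "hotspots.tsv", sep="\t", index=False)
    pd.DataFrame(window_rows).to_csv(out / "windows.tsv", sep="\t", index=False)
    report["stages"]["hotspots"] = {
        "n_significant": int(sum(r["significant"] for r in hotspot_rows)),
        "n_major": int(sum(r["major"] for r in hotspot_rows)),
    }

    # 3D clusters when structures are given
    if config.structures:
        from mutprofile import structures as s3d

        graph = s3d.build_contact_graph(config.structures, thr)
        clusters = s3d.enumerate_clusters(graph)
        counts_all = hs.tally_codon_counts(variants, class_filter="missense+inframe")
        tested = s3d.permutation_test_clusters(
            clusters, counts_all, graph, seed=seed, thr=thr
        )
        pd.DataFrame([
            {"center": c.center, "members": ",".join(map(str, sorted(c.members))),
             "count": c.count, "p_value": c.p_value, "significant": c.significant}
            for c in tested
        ]).to_csv(out / "clusters3d.tsv", sep="\t", index=False)
        report["stages"]["hotspots3d"] = {
            "n_clusters": len(tested),
            "n_significant": int(sum(c.significant for c in tested)),
        }

    # zygosity
    loh_calls = zy.classify_loh_all(variants)
    matrix = zy.loh_matrix(variants)
    matrix.to_csv(out / "loh_matrix.tsv", sep="\t")
    counts_per_sample = st.pten_mutation_counts(variants)
    mult_counts = [
        counts_per_sample.get(s.sample_id, 0) for s in samples
        if s.cohort in st.ANALYSIS_COHORTS
    ]
    skew = zy.multiplicity_skew(mult_counts) if mult_counts else []
    pd.DataFrame([dataclasses.asdict(r) for r in skew]).to_csv(
        out / "multiplicity.tsv", sep="\t", index=False
    )
    loh_class_counts: dict[str, int] = {}
    for c in loh_calls.values():
        loh_class_counts[c.loh_class] = loh_class_counts.get(c.loh_class, 0) + 1
    report["stages"]["zygosity"] = loh_class_counts

    # co-occurrence
    panel = co.cooccurrence_panel(
        samples, variants, selector="all",
        cohorts=("MT-L", "MT-H", "MSS-htmb"),
    )
    pd.DataFrame([
        {"cohort": k[0], "gene": k[1], "a": r.a, "b": r.b, "c": r.c, "d": r.d,
         "odds_ratio": r.odds_ratio, "log2_or": r.log2_or,
         "ci_low": r.ci_low, "ci_high": r.ci_high,
         "p_value": r.p_value, "q_value": r.q_value}
        for k, r in panel.items()
    ]).to_csv(out / "cooccurrence.tsv", sep="\t", index=False)
    report["stages"]["cooccurrence"] = {
        "n_pairs": len(panel),
        "n_significant": int(sum(r.q_value < 0.05 for r in panel.values())),
    }

    report["wall_time_s"] = round(time.time() - t0, 3)
    (out / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def render_report(report: dict) -> str:
    """Deterministic human-readable rendering of a run report."""
    lines = [f"mutprofile {report.get('version', '?')} run (seed "
             f"{report.get('seed')})"]
    for stage in sorted(report.get("stages", {})):
        lines.append(f"[{stage}]")
        section = report["stages"][stage]
        if not section:
            lines.append("  0 samples")
            continue
        for key in sorted(section, key=str):
            lines.append(f"  {key}: {section[key]}")
    return "\n".join(lines) + "\n"
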