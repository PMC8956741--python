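# Methods

This note documents the statistical models, thresholds, and design choices
behind `mutprofile`, and what the synthetic-data tests do and do not
establish about real cohorts.

## Cohort stratification

Tumors are assigned to analysis cohorts from two observables: a clinical
microsatellite annotation (MSI-H / MSS / unknown) and TMB in mutations per
megabase. A clinical MSI annotation always wins: MSI-H → MT-H and MSS →
MT-L or MSS-htmb regardless of TMB, because a small fraction of annotated
tumors are TMB-discordant and the annotation is the more direct
measurement. When only TMB is known, the cutpoints are 16 (below → MT-L,
grouped with MSS) and 100 (at or above → excluded, since very high TMB
mixes MSI-H and MSS ultramutators indistinguishably). TMB exactly 100 with
unknown MSI is excluded: the interval [16, 100) is assigned to MT-H and the
exclusion rule is stated as "> 100", leaving the boundary point unclaimed;
we resolve it conservatively. Samples missing both observables are
excluded. The assignment is total: every sample receives exactly one of
MT-L, MT-H, MSS-htmb, excluded.

Prevalence confidence intervals are Wilson score intervals (the method
behaves well at the small counts that arise in the MSS-htmb cohort; the
choice is ours, as no CI method is mandated by the analysis conventions we
follow). Proportion comparisons use the classical two-sample test for
equality of proportions with continuity correction; trends use a
single-predictor maximum-likelihood logistic fit with a two-sided Wald
p-value, with perfect separation detected and reported as a missing
p-value rather than a spurious number.

## Hotspot statistics

The per-codon null is uniform: each of N cohort mutations falls on any of
the L = 403 residues with probability 1/L, and the hotspot p-value is the
exact binomial upper tail P(X ≥ k) with no normal approximation. No
mutability weighting (e.g. trinucleotide composition) enters the default
null; a context-weighted null would change individual p-values but not the
test's architecture, and the analysis convention this package follows
compensates for multiplicity by globally tightening α to 0.005 instead of
per-family correction (Benjamini–Hochberg is available as a helper for the
co-occurrence panels, where it is part of the procedure).

Significance additionally requires k ≥ 2. With tiny cohorts a single
mutation already has P(X ≥ 1) < 0.005, a degenerate call that a count
guard suppresses; at realistic cohort sizes the guard is inert.

"Strongly preferred" (major) hotspots carry strictly more than 3% of the
cohort's mutations; "recurrent" sites have counts strictly greater than 6.

The window-enrichment track is a second pass over non-hotspot mutations:
codons significant in the first pass are removed, and every window of 5
consecutive residues (stride 1, tiling 1..L−4) is tested against
Binomial(N_nh, 5/L). Values are reported as −log10 p, significant above
−log10(0.005) ≈ 2.30. Stride 1 is our choice — it maximizes the resolution
of the plotted density and makes the window set unambiguous.

Saturation analysis subsamples mutations without replacement at a ladder of
sizes, re-calls hotspots per replicate, and averages the significant-codon
count — an empirical discovery curve whose flattening indicates approaching
saturation.

## 3D clustering

Contacts are all-heavy-atom (hydrogens configurable): two residues are in
contact when any atom pair sits within 5 Å. Reproducibility gates the
graph: with S structures a contact must hold in at least ⌈2S/3⌉ of them,
and a structure supports a contact only when at least ⌈2C/3⌉ of its C
chains show it (the 2-of-3 rule generalized to arbitrary structure and
chain counts). Residues are cluster-eligible when resolved in at least the
same minimum number of structures. A candidate cluster is the closed
neighborhood of any residue with ≥ 1 contact neighbor.

The permutation null reassigns each individual mutation uniformly at random
among resolved residues (a multinomial draw), recomputes cluster sums, and
estimates p with the add-one formula p = (1 + #{null ≥ obs}) / (1 + B), so
p is never 0 and the estimator is valid at any B. An alternative
residue-shuffle scheme (permuting the observed count vector over residues)
is provided; it conditions on the observed count multiset and is stricter
for clusters driven by a single heavily mutated residue. The multinomial
scheme is the default because "expected by chance" most naturally means
random placement of mutations, and it is exactly enumerable on small toys,
which the tests exploit.

## Signature compatibility

SNVs map to the 96 pyrimidine-centric trinucleotide channels; purine
references are reverse-complemented (flanks swap), making the normalization
idempotent. A mutation is *compatible* with an SBS signature when its
channel holds at least θ = 0.05 of that signature's probability mass — a
formalization of "most frequent channels"; θ is configurable and the
labeling is deliberately per-mutation compatibility, not a fitted
deconvolution (no NNLS/NMF refitting). 1-bp indels in homopolymer runs of
length ≥ 4 are eligible for the grouped homopolymer-indel label IDT
(ID1/ID2/ID5/ID7); 4 is permissive relative to the longer runs those
signatures emphasize, and configurable.

Where several signatures are compatible, a fixed biological-context
priority resolves the tie: (1) POLE-exonuclease signatures
(SBS10a/SBS10b/SBS28) in POLE-mutant samples, highest channel probability
breaking ties; (2) in MT-H (hypermutated, MMR-deficient) samples, IDT for
eligible indels and SBS44 for compatible SNVs; (3) SBS1; (4) IDT in any
cohort; (5) "other". The order within (1)–(3) is our documented
interpretation of context priority; deletions, amplifications and
rearrangements are labeled "not-applicable".

## Functional dichotomization

The LoF call evaluates evidence tiers in a fixed order: truncating classes
(nonsense/frameshift/splice) at codons 1–352 are damaging outright and
later truncations WT-like; then curated clinical labels, with
"conflicting" treated as damaging (varying assessments across knowledge
bases count as damaging); then lipid-phosphatase fitness < −1.1; then
VAMP-seq abundance < 0.4; a benign label or scores above both cuts give
WT-like; otherwise NA. Truncation-first ordering reflects that a premature
stop inside the catalytic or C2 domain is mechanistically unambiguous,
whereas score-based evidence is assay-derived. Score-based damaging calls
(only) are demoted to NA when the substitution's population frequency is
≥ 1e-5, since common germline alleles are unlikely to be strongly
function-impairing. Splice variants lacking a codon mapping are NA.
Abundance scores from a secondary assay fill gaps only where the primary
assay has none.

The dominant-negative flag marks missense/in-frame variants with impaired
phosphatase activity (< −1.1) but retained abundance (≥ 0.4) — PTEN acts
as a homodimer, so a stable catalytically dead subunit can poison the
wild-type partner — plus curated DNE variants. Truncations are never DNE.

## Zygosity and multiplicity

Samples with PTEN point/indel mutations and copy-number data fall into
three classes: ≥ 2 distinct mutations → multi-mutated; one mutation with
total copy number equal to the mutated-allele copy number → only the
mutated allele remains (LOH); otherwise a wild-type allele persists.
Samples without copy-number data are undetermined and excluded from the
matrix.

The multiplicity skew compares observed frequencies of 0/1/>1 mutations
per sample with a Poisson null at the cohort's empirical rate λ̂ =
total/n, reporting log2(obs/exp) and a two-sided exact binomial p per
category. Poisson is the simplest exchangeable "random distribution"
null; the synthetic generator draws per-sample counts from the same
Poisson family, deliberately closing the loop so the null-calibration
tests are exact by construction. A TMB-scaled binomial null would be the
natural extension if per-sample mutation opportunity varied strongly; the
observation that TMB does not differ between single- and multi-mutated
samples motivates the simpler default. The skew denominator is all cohort
samples (not only copy-number-evaluable ones).

Pairwise hotspot co-occurrence uses the independence null p0 =
(nA/n)(nB/n) and the exact binomial upper tail of the co-carrier count.

## Co-occurrence panels

Each (PTEN class selector, partner gene, cohort) yields a 2×2 table of
sample counts. The two-sided Fisher p is computed by hypergeometric
enumeration over the support in a single vectorized pmf evaluation
(numerically identical to the classical implementation, an order of
magnitude faster — relevant for the exhaustive small-table verification).
The odds ratio applies a Haldane–Anscombe +0.5 to all cells when any cell
is zero; the 95% CI is Woolf's logit interval on the corrected table. A
conditional-MLE CI would differ from the sample OR and is intentionally
not the default. Selectors: all alterations, point only, point-LoF only,
deletions only; a sample counts once per selector regardless of how many
qualifying records it carries. The 8-way presence/absence partition over
APC/KRAS/TP53 reports PTEN alteration rates per cell with pairwise
continuity-corrected proportion tests, BH-adjusted.

## Synthetic cohorts

The generator's defaults emulate the published composition of a
34,129-tumor CRC profiling series: cohort shares 0.9446/0.0483/0.0071
(MT-L/MT-H/MSS-htmb), log-normal TMB with medians 4 (MT-L, truncated
below 16) and 50 (MT-H, truncated to [16, 100)) and 30 for MSS-htmb
(truncated ≥ 16), normal ages with medians 59/64/55 (sd 12.9), 55% male,
84% colon, POLE-mutant fractions 0.01/0.05/0.54, PTEN alteration
prevalences 7.56%/24.95%/45.27% (event rate λ = −ln(1 − prevalence), so
P(≥ 1 event) matches the prevalence exactly under the Poisson count
model), deletion shares 0.41/0.00/0.02, and signature mixtures dominated
by unattributable background in MT-L, homopolymer indels in MT-H, and
POLE signatures in MSS-htmb. Partner-gene marginal rates (APC 0.79, KRAS
0.51, TP53 0.77, SMAD4 0.21, PIK3CA 0.195) and default odds ratios vs
PTEN status (co-occurrence for PIK3CA/KRAS/SMAD4, exclusion for TP53) are
realized by solving the 2×2 cell probabilities from (marginals, OR) via
Plackett's quadratic and drawing gene status conditionally on the
sample's realized PTEN status. LOH probabilities per cohort are not
published as numbers; we fixed 0.60/0.15/0.10 (MT-L markedly higher, as
qualitatively reported) once and did not revisit them.

SNV placement is signature-driven: a channel is drawn with probability
proportional to signature channel probability × the count of matching
trinucleotides in the coding sequence (both strands), a matching site is
drawn uniformly, and the protein consequence follows from the standard
genetic code (silent draws are rejected). IDT events are 1-bp deletions
placed uniformly in homopolymer runs ≥ 4. Planted hotspots receive a
configured share of point events, realized as single-base changes at the
target codon with the requested consequence.

The bundled coding sequence is a deterministic 1209-nt toy (fixed internal
seed, sense codons only, embedded A/T homopolymer tracts, CGA codons at
the canonical hotspot positions so both R→Q missense and R→* nonsense
changes are single-base-reachable). It is not the real NM_000314
transcript — the package stays download-free — and any analysis needing
the real sequence can pass it by path. Consequences: absolute channel
availabilities differ from the real gene, so synthetic signature-mixture
recovery validates the machinery, not PTEN-specific channel counts.

All randomness flows from one seed, split into independent streams per
stage by stable stage name (samples, mutations, copynumber, comutations),
so adding a stage never perturbs earlier draws and fixture bundles are
byte-identical across runs.

### What the synthetic tests do not show

The generator draws mutations independently across samples given cohort,
with no clonal structure, no germline contamination, no panel-footprint
effects, no subsite- or sex-linked mutational differences, and
context-faithful but gene-unfaithful sequence composition. Passing
recovery tests therefore demonstrates correctness of the estimators and
calibration of the tests under their stated nulls — not that real CRC
cohorts satisfy those nulls.

## Numerical choices and problem sizes

Binomial tails are exact (scipy's regularized incomplete beta), verified
against arbitrary-precision rational summation to 1e-12 on a grid of
n ≤ 200. Fisher p-values are verified against exact integer enumeration
for every 2×2 table with n ≤ 60. Permutation p-values are verified
against full multinomial enumeration on ≤ 6-residue toys within 3
Monte-Carlo SEs. Calibration suites use 1000 uniform-null cohorts of 500
mutations (type-I rate), 100 cohorts of 2000 mutations with five planted
3%-share hotspots (sensitivity), and 5000-sample synthetic cohorts
(parameter recovery) — sizes chosen to make the Monte-Carlo error small
relative to the margins being asserted while keeping the default suite
fast.

## Known limitations

- Signature labels are compatibility calls; overlapping signatures are
  resolved by priority, not likelihood, and label frequencies are only
  interpretable jointly with the priority order.
- Splice-variant truncation position uses the parsed codon when present;
  intronic HGVS without a codon mapping yields NA rather than a guess.
- The 2D window track's "non-hotspot" set is the self-consistent two-pass
  exclusion (first-pass significant codons removed); a fixed external
  hotspot list would shift the track where the two disagree.
- Multi-structure contact support treats chains as exchangeable replicas;
  genuinely asymmetric assemblies would need per-chain weighting.
- The co-occurrence panels are marginal 2×2 analyses; no multivariable
  adjustment is attempted.
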