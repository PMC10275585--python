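# Methods

Models, assumptions, parameters and numerical choices behind `clonostate`.

## 1. Repertoire analysis

**Clonotype calls.** AIRR rearrangement rows are filtered to productive
chains. Per cell and locus (TRD, TRG) one chain is kept: the highest
`duplicate_count` when present, else the lexicographically smallest `v_call`;
multi-chain cells are flagged `ambiguous`. Allele suffixes (`*01`) are
stripped before any comparison, so alleles never split clones. The clonotype
key concatenates `(v_call, j_call, junction_aa)` of both loci; cells missing a
locus are keyed on the available one and flagged `partially_paired`.

**Classes.** TRDV1 → Vδ1, TRDV3 → Vδ3; TRDV2 splits on the γ-chain into
Vγ9⁺Vδ2⁺ and Vγ9⁻Vδ2⁺. Cells carrying TRGV9 with TRGJP on a Vδ2 background
are flagged as the public semi-invariant receptor. Unknown segments map to
`other`, never to an exception.

**Clonal focusing.** The Gini coefficient uses
G = Σᵢⱼ|xᵢ−xⱼ| / (2 n² x̄), computed by the O(n log n) sorted identity
Σᵢⱼ|xᵢ−xⱼ| = 2 Σᵢ (2i−n+1) x₍ᵢ₎; the test suite checks it against the
brute-force double loop to 1e-12. `partition_by_size` uses a strictly-greater
threshold (default 10 cells); `classify_expansion` calls a single-clone
culture strong when its final count strictly exceeds 500 cells, and
percentages are rounded to one decimal (74/382 → 19.4 %).

## 2. Signature and phenotype scoring

**Control-matched module scores.** Genes are binned into `n_bins` = 25
average-expression bins (rank, `method="min"`, then equal-width cut). Per
signature gene, `n_ctrl` = 50 control genes are drawn without replacement from
the gene's bin, excluding all signature genes; when a bin holds no candidates,
the gene acts as its own control, so a signature covering every gene scores
exactly 0. The score is mean(signature) − mean over signature genes of their
control means. Sampling is seeded and the fitted scorer is reusable
(sklearn `fit`/`transform`). scanpy's `score_genes` serves as an independent
cross-check in the tests, not as the implementation.

**Innateness.** Expression is z-scored per gene (population sd, ddof = 0;
zero sd treated as 1); the score is the mean z over the innateness-up set
minus the mean over the down set. Because z-scores are centered, the score
averages to 0 over the scored population; it is a relative ordering, not an
absolute scale.

**GZMA/GZMB.** Per cell: log2((GZMA + 1)/(GZMB + 1)) on normalized (expm1 of
log-normalized) counts; per group: the log-ratio of group means with the same
pseudocount. Groups are assigned lo/mo/hi by tertiles unless explicit cutoffs
are given.

**Memory gating.** `MemoryGate` fits a two-component 1-D Gaussian mixture to
log intensities per marker and sets the threshold at the posterior crossover
between the two component means; manual thresholds override. The quadrant
gate is CD27⁻ → T_E regardless of CD45RA; CD27⁺ splits into T_N (CD45RA⁺) and
T_CM (CD45RA⁻). Fractions always sum to 1.

**Cluster-state decision list.** Per cluster the profile holds mean module
scores (antigen presentation, exhaustion, tissue-residency), mean z-scored
CCR7/ZNF683/KLRG1, and the cluster GZMA/GZMB log-ratio. The ordered rules
are: high CCR7 + high antigen presentation → APC-like; high exhaustion +
GZMB-dominant ratio → early exhaustive CTL; ZNF683⁺ KLRG1⁻ with high
tissue-residency score → TRM-precursor CTL; ZNF683⁺ KLRG1⁻ otherwise →
TRM-precursor-like; fallthrough → early differentiating. All thresholds
default to 0, i.e. "above the cross-cluster average".

## 3. Marker genes and coexpression modules

**Rank-sum test.** Two-sided Wilcoxon rank-sum with midranks. For group
sizes both ≤ 10, the p-value is exact: all C(n, n₁) assignments of the pooled
midranks are enumerated and p is the fraction at least as extreme (|W − E[W]|)
as observed — this handles ties, which scipy's exact method does not. Larger
groups use the normal approximation with tie-corrected variance
Var(W) = n₁n₂/(n(n−1)) · (Σr² − n(n+1)²/4) and a 0.5 continuity correction.
BH correction is `statsmodels.multipletests(method="fdr_bh")`, verified
against a brute-force step-up in the tests.

**Markers.** Cluster-vs-rest (or the single pairwise contrast with exactly
two labels); `log2_fc` is the difference of mean log-normalized expression
divided by ln 2; filters are padj ≤ 0.05, log2_fc ≥ 0.25, fraction expressing
in-cluster ≥ 0.1. Singleton clusters are skipped with a warning.

**Modules.** Marker genes are aggregated to a cluster × gene matrix of
per-cluster mean z-scored expression (z across cells; single-cluster input
returns raw means). Genes are clustered on correlation distance (1 − Pearson
across clusters; constant genes receive correlation 0 → maximal distance)
with average linkage, cut into k = 12 modules (fewer when fewer marker genes
exist). Genes are processed in sorted-name order, so results are invariant to
input column order.

## 4. Clone-level differentiation bias

States are grouped TRM (TRM-precursor-like), APC (APC-like), CTL
(TRM-precursor CTL + early exhaustive CTL), other. Per clone the APC:CTL
ratio is (n_APC + 0.5)/(n_CTL + 0.5) (Haldane–Anscombe pseudocount); ratios
below 1 are CTL-biased, above 1 APC-biased. Per-clone records are built for
clones with ≥ 3 cells (`min_clone_size`), below which the ratio is mostly
pseudocount. Class summaries report % CTL-/APC-biased clones and the
geometric mean ratio per size class; between-group differences in the
CTL-bias fraction use a two-sided two-proportion z-test
(`statsmodels.proportions_ztest`).

## 5. Bulk-culture statistics

* Fold expansion: final/initial calculated absolute counts; the cohort mean
  is reported ± SEM with sample sd (ddof = 1). A raw-count variant accepts
  reseed fractions and computes Π Nₜ₊₁/(fₜ·Nₜ).
* Specific cytotoxicity: [(sample − negative)/(positive − negative)] × 100 %,
  reported unclamped with a clamped convenience value.
* Paired t-test: classical paired t on differences, df = n−1. Degenerate
  inputs: all-zero differences → t = 0, p = 1; zero-variance nonzero shift →
  p = 0 with a flag. For df = 2 the closed form p = 1 − |t|/√(2+t²) is
  verified to 1e-9.
* Spearman: Pearson on midranks; two-sided exact permutation p (all n!
  orderings) for n ≤ 9, t-approximation above. Constant vectors are a domain
  error.
* Cytokine heatmap prep: per-subtype median collapse, per-row centering and
  unit-variance scaling (sample sd), constant rows dropped with a warning,
  then average-linkage clustering with Euclidean distance on both axes. A
  single surviving row or column is returned unclustered.
* Published MFI p-values are compared after half-up rounding to 2 decimals.

## 6. Synthetic data generator

The generator emulates the structure of a day-14 expansion-culture dataset;
it is the substrate for all single-cell-level tests because raw study data is
not bundled.

**Clone sizes.** Zero-truncated negative binomial per class (rejection
sampling), so the repertoire spans singletons to clones of tens of cells.

**Clone-level bias.** Each clone draws one state-probability vector from its
class's Dirichlet prior and assigns member cells multinomially across the
five states. Default concentrations (each summing to 50):

| class | TRM-like | APC | CTL states | notes |
|---|---|---|---|---|
| Vδ1 / Vδ3 | 10 | 2.5 | 30 | strongly CTL-skewed |
| Vγ9⁻Vδ2⁺ | 10 | 7.5 | 22.5 | mildly CTL-skewed |
| Vγ9⁺Vδ2⁺ | 10 | 15 | 15 | APC-shifted |

Default clone classes: Vδ1 150 clones (μ=9, θ=2), Vδ3 120 (μ=7, θ=2),
Vγ9⁻Vδ2⁺ 120 (μ=6, θ=2.5), Vγ9⁺Vδ2⁺ 220 (μ=4, θ=3) — about 4,000 cells at
scale 1. These defaults are a deliberate power-analysis calibration: the
variance of a class's clone-mean state fraction is roughly
p(1−p)(1/(α₀+1) + E[1/s])/n_clones, so recoverability of the configured
Dirichlet means at a ~5,000-cell budget requires concentrated priors, enough
clones per class, and size spectra that are not singleton-dominated. The
recovery check estimates class means over clones with ≥ 3 cells, matching the
pipeline's per-clone floor.

**Expression.** Negative-binomial counts around a baseline mean (0.2) with
state programs applied as log2 elevations of named genes (e.g. APC-like:
CCR7, CD74, HLA-DR; exhaustive CTL: GZMB, LAG3, KLRG1, MKI67) and per-cell
lognormal library-size factors (σ = 0.2). The gene universe is the named
program genes padded with filler genes to `n_genes` = 1000.

**Protein.** CD45RA/CD27 intensities are lognormal with state-specific
locations, giving bimodal marker distributions the GMM gate can threshold.

**Chains.** Each clone gets class-consistent V/J calls and unique junctions;
cluster labels default to the true state labels with optional label noise.

**What it does not emulate.** Doublets and ambient RNA; dropout beyond NB
sampling; cell-cycle structure (the packaged s_phase/g2m signatures are
mostly outside the simulated universe and are skipped by the pipeline with a
warning); batch effects; clonotype sequencing errors; day-0 populations.

## 7. Pipeline and reproducibility

Configuration is pydantic-validated before any stage runs (missing paths fail
fast with exit code 2; compute errors exit 3 and name the failing stage and
input provenance). Every tabular output begins with `# config_hash=<sha256
prefix of the sorted JSON config>`; the manifest records hash, seed and
outputs, and no timestamps are written, so reruns are bit-identical. All
randomness flows from explicit seeds.

## 8. Limitations

* The cluster-state decision list assumes clusters are given (clustering
  itself is upstream); with noisy or mixed clusters the fallthrough state
  absorbs ambiguity.
* The packaged gene signatures are synthetic stand-ins aligned with the
  simulator's programs; analyses of real data should supply published
  signature files via `signature_file`.
* Exact tests are enumerative and only engage at small n (rank-sum ≤ 10 per
  group, Spearman n ≤ 9); beyond that, asymptotic approximations apply.
* Per-clone bias is undefined for clones below `min_clone_size`; summaries
  describe the analyzable (≥ 3 cells) repertoire, not all clones.
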