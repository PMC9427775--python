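# Methods

This note documents the statistical procedures implemented in `icfuse`,
the defaults they run under, the design of the synthetic cohort generator,
and the numerical choices made where the design was genuinely open.

## Preprocessing

Expression input is any variance-stabilized log-scale matrix (the pipeline
does not re-implement a count transform; the simulator produces data
directly on that scale). Methylation input is beta fractions in [0, 1];
statistics are computed on M-values, `M = log2(β/(1−β))` (betas clipped to
[1e-6, 1−1e-6] before the logit), while effect sizes are reported as Δβ —
the standard split, since M-values are closer to homoscedastic while beta
differences are the interpretable quantity.

For clustering, each layer goes through, in order: beta→M conversion
(methylation), removal of the array-platform batch term (per-feature least
squares with sum-to-zero coding, grand mean preserved), selection of the
top 200 genes / top 1000 probes by median absolute deviation (raw
`median|x − median|`; the 1.4826 consistency constant is omitted because
only ranks matter), and per-feature z-scoring with the population (n)
standard deviation — the denominator choice only rescales Euclidean
distances by a constant, but fixing it makes tests exact. Z-scoring is per
feature, the standard choice for distance-based clustering. TPM-level gene
filtering (drop genes with TPM < 1.0 everywhere or mean TPM < 0.5, plus
sex-chromosome genes when annotated) and the single-cell QC rules (cells:
≥1000 counts, 500–3000 genes, ≤15% mitochondrial; then genes detected in
<10 cells and mitochondrial genes, in that order) are provided for
real-data inputs.

## Similarity network fusion

Per layer, pairwise sample Euclidean distances d are converted to an
affinity with a locally adaptive Gaussian-density kernel,

    ε(i,j) = (μᵢ + μⱼ + d(i,j)) / 3,   μᵢ = mean distance of i to its K NN
    W(i,j) = exp(−d²/(2(αε)²)) / (√(2π)·αε),

symmetrized, with α = 0.5 and K = 10. Two row-stochastic operators are
derived: the full kernel P (diagonal 1/2, off-diagonal mass 1/2) and the
sparse local kernel S restricted to each sample's K nearest neighbors
(ties at the K-th neighbor resolved toward the lower index). Fusion
iterates `P⁽ᵛ⁾ ← S⁽ᵛ⁾ · mean_{u≠v} P⁽ᵘ⁾ · S⁽ᵛ⁾ᵀ` for t = 20 steps with
re-normalization after each step; S is computed once from the initial
affinities and held fixed (reference behavior of the published SNF
construction). The final network is the layer average, symmetrized, with
the diagonal reset by one more full-kernel normalization. Floors of 1e-12
on ε and on row sums guard degenerate inputs. The Gaussian *density* form
(with its 1/(√(2π)αε) prefactor) is used rather than a bare exponential
because it is what the reference implementation computes; on
well-separated data the final labels are invariant to this choice.

## Consensus clustering and model selection

For each candidate k in 2..8, the fused network is subsampled 1000 times
(80% of samples, without replacement — tests and the acceptance script use
100 repetitions, which gives consensus entries at a granularity of ~0.01
and reproduces the same selections at a fraction of the cost), each
submatrix is spectral-clustered (normalized-Laplacian embedding
D^{−1/2}SD^{−1/2}, top-k eigenvectors, row-normalized, k-means with 10
seeded restarts, labels canonicalized to first-occurrence order), and the
consensus matrix M_k records co-clustering frequency among co-sampled
pairs (never co-sampled pairs get 0 and are logged). The final partition
at each k cuts an average-linkage dendrogram built on the one-minus-Pearson
distance between consensus-matrix rows (the convention of applying the
configured distance to the consensus matrix itself).

Three stability metrics are attached per k: the cophenetic correlation of
that dendrogram, PAC (fraction of off-diagonal consensus entries strictly
inside (0.1, 0.9) — bounds exposed in config since the literature default
is adopted), and the mean silhouette of the final cut on 1 − M_k
(singletons contribute 0).

**Choosing k.** Metrics are quantized to 0.01 — differences below that are
resampling noise at these repetition counts — ranked (cophenetic and
silhouette high-good, PAC low-good), and the k with the best mean rank is
chosen. When several k tie for the best mean rank, the *largest* tied k is
selected. The rationale: coarse splits of a hierarchically structured
cohort are trivially stable, so a tie between a coarse and a fine solution
is exactly the situation in which the fine partition carries the
information; this mirrors how the original analysis retained the
five-cluster solution alongside an equally stable two-cluster split. A tie
spanning the entire candidate range (a fully degenerate input) falls back
to the smallest k.

## KNN label transfer

Feature selection computes per-class one-vs-rest Welch t statistics and
interleaves the per-class rankings round-robin (skipping already chosen
features) until n features are selected, guaranteeing balanced class
representation — the multiclass handling is unspecified in the tool this
mirrors, so the scheme is documented and configurable. Prediction scores
each class by Σ 1/d over the K nearest training samples (d floored at
1e-12; an exact-zero distance decides outright); ties break toward the
earlier class in training order. Hyper-parameters are tuned by
leave-one-out cross-validation over K ∈ {3, 5, 10} × n_features ∈
{3, 4, 5, 10, 20, 30, 50, 100, 250, 500, 1000, 2500, 5000, 10000}, with
feature selection re-run inside every fold — selecting once globally would
leak the held-out label and inflate accuracy. Ties prefer fewer features,
then smaller K. For label transfer the two preprocessed layers are stacked
into one feature matrix (neither single layer resolves all five clusters
under the complementary design); an external query cohort is standardized
on its own samples, as one would for an independent validation set.

## Enrichment scoring

The single-sample score follows the GSVA construction: per gene, a
Gaussian-kernel smoothed empirical CDF across samples
(`z_gj = mean_k Φ((x_gj − x_gk)/h_g)`, bandwidth `h_g = sd_g/4`, floored at
1e-8 for constant genes); per sample, genes ranked by z, ranks folded to
`r = |P/2 − p|`; a weighted KS random walk with in-set steps `r^τ`
(τ = 1, normalized within the set) and out-of-set steps 1/(P − m); score =
max positive + min negative deviation (`mx_diff`, the package default this
replicates), bounded in [−1, 1]. Preranked GSEA uses the classic weighted
KS statistic with exponent 1 on |metric|, a null of random same-size gene
sets, NES = ES / mean|null ES of matching sign|, an empirical two-sided P
over the full null (uniform under the null, and reaching 1/(n_perm+1) for
a maximally enriched set), and a sign-matched null-pool FDR estimate.

Cluster markers come from Welch t tests on the log-scale expression
(cluster vs rest, BH-adjusted) — a deliberate, documented stand-in for a
count-model Wald test, since the pipeline accepts variance-stabilized
input and does not model counts. Dual-omics markers additionally require a
mapped probe with |Δβ| ≥ 0.2 (BH P < 0.05) in the *opposite* direction to
the expression change (|log2FC| ≥ 2, BH P < 0.05). Developmental stages
are assigned per cluster as the most significantly upregulated signature
(Welch t on enrichment scores, BH across signatures, α = 0.05 — the cutoff
is not stated by the marker tool this mirrors, so 0.05 is adopted and
configurable), with the stem-cell (HSC/MPP) signature assigned only when
it is the sole significant one. Regulons are a simplified,
correlation-defined stand-in for mutual-information network inference:
positive targets with Spearman ρ ≥ 0.5 and BH P < 0.01, regulons under 10
targets dropped; outputs are labeled as such.

## Somatic variant filters and burden

The WES rule set: mapping quality ≥ 20, base quality ≥ 15, tumor and
normal depth ≥ 8, variant reads ≥ 4, tumor VAF ≥ 0.04 (SNV) / 0.10
(indel), normal VAF < 0.02, EBCall P ≤ 1e-5, Fisher P ≤ 1e-2; hotspot
positions instead use tumor VAF ≥ 0.02 and Fisher P ≤ 10^−1.5 with no
EBCall criterion. Post-exclusions (synonymous/ambiguous effects,
non-coding non-splice positions, single-strand support) apply to
non-hotspot candidates, following the published procedure. The deep-seq
rule set: the same quality gates with tumor depth ≥ 8, variant read pairs
≥ 4, VAF ≥ 0.02, EBCall P ≤ 1e-4, then exclusion of synonymous or
splice-site calls, single-strand calls, SNP-database SNVs, simple-repeat
calls, calls seen in paired normals, and calls with 0.45 ≤ VAF ≤ 0.55 in
copy-neutral regions unless confirmed somatic by paired WES. Each failing
record is annotated with the first violated rule in the published
numbering. Subclonality is VAF < 0.10, strict — the source text uses both
"<10%" and "≤0.10" in different places, so the threshold and strictness
are configurable. Burden counts distinct non-silent mutations in the
RTK–RAS gene set per case (duplicates of the same case/position/allele
collapsed; all passed calls counted, including hotspot rescues) and maps 0
→ none, 1–2 → low, ≥3 → high. The default gene set {KRAS, NRAS, FLT3,
PTPN11, BRAF, NF1, CBL} is the named recurrent genes plus canonical
pathway members, and is fully configurable since the authoritative
membership exists only as a figure.

## Survival

EFS intervals count failure to achieve remission as an event at day 0;
otherwise the recorded time and event stand. Kaplan–Meier, the k-sample
log-rank test and Cox proportional-hazards regression are delegated to
lifelines behind this module's interface; the Cox fit uses the Efron tie
approximation (appropriate for day-granularity ties). Zero event times are
kept as the earliest event time by shifting them to half the smallest
positive time, which leaves every risk-set ordering unchanged. Constant
covariates leave the partial likelihood flat and are reported as a null
effect (coef 0, HR 1) rather than passed to the optimizer.
Categorical covariates are reference-coded; by default the
reference cluster is the worst-prognosis group (highest event fraction),
matching the original model's choice of its most refractory subgroup.
Non-convergence or separation is flagged in the result, never silently
dropped.

## The synthetic cohort generator

The generator emulates the *statistical* structure of a 61-infant
dual-omics cohort; it makes no attempt at realistic genome coordinates,
linkage or sequence context.

**Clusters and layers.** Five planted clusters of 14/14/12/9/12. Under the
default *complementary* design, expression marker blocks (100 genes per
cluster, mean shift 2.0 log units, gene-level noise sd 1.0) are shifted by
the coarse two-way side of their cluster (the first two clusters form one
side), so expression alone separates only that split; methylation marker
blocks (200 probes per cluster, Δβ = 0.3, M-value noise sd 0.5) are
planted for every cluster except the last cluster of each side — the
unmarked clusters are defined by the absence of shifts plus the side
signal — so methylation alone resolves a four-way partition and only the
fusion resolves all five. Probe baselines are drawn mid-range with
headroom for the planted shift, and the planted M-shift is computed
against the noise-smoothed logistic transform (Gauss–Hermite quadrature)
so the *realized* mean Δβ equals the configured 0.3 rather than being
compressed by Jensen's inequality. Setting `complementary_design=False`
gives every cluster its own marker blocks in both layers, including a
subset of dual-marker genes (stronger shift, 3.5) paired one-to-one with
hypomethylated probes — the configuration used to test dual-omics marker
discovery and stage assignment.

**Cluster-unrelated variability.** Real cohorts carry high-variance
features unrelated to subtype (proliferation, immune admixture, age,
sex-linked probes), so MAD selection never returns a pure marker panel.
The generator therefore includes 200 genes with sd drawn from U(1.2, 1.8)
and 500 probes with M-sd from U(0.45, 0.6) and no cluster structure.
These values were fixed once, at design time, to place the simulator in
the regime the integrative analysis is built for: the fused network
maximally stable at both the coarse 2-split and the 5-cluster solution,
expression alone stable only at 2, methylation alone below 5 — the same
qualitative picture the model-selection rule (above) is designed to read.

**Batch.** Each sample is assigned one of two array platforms (p = 0.5);
the second platform adds a per-probe shift δ_p ~ N(0, 0.3) in M-value
space only, so the linear batch-removal step is exactly sufficient — a
deliberate simplification (real platform effects are not purely additive).

**Clinical covariates.** Fusion partners are drawn per cluster from
categorical distributions that concentrate MLLT1, MLLT3 and AFF1 in the
third, fourth and fifth clusters respectively, reproducing the
cluster–partner associations. Age, sex, WBC, CNS status and protocol are
drawn independently of cluster (the cohort's known prognostic factors did
not correlate with cluster assignment).

**Survival.** Exponential EFS times with per-cluster hazards (default
2.5e-4, 1.5e-3, 5e-4, 7e-4, 6e-4 per day — the second cluster is the
refractory one; no per-cluster hazards are published, so these are chosen
for test power, not biological fidelity), administrative censoring at
2000 days, OS hazards at 0.6× EFS. Exactly round(10%) of the
worst-cluster cases are marked as induction failures (EFS event at day 0).

**Mutations.** The refractory cluster draws its RTK–RAS burden from a
truncated Poisson on {1..6} with λ = 2.45 (mean ≈ 2.6); other clusters
have probability 0.4 of zero and otherwise 1 + Poisson(0.5) capped at 4,
giving ~70% of cases with at least one pathway mutation. VAFs are a
clonal/subclonal mixture: with probability 0.48 subclonal ~ U(0.02, 0.10),
else clonal ~ N(0.45, 0.05) truncated to [0, 1]. The subclonal floor is
0.02 — the deep-seq detection limit — so every planted cohort mutation
passes the filters and the post-filter burden matches the configured
means; clonal calls falling in the 0.45–0.55 germline band are emitted
with WES confirmation set, the same waiver the filter honors. A separate
candidate generator for filter-fidelity testing emits true calls
alongside artifacts that each violate exactly one rule (including
sub-floor VAFs), with ground-truth labels.

## Problem sizes used in tests

The test suite and the acceptance script run consensus clustering at 100
repetitions (not 1000) and evaluate planted-structure recovery over 10
generator seeds; calibration checks use 200 replicates (log-rank type-I
error, Cox coverage) and ~1000 pooled mutations (subclonal fraction).
These sizes give metric granularity and Monte-Carlo error comfortably
inside the asserted tolerances while keeping a full run to a few minutes.

## What passing tests do and do not show

The simulator's Gaussian blocks, additive batch term and exponential
survival are idealizations. Passing the planted-structure tests shows the
pipeline correctly integrates complementary layers, selects the planted
model, transfers labels and applies the published filter logic — it does
not show that five clusters exist in any particular real cohort, nor
validate the biological interpretation of the clusters. Filter fidelity is
exact by construction on planted candidates; on real sequencing data the
upstream caller's error model dominates. The Cox and log-rank calibration
checks operate under proportional hazards and independent censoring, which
real relapse processes may violate.

## Known limitations

- Fusion supports m ≥ 2 layers, but the pipeline surface is built around
  the two-layer (expression + methylation) case.
- Differential methylation does not yet take covariates; platform effects
  must be removed beforehand (the batch-removal step does this).
- Regulon inference is correlation-based by design and should not be read
  as a network reconstruction.
- The VCF importer handles minimal single-sample VCFs with AD/DP fields;
  annotation-rich VCFs should be converted to the TSV schema.
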