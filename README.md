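# icfuse

Dual-omics integrative subtyping of *KMT2A*-rearranged infant acute
lymphoblastic leukemia (ALL), as a tested, reusable Python pipeline.

*KMT2A*-rearranged infant ALL is the most refractory childhood leukemia,
and its only accepted molecular risk factor is the rearrangement itself.
Clustering patients on a single omics layer resolves no more than the two
coarse transcriptional super-groups (IRX-type vs HOXA-type). Integrating
the transcriptome with the DNA methylome, however, resolves five
integrative clusters (ICs) with distinct master regulators, fusion-partner
distributions, B-lymphopoietic developmental stages, RTK–RAS mutational
burden and prognosis. `icfuse` implements that full analysis for anyone who
wants to run it on their own cohort — or to study its statistical behavior
on simulated ones:

- **Similarity network fusion (SNF).** Per layer, the top-200 genes /
  top-1000 probes by median absolute deviation are z-scored and turned into
  sample affinity networks with a locally adaptive Gaussian kernel,
  `W(i,j) = N(d(i,j); 0, (α·ε(i,j))²)` with
  `ε(i,j) = (mean_K(i) + mean_K(j) + d(i,j))/3`, then merged by iterative
  cross-diffusion `P⁽ᵛ⁾ ← S⁽ᵛ⁾ · P̄⁽⁻ᵛ⁾ · S⁽ᵛ⁾ᵀ` (α = 0.5, K = 10, t = 20).
- **Consensus clustering** of the fused network: spectral clustering of
  resampled submatrices (pItem = 0.8, 1000 reps), with model selection over
  k = 2..8 by cophenetic correlation, proportion of ambiguous clustering
  (PAC) and mean silhouette.
- **KNN label transfer** to external cohorts: one-vs-rest t-statistic
  feature selection, inverse-distance-weighted votes, leave-one-out tuning
  over K ∈ {3, 5, 10} and feature counts {3, …, 10000}.
- **Single-sample gene-set enrichment** (GSVA-style weighted
  Kolmogorov–Smirnov random walk) and preranked GSEA, used to assign each
  cluster a B-lineage developmental stage.
- **Somatic variant filtering** for WES (with hotspot relaxations) and
  targeted deep sequencing (depth ≥ 8, variant reads ≥ 4, VAF ≥ 0.02,
  EBCall P ≤ 1e-4, plus SNP-database / simple-repeat / strand /
  germline-band exclusions), subclonality flagging (VAF < 0.10), and
  per-case RTK–RAS pathway burden with the 0 / 1–2 / ≥3 risk groups.
- **Survival analysis**: event-free survival with induction failure as an
  event at day 0, Kaplan–Meier, log-rank, and multivariate Cox regression
  (Efron ties).

A first-class synthetic-cohort generator (`icfuse.simulate`) reproduces the
statistical structure this analysis assumes — 61 samples in five clusters
of 14/14/12/9/12, complementary information across the two layers,
cluster-linked fusion partners, clonal/subclonal VAF mixtures, a heavily
RAS-burdened cluster and cluster-dependent survival — so every stage is
testable without access to patient data.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from icfuse import AnalysisConfig, SimulationConfig, simulate_cohort
from icfuse.pipeline import cluster_cohort

bundle = simulate_cohort(SimulationConfig(seed=1))
cfg = AnalysisConfig()
cfg.consensus.reps = 100
cfg.consensus.seed = 1
out = cluster_cohort(bundle.expression, bundle.methylation, cfg,
                     batch=bundle.batch)
print("chosen k:", out.fused_result.chosen_k)
print("ARI at k=5:", adjusted_rand_score(bundle.labels.values,
                                         out.fused_result.per_k[5].labels))
print("expression alone:", out.per_layer_results["expression"].chosen_k)
print("methylation alone:", out.per_layer_results["methylation"].chosen_k)
```

prints

```
chosen k: 5
ARI at k=5: 1.0
expression alone: 2
methylation alone: 4
```

i.e. the fused network recovers all five planted clusters exactly, while
expression alone sees only the coarse two-way (IRX/HOXA-like) split and
methylation alone only a four-way partition — the resolution gap that
motivates the dual-omics integration.

The same pipeline is available from the shell:

```sh
icfuse simulate --seed 1 --outdir cohort/
icfuse preprocess --matrix cohort/expression.tsv --layer expression_log \
    --outdir work/ --out expr_pre.tsv
icfuse preprocess --matrix cohort/methylation_beta.tsv --layer methylation_beta \
    --batch-file cohort/batch.tsv --outdir work/ --out meth_pre.tsv
icfuse fuse --expression work/expr_pre.tsv --methylation work/meth_pre.tsv --outdir work/
icfuse cluster --similarity work/fused_similarity.tsv --seed 1 --outdir work/
icfuse variants --variants cohort/variants.tsv --outdir work/
icfuse survival --clinical cohort/clinical.tsv --outdir work/
```

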