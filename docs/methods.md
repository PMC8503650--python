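# Methods

This note records the statistical models, conventions and design choices
behind `matriscore`, and what the synthetic studies used in the test suite
do and do not establish about real data.

## Single-sample enrichment (the ECM score)

The scorer is a nonparametric single-sample enrichment statistic for
continuous log2-scale expression (microarray-like data or log2 TPM):

1. **Kernel ECDF.** Per gene *i*, each sample's value is located within the
   gene's cross-sample distribution by a Gaussian-kernel ECDF,
   z_ij = mean_k Φ((x_ij − x_ik)/h_i), with bandwidth h_i = s_i/4 (sample
   standard deviation).  Because the bandwidth scales with the gene's own
   spread, scores are invariant to per-gene positive affine transforms —
   probe-level scale and offset differences cancel.  A zero-variance gene
   receives the neutral value 0.5 everywhere.
2. **Symmetric rank weights.** Per sample, genes are ranked by decreasing
   z (ties broken by input order) and weighted by r_ij = |N/2 − rank_ij|,
   so both extremes of the ranking carry weight.
3. **Random walk.** For each gene set, a weighted KS-like walk over the
   ranked list steps up by r/Σr at member genes (weight exponent τ = 1)
   and down by 1/(N − m) otherwise.  The set score is the signed sum of
   the maximum positive and minimum negative deviation ("max.diff"):
   sets coherently up in a sample score positive, coherently down score
   negative, incoherent sets shrink toward 0.
4. **Normalisation.** The pathway × sample matrix is divided by its
   largest absolute entry, mapping all scores into [−1, 1].  This global
   rescale is this package's convention for a "normalized" score; scores
   are therefore comparable within one scoring run, not across runs.

Sets with fewer than `min_size` (default 5) or more than `max_size`
(default 2000) genes present in the matrix are skipped.  The optimized
implementation is checked to 1e−12 against a straight-loop reference
written directly from the definition above (tests/_reference.py).

A caveat discovered while validating hub recovery: single-sample scores of
*disjoint* sets are not independent, because ranks are compositional — in
a small gene universe a strong co-expressed module displaces every other
gene's ranks and induces spurious negative correlation with unrelated set
scores.  With a module at ~3% of the universe (the regime of a ~300-gene
set against a genome-scale matrix) the effect is negligible; simulations
here therefore use 1000-gene universes with 30–60-gene modules.

## Pre-ranked GSEA

Genes are ranked by log2 fold-change (mean difference of log2 values,
ties broken lexicographically); hit steps are weighted by |log2FC|^1; the
enrichment score is the walk deviation of maximum absolute value.  The
null is gene-label permutation (positions of the set resampled uniformly),
appropriate because the input is a ranked list rather than a sample
matrix.  NES divides ES by the mean |null ES| of matching sign.  The
empirical p compares |ES| with the whole permutation null,
p = (1 + #{|ES₀| ≥ |ES|})/(n_perm + 1): this is uniform under the null and
reaches 1/(n_perm + 1) for a maximal score, which a sign-conditioned
denominator cannot do.  FDR is Benjamini–Hochberg within each ES sign.

## Survival machinery

* **Cox fits** maximize the Efron partial likelihood by Newton–Raphson
  (|Δβ| < 1e−9, ≤ 50 iterations).  Monotone-likelihood divergence
  (|β| > 15, e.g. perfect separation) is returned as a flagged
  non-converged fit rather than an exception.  The score test at β = 0 on
  tie-free data equals the log-rank chi-square to numerical precision —
  asserted as a cross-check, with `lifelines` as an independent oracle for
  β and its standard error.
* **Log-rank** accumulates observed-minus-expected with the hypergeometric
  covariance over shared event times; K-group via a generalized inverse.
* **Cutpoint.** The maximally selected rank statistic uses log-rank scores
  a_i = δ_i − Λ̂(t_i) (Nelson–Aalen cumulative hazard), which sum to zero;
  the statistic of a split is its standardized partial sum with the
  permutation variance m(n−m)/(n(n−1))·Σa².  Candidates are midpoints of
  consecutive distinct scores with both groups ≥ `minprop` (default 0.1)
  of the samples; ties go to the more balanced split, then the smaller
  cutpoint.  Only ranks matter, so any monotone transform of the score
  yields the same partition.
* **Post-selection optimism.** The p-value reported after dichotomizing at
  the best cutpoint is the plain post-split log-rank p, *not* the adjusted
  distribution of the maximally selected statistic; it is optimistic by
  construction.  The same phenomenon appears in treatment stratification:
  estimating the cutpoint on the treated subgroup's own survival leaks
  outcome selection into the within-stratum treated-vs-untreated test
  (measured null size ≈ 6–9% at nominal 5% in the planted null), whereas a
  full-cohort cutpoint stays calibrated (≈ 5%).  Both sources are exposed
  (`cutpoint_source`); the treated-subgroup default mirrors common
  practice and should be read accordingly.

## Screening, intersection, networks

Pathway screening classifies each score row by its univariate Cox fit at
unadjusted Wald p < α (default 0.05) — reflecting the uncorrected
screening scale typical of this analysis style; a flag switches to BH.
Cross-cohort intersection keeps pathways prognostic in *every* screen
regardless of direction, flagging direction-discordant ones.  Networks
connect rows with |Spearman ρ| above a threshold (default 0.5); hubs are
ranked by degree with ties broken by mean incident |ρ| then name, and
cross-cohort hubs by mean degree.  Constant rows are isolated (ρ
undefined).  At n = 200 samples the null |ρ| rarely reaches 0.35
(sd ≈ 1/√(n−1)), so 0.5 is a conservative edge rule.

## Consensus clustering

Each of `reps` iterations subsamples `item_frac` (default 0.8) of the
samples, builds one Ward dendrogram on Euclidean distances over per-gene
z-scored expression, and cuts it at every k.  consensus[i,j] =
co-cluster count / co-sampling count; the final partition at each k is
average-linkage clustering of 1 − consensus.  k is selected by the
delta-area criterion on the consensus-CDF (largest drop in the relative
area increment).  Structurelessness is flagged by PAC — the proportion of
off-diagonal consensus entries in (0.1, 0.9) at the chosen k — with
weak structure declared above 0.5; in simulation PAC separates pure noise
(≈ 0.9) from planted clusters (≈ 0.0) where raw area increments do not.

Partition agreement uses Cohen's kappa after optimal one-to-one class
matching (assignment problem), necessary because cluster labels are
arbitrary.  The matching maximizes over k! alignments and so carries a
small positive null bias (≈ +0.05 for three classes at n = 300);
`match_classes=False` gives the exactly centered plain kappa when the two
label spaces already correspond.  The permutation p applies the same
matching to every permuted labeling.

## Multi-omics couplings

TMB is the raw per-sample count of nonsilent MAF records (nonsilent =
classification not in {Silent, Intron, 3'UTR, 5'UTR, IGR, RNA, 3'Flank,
5'Flank}); no per-megabase denominator is applied, so compare only within
one calling pipeline.  CNV burden is the L1 norm of gene-level calls in
{−2…2}.  Associations are Spearman with mid-rank ties plus a two-sided
Wilcoxon rank-sum for the dichotomized contrast.  Methylation contrasts
report per-probe Δβ (high − low), Wilcoxon p, BH q, and mean Δβ per
region label and island status; probes collapse to genes by mean Δβ
before process-level pre-ranked enrichment.

## Batch adjustment

Cohort merging restricts to the common gene intersection, then removes
per-batch location/scale effects per gene with empirical-Bayes shrinkage
(ComBat-style: pooled standardization; per-batch gene means/variances
shrunk across genes under a normal/inverse-gamma prior with
method-of-moments hyperparameters; effects removed and the grand mean
restored).  Zero-variance guards: a globally constant gene is returned
unchanged; a gene constant within one batch gets a location-only
adjustment there.  Because shrinkage leaves a small residual batch
difference, the adjustment is a strong contraction but not exactly
idempotent: on planted-shift simulations a second pass moves values by
< 5% of the first pass.  Agreement with an independent implementation of
the same algorithm (`scanpy.pp.combat`) is within ~1e−3, attributable to
iteration stopping rules.

## Synthetic study conditions

One standard-normal latent activity f per sample couples every layer:

| layer | model | default |
|---|---|---|
| expression | module gene = a·f + √(1−a²)·ε on baseline 8 (log2 units) | a = 0.8, 60/1000 genes, 3 cohorts × 200 |
| batch | per-gene offsets ~ N(shift_c, 0.5) per cohort | shifts (0, +1, −0.5) |
| survival | T ~ Weibull(shape 1), hazard λ₀·exp(β_f·f)·θ | λ₀ = 0.02/month, β_f = 0.7, administrative censoring at the 0.7 event-time quantile |
| chemo | hazard ×θ_low below the latent median under treatment | 40% treated, θ_low = 0.5, θ_high = 1 |
| TMB | Poisson(exp(3 − 1.2·f + 2.5·ε)) | log-normal overdispersion mimics hypermutator tails |
| CNV | call probability σ(logit(0.15) − 0.8·f + 1.5·ε), sign random, 20% magnitude 2 | 200 genes |
| methylation | β = base + noise; −0.2 on Island probes in high-f samples | 500 probes, 40% Island |
| gene sets | planted module, 3 overlapping sub-sets (60% module genes), random decoys | 30 decoys of 20–50 genes |

The overdispersion terms are deliberate: without them the score–burden
rank correlation approaches −0.95, far stronger than any real cohort; with
them the recovered Spearman ρ sits near −0.4, the regime reported for
tumor data.  The generator is bit-reproducible from (config, seed); the
three canned fixtures ("prognostic", "interaction", "null") are frozen by
SHA-256 checksums tied to this generator and NumPy's PCG64 stream.

What these simulations do **not** emulate: probe-level microarray noise,
expression count distributions, segment-level CNV structure, methylation
autocorrelation along chromosomes, informative censoring, or confounding
between treatment assignment and prognosis.  Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under its
assumed model — not that the biological conclusions transfer to any
particular real cohort.

## Numerical and degenerate-input conventions

Events are coded 1 = observed, 0 = censored; times ≥ 0.  Missing
expression values are rejected, never imputed.  Gene identifiers are
opaque strings (no alias resolution).  Log2 transforms use offset 1 by
default.  Stage-level randomness in the pipeline derives from
SeedSequence([global_seed, stage_code]) with fixed per-stage codes, so
disabling one stage never perturbs another; summaries are byte-identical
across reruns at fixed (config, seed).  Problem sizes in the test suite
(e.g. 50-seed recovery loops at n = 150–600, 1000-gene universes) are
chosen as the smallest sizes at which the planted effects are comfortably
identifiable under the models above.

## Known limitations

* The post-cutpoint p-values are optimistic (no maximally-selected-rank
  adjustment); a formal treatment×score interaction Wald p is provided as
  supplementary output.
* The [−1, 1] score normalisation is run-relative; scores from separate
  runs are not directly comparable.
* Screening uses unadjusted p by default; with thousands of pathways the
  intersected set still contains false positives by design.
* TMB is a raw count, not per-megabase.
* Consensus clustering with small `item_frac`·n can leave sample pairs
  never co-sampled (consensus 0, warned).
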