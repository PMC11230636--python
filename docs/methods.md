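# Methods

This note documents the models and procedures implemented in `driversub`,
the parameters that matter, the numerical conventions that were fixed where
the method description left them open, and what the synthetic cohort does
and does not emulate.

## Domain mutation burden

**Model.** Each gene family's shared protein domains are tested for excess
mutation burden under a null in which every residue of a protein is equally
likely to mutate. For a domain carried by genes *g* with protein lengths
*L_g* and union domain coverage *c_g* residues, one permutation re-places
each gene's observed mutation total *m_g* independently and uniformly over
its residues (with replacement; multiple hits on one residue are allowed)
and records the family-wide in-domain count. Because placements are
independent and uniform this count is distributed exactly as
Σ_g Binomial(m_g, c_g / L_g), and the implementation samples it that way —
an exact reformulation of the permutation, not an approximation. The
p-value after *i* permutations is (#{permuted ≥ observed} + 1) / (i + 1):
the ≥ makes the test conservative at ties and bounds p below by 1/(i+1).

**Dispersion entropy.** S = −Σ P_i ln P_i / ln n over the n carrier genes,
with P_i the gene's share of the domain's mutations and 0·ln 0 ≡ 0. S is
invariant to gene order and to scaling all counts. Conventions: a domain
with zero mutations has undefined S (returned as NaN, never "high
entropy"); a single-carrier domain has S = 0, so it can never pass the
dispersion filter — it carries no family-dispersion evidence.

**Parameters.** n_perm = 9999 (resolves p to 10⁻⁴; configurable), BH
correction across all tested domains at α = 0.05, entropy cutoff 0.5.
Coordinates are 1-based closed intervals; a mutation at position p is
in-domain iff start ≤ p ≤ end; overlapping instances of *different*
domains each count a mutation once. TMB = non-silent coding mutations /
38 Mb; samples with TMB strictly above 30/Mb are excluded (a sample at
exactly 30.0 is retained).

## Differential analysis and DDG integration

Expression and miRNA differences use the two-sided Mann–Whitney U test
(normal approximation with tie and continuity correction; a feature
constant across both groups gets p = 1), BH correction, and
log₂FC = log₂((mean_t + 1)/(mean_n + 1)); calls require |log₂FC| > 1,
adjusted p < 0.05 and at least one group mean ≥ 1. Methylation probes are
called DMPs at |Δβ| > 0.2 and adjusted p < 0.05. CNV gain (loss) requires
strictly more than 20 % of samples with score above 1 (below −1).

A DDG is a family-member DEG with at least one evidence link whose
Spearman correlation against the gene's tumor expression passes |ρ| > 0.2
at BH-adjusted p < 0.05. Correction is applied within each evidence batch
(all methylation pairs together, all miRNA pairs, all CNV pairs), since the
batches are separate screens. Evidence combination across layers is a
union by default (any one layer suffices) with an intersection switch; no
sign constraint is imposed on ρ — direction is reported so users can
filter. Constant regulator or target vectors are skipped with a warning.

## Subtype recognition model

**Propagation.** The binary patient × gene matrix F₀ (1 iff the sample has
≥ 1 non-silent mutation in the gene) is smoothed by
F_{t+1} = αF_tA + (1−α)F₀ with α = 0.7, stopping when the Frobenius norm
of the step falls below 10⁻⁶ ("matrix norm" fixed as Frobenius). A is the
row-stochastic normalization D⁻¹W of the gene-interaction network; genes
absent from the network or isolated keep their mass through a
self-indicator row. Row-stochastic A makes F·A an averaging operator, so
each patient's row sum is conserved exactly — a testable invariant — and
the iteration's fixed point equals the resolvent form
(1−α)F₀(I−αA)⁻¹. Note the stop rule leaves a residual to the fixed point
bounded by tol·α/(1−α) (≈ 2.3·tol at α = 0.7); tests that compare against
the closed form iterate to a tighter tolerance. An optional switch applies
rank-based quantile normalization across patients after smoothing
(default off: the analysis chain uses only the smoothed profiles).

**Expression layer.** log₂(x+1), then per-gene z-scores across samples
using the population (ddof = 0) standard deviation; zero-variance genes
become all-zero rows with a warning. (The classifier's mean-interval
filter, by contrast, uses the sample sd, ddof = 1 — the two conventions
are fixed per stage and documented here because upstream descriptions of
this style of analysis leave them open.)

**Similarity network fusion.** Per layer, squared Euclidean sample
distances become a scaled-exponential kernel
W_ij = exp(−d²_ij / (2(μ ε_ij)²)) with the local bandwidth
ε_ij = (T_i + T_j + d_ij)/3, T_i the mean distance from i to its K nearest
neighbors (K = 20, μ = 0.5). Each layer keeps a row-normalized full kernel
(off-diagonal mass ½, diagonal ½) and a K-NN-sparsified local kernel; T =
20 rounds of cross-diffusion propagate each layer's local kernel over the
average of the other layers' full kernels (with a single layer, over
itself), re-normalizing and symmetrizing each round. W is the symmetrized
average of the diffused layers. K is reduced to n−1 with a warning when it
reaches the sample count.

**Consensus clustering.** Per repetition (5000 by default; the demo
profile and the test suite use 150–500, which changes only Monte-Carlo
resolution of the consensus frequencies), ⌈0.8·n⌉ samples are drawn
without replacement; each is represented by its W row restricted to the
subsample; pairwise distance is 1 − Spearman correlation of those rows
(the distance is only meaningful row-wise on a similarity matrix);
average-linkage hierarchical clustering is cut at each k in 2…6. The
consensus M(i,j) is the co-clustered count over the co-sampled count;
never-co-sampled pairs get 0 with a logged counter (negligible at the
default sampling intensity). Final labels per k come from average-linkage
clustering of 1 − M. Subsampling is the only seeded randomness; linkage
tie-breaks follow the deterministic input order.

**Model selection.** Per-sample silhouettes use the distance
D = max(W) − W with the diagonal of W set aside first: self-similarity
(the kernel diagonal) carries no between-sample information and would
otherwise compress all informative distances into a narrow band.
Singleton clusters get silhouette 0; any k whose cut degenerates to fewer
than k clusters is skipped. The chosen k maximizes the mean silhouette
(ties to the smaller k); clusters are renamed CLASS A, CLASS B, … by
descending size, ties by first occurrence.

## Characterization

CIN ratio = arms with score strictly beyond ±0.1 / arms present (missing
arms are excluded from numerator and denominator). Subtype × mutation
contingency tables use chi-square with continuity correction, switching to
Fisher's exact test when any expected count is below 5 (the standard
rule; the choice matters only for sparse tables). Survival comparisons use
the two-group log-rank test and Kaplan–Meier medians (first time the
estimate drops to ≤ 0.5; missing when never reached), both via lifelines.

## Classifier

Candidates: subtype-differential genes at adjusted p < 0.001 and
|log₂FC| > 1 (the same differential machinery and mean-≥1 rule as the
tumor/normal analysis). Interval filter: per subtype, [μ−σ, μ+σ] on
log₂(x+1) expression with sample sd; intervals are closed, and a shared
endpoint counts as overlap (the conservative reading). Panel: elastic-net
logistic regression (l1_ratio 0.5, saga) over a descending C grid
(100, 10, 1, 0.1, 0.01), C chosen by stratified 5-fold CV accuracy with
ties resolved toward the least-regularized model — the elastic net's
grouping effect then keeps correlated informative genes together rather
than arbitrarily dropping redundant ones; the panel is the nonzero-
coefficient genes, with a fallback to the full interval-pass set (warned)
if every C zeroes everything. Panel size is data-driven, never forced.
Training: stratified 70/30 split, features standardized on the training
split, linear soft-margin SVM with C grid-searched by stratified CV
(the backend is pluggable: anything with fit/predict/decision_function).
Metrics follow the printed confusion-matrix formulas; MCC is reported on
its natural [−1, 1] scale; the positive class is the last subtype in
sorted label order (CLASS B for two classes). Pseudo-bulk profiles are
per-sample sums of single-cell expression, pushed through the same
log-transform and training-set standardization.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes.
Defaults (the study conditions of the test suite): 120 tumors, 50 %
subtype B, 10 families × 6 members plus 140 background genes (protein
length 500, family domain spanning residues 101–200), 3 hotspot domains
receiving Poisson(1.5) in-domain mutations per subtype-B sample allocated
uniformly across family members (high planted entropy), background
mutations at Poisson(0.02) per gene per sample, and one always-planted
low-entropy decoy domain whose subtype-neutral burden lands in a single
member — exercising the entropy filter. Expression: per-gene log₂
baselines U(2, 8); 30 planted DEGs get +2 log₂ units in subtype-B tumors;
Gaussian noise sd 0.5; normals (n = 60) share the baselines. The planted
DEGs split 10/10/10 into promoter-methylation evidence (tumor β shifted
−0.3 and tracking expression, normal β flat), miRNA evidence (a regulator
anti-correlated within tumors, slope −0.8, and ~4× lower in tumor than
normal), and CNV evidence (score tracking expression, gain in most B
samples). Arm CNV: 39 arms (p+q of 22 autosomes minus acrocentric p arms),
altered with probability 0.5 per arm in subtype B vs 0.1 in A (|score|
drawn from ±U(0.15, 0.5), quiet arms U(−0.05, 0.05)). Survival:
exponential event times with subtype-A median 20 months and hazard ratio
2 for B, independent exponential censoring tuned to ≈ 30 % censored.
Network: within-family edges with probability 0.8, background pairs 0.01,
unit weights.

Gene-level parameters — baseline expression, which genes carry planted
effects, miRNA base abundances — are drawn from a fixed structure stream
shared by all cohorts, while the config seed drives per-sample
realizations. They are properties of the simulated disease process, so
independently seeded cohorts are draws from one population and a
classifier trained on one cohort transfers to another, as it must for
external-validation-style tests. The null configuration zeroes every
planted effect (fold change 0, no hotspot or decoy burden, flat β, no
miRNA coupling, arm probability equal between subtypes, hazard ratio 1).

What the generator does **not** emulate: realistic mutational signatures
or gene length variation, batch effects, library-size or GC biases,
non-exponential survival, cross-layer couplings beyond the planted
correlations, and population substructure. Passing tests therefore
demonstrate correctness of the algorithms under the planted model, not
robustness to the full messiness of real cohorts; thresholds tuned to
these conditions (effect sizes, rates) are study conditions, not
recommendations for real data.

## Problem sizes and determinism

The test suite runs the full pipeline at the default cohort size with
consensus repetitions reduced to 150–500 and n_perm = 999, keeping
Monte-Carlo resolution adequate for the planted effect sizes. All
randomness flows from one global seed expanded into independent per-stage
streams (burden permutations, consensus subsampling, classifier CV/split),
so any stage can be re-run in isolation and a run manifest plus seed
reproduces a run exactly. Known limitations: the pipeline assumes a single
harmonized expression matrix (cross-cohort batch correction is upstream);
the file-based entry point covers the synthetic bundle layout; and with
two omics layers the SNF implementation is exercised as in the analysis —
more layers are supported generically but not tuned.
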