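# driversub

Driver-gene-based multi-omics subtyping of hepatocellular carcinoma (HCC),
packaged as a tested, reusable pipeline. Tumor cohorts are heterogeneous;
stratifying them into molecular subtypes with coherent biology and distinct
prognosis is a prerequisite for precision treatment. `driversub` builds such
subtypes from the genes most likely to matter — known driver genes and
their family members — rather than from genome-wide features.

The pipeline has five stages:

1. **Stratification genes from domain mutation burden.** For every protein
   domain shared by the members of a gene family, a permutation test asks
   whether the domain accumulates more mutations than expected when every
   residue of each protein is equally likely to mutate; the p-value after
   *i* permutations is `(#{permuted ≥ observed} + 1) / (i + 1)`. The
   dispersion of a domain's mutations across its *n* family carriers is
   scored with a normalized Shannon entropy

   `S = −Σᵢ Pᵢ ln Pᵢ / ln n`,

   where `Pᵢ` is gene *i*'s share of the domain's mutations: S → 1 for
   mutations spread uniformly across the family (a candidate novel
   oncogenic alteration), S → 0 when one gene absorbs them all.
   Stratification genes are family genes mutated in a domain that is both
   significant (Benjamini–Hochberg-adjusted p < 0.05) and high-entropy
   (S > 0.5). Hypermutated samples (TMB > 30 mutations/Mb, with TMB =
   non-silent coding mutations / 38 Mb) are excluded first.
2. **Driver-dysregulated genes (DDGs).** Family genes differentially
   expressed between tumor and normal (Mann–Whitney U, BH-adjusted
   p < 0.05, |log₂FC| > 1, group mean ≥ 1 TPM) whose dysregulation is
   supported by a correlated regulatory layer — a differentially methylated
   promoter/body/enhancer probe (|Δβ| > 0.2), a differentially expressed
   miRNA targeting the gene, or a recurrent copy-number gain/loss (> 20 %
   of samples beyond ±1) — with Spearman |ρ| > 0.2 at BH-adjusted p < 0.05.
3. **Subtype discovery.** The binary patient × stratification-gene mutation
   matrix F₀ is smoothed by network propagation over a gene-interaction
   network, `F_{t+1} = αF_tA + (1−α)F₀` (α = 0.7, stop when
   ‖F_{t+1}−F_t‖_F < 10⁻⁶, A row-stochastic); the smoothed profiles are
   fused with z-scored log₂(TPM+1) DDG expression by similarity network
   fusion (K = 20 neighbors, kernel bandwidth μ = 0.5, T = 20 diffusion
   rounds) into one patient similarity matrix W; consensus clustering of W
   (5000 subsamples of 80 % of patients, Spearman distance between W rows,
   average-linkage hierarchical clustering) yields cluster labels for
   k = 2…6, and the k with the best mean silhouette
   `Sil(i) = (b(i)−a(i)) / max(a(i), b(i))` is chosen. Clusters are named
   CLASS A, CLASS B, … by descending size.
4. **Characterization.** Chromosomal instability per sample (CIN ratio =
   arms with |score| > 0.1 / total arms), subtype × mutation association
   tests (chi-square, or Fisher's exact when expected counts drop below 5),
   and Kaplan–Meier / log-rank survival comparison.
5. **Subtype classifier.** Subtype-differential genes (BH p < 0.001,
   |log₂FC| > 1) are filtered by disjoint per-subtype mean intervals
   [μ−σ, μ+σ], reduced to a sparse panel by cross-validated elastic-net
   logistic regression, and used to train a soft-margin SVM on a stratified
   70/30 split, evaluated with ACC, SEN, SPE and MCC. The trained model
   classifies new expression profiles, including pseudo-bulk profiles
   summed from single-cell data.

Because the real cohorts behind this kind of analysis are controlled-access,
the package ships a first-class synthetic-cohort generator
(`driversub.synthetic`) that plants two subtypes with known ground truth —
domain-localized mutation hotspots dispersed across family members, a
low-entropy decoy domain, subtype-differential expression, correlated
methylation/miRNA/CNV evidence, arm-level instability and a survival hazard
difference — so every stage can be validated against planted truth.

## Worked example

```sh
driversub run --demo --seed 1 --out demo_out
```

runs the full pipeline on the default synthetic cohort (120 tumors, two
planted subtypes) and prints:

```
chosen k: 2
mean silhouette: 0.209
ARI vs planted labels: 0.967
log-rank p: 0.0425
classifier ACC: 0.972 MCC: 0.946
outputs written to demo_out
```

The model selects k = 2 subtypes; the adjusted Rand index of 0.967 means
the recovered CLASS A / CLASS B labels almost perfectly match the planted
subtypes (1.0 would be identical up to renaming). The planted subtype with
higher chromosomal instability and hazard separates in survival (log-rank
p = 0.043), and the gene panel chosen by the classifier stage labels
held-out samples with 97 % accuracy (MCC 0.95). `demo_out/` contains the
per-sample assignments with silhouettes, the domain-burden table, the DDG
evidence table, CIN and mutation-association tables, the classifier panel
and metrics, and a `run_manifest.json` recording every parameter and seed
(the same seed reproduces the run bit-for-bit).

The same stages are available as a library:

```python
from driversub import SyntheticCohortConfig, generate_cohort, analyze_domain_burden

cohort = generate_cohort(SyntheticCohortConfig(seed=1))
results = analyze_domain_burden(cohort.mutations, cohort.domains,
                                cohort.protein_lengths, n_perm=9999, seed=1)
```

`driversub simulate --seed 3 --out cohort_dir` writes a complete synthetic
cohort (MAF-like mutations, all omics matrices, network, clinical table,
planted truth labels) as tab-separated text.

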