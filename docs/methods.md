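# Methods

This note documents the statistical models, conventions, and design choices
behind `breedqc`, in the order the pipeline applies them.

## Genotype coding

All analyses run on a samples × markers grid of allele dosages: each cell
counts copies (0/1/2) of the marker's *counted allele*, with a dedicated
missing sentinel distinct from 0.  For VCF input the counted allele is ALT.
KASP-style call grids carry no REF/ALT, so the counted allele is the
alphabetically first allele observed at the marker — a deterministic
convention that needs no reference sequence.  Coordinates are 1-based as in
VCF; marker ids (not positions) are the join key across panels.  Every
distance, diversity, and differentiation statistic here is invariant to
which of the two alleles is counted.

## Quality control

Markers failing call rate (< 0.85) or minor allele frequency (< 0.05) are
removed first, then samples failing call rate (< 0.85) on the retained
markers.  Call rate and MAF are evaluated on the same snapshot of the matrix
within a sweep, so the two marker criteria cannot interact through removal
order.  Removing samples can in turn drop a marker's call rate below
threshold, so the marker → sample sweep repeats until nothing changes; the
filter is therefore idempotent, and the report records every removal with
its reason.  Thresholds are inclusive (a value equal to the minimum passes).
A sample call-rate threshold of 0.80 is also in routine use; it is exposed
as a parameter rather than guessed as canonical.

## Identity-by-state distance and duplicates

d(i,j) = Σ_l |g_il − g_jl| / (2·L_ij) over the L_ij loci called in both
samples (pairwise deletion), which equals 1 − (proportion of alleles
identical by state) — the allele-sharing distance convention of standard
SNP-QC tooling.  Pairs sharing no loci get an undefined (NaN) distance,
excluded from duplicate calls with a warning.

Duplicates are the connected components (size ≥ 2) of the graph with an
edge wherever d ≤ τ (default τ = 0.05, roughly five times the per-sample
assay error rate of ~1 %).  Components rather than cliques: field and
crossing-block copies of the same clone form chains in practice, and a
chained group is one identity.  The lexicographically smallest id in each
group is nominated as representative for the deduplicated set.

## Relationships and PCA

The additive genomic relationship matrix is VanRaden's first method:
W = dosages − 2p per marker (missing cells imputed to the marker mean,
hence 0 after centring, keeping A positive semi-definite), and
A = WWᵀ / (2 Σ_l p_l(1−p_l)) over polymorphic markers.  PCA is the
eigendecomposition of A, scores scaled by √eigenvalue, sign fixed so the
largest-magnitude loading in each component is positive; a direct PCA of
centred dosages is available as an alternative route.

## Hierarchical clustering and the number of clusters

Clustering uses Ward's minimum-variance criterion in the variant that
squares the input dissimilarities inside the Lance–Williams update (R's
`Ward.D2`; SciPy's `ward`), applied to the IBS distance matrix.  Given a
distance matrix, diagnostics operate on its classical-MDS embedding
(double-centred squared distances, positive-eigenvalue components), so that
within-cluster sums of squares are well defined.

Three K-selection diagnostics are computed for k = 1..k_max (default 10):

- **elbow** — argmax of the second difference of W_k (the sharpest bend in
  the within-cluster sum of squares);
- **silhouette** — argmax of the mean silhouette width (k ≥ 2);
- **gap statistic** — Gap(k) = E*[log W_k] − log W_k with B = 100 reference
  data sets drawn uniformly over the PCA-aligned bounding box of the
  embedding (the method's standard variant), choosing the smallest k with
  Gap(k) ≥ Gap(k+1) − s_{k+1};

plus a majority consensus with ties broken toward the smallest K.  All
reference draws are seeded; clustering of the same matrix is deterministic.

## Admixture model

The likelihood is the standard unsupervised admixture model for unlinked
biallelic loci: dosage g_il ~ Binomial(2, p_il), p_il = Σ_k q_ik f_kl, with
q_i the individual's ancestry proportions and f_k the ancestral allele
frequencies.  It is maximised by expectation–maximisation with the
closed-form updates (allele-origin responsibilities in the E-step; weighted
frequency and ancestry updates in the M-step), rather than the quasi-Newton
block relaxation of the commonly used tool — the same optimum, slower
convergence, acceptable at desk scale, and a genuine re-implementation
rather than a wrapper.  Missing cells are skipped; F is clipped to
[1e-6, 1−1e-6] to keep the likelihood finite; the log-likelihood trace is
non-decreasing by construction (asserted in tests); the binomial-coefficient
constant is omitted from the reported log-likelihood.

**Cross-validation over K** masks entries rather than samples (a held-out
sample has no q̂, so sample holdout is undefined): all non-missing cells are
partitioned into 10 disjoint folds, each fold is masked during fitting, and
the held-out cells are scored by binomial deviance of g against 2p̂; the CV
error per K is the mean per-cell deviance and the selected K its argmin.
CV fits use a looser tolerance (1e-5) and iteration cap (500) than final
fits (1e-6, 2000) since only the deviance ranking matters.

**Membership**: a sample is assigned to its majority ancestry when
max_k q_ik ≥ 0.80 (inclusive), otherwise labelled "admixed"; argmax ties
break toward the lowest component index.

## Cross-panel concordance

Cluster labels are arbitrary per panel, so labels are matched by
maximum-agreement (Hungarian) assignment on the contingency table over the
shared samples; the dissimilarity is the percentage of shared samples whose
matched labels still disagree, reported alongside the adjusted Rand index
and the overlap of the two panels' duplicate-pair sets.

## Diversity statistics

Per population and locus: H_o is the heterozygote fraction among non-missing
calls; gene diversity uses Nei's unbiased estimator with the heterozygote
correction, H_s = n/(n−1)·(1 − Σ_a p_a² − H_o/(2n)); a plain 2p(1−p) option
exists for comparison.  Population values are means over loci polymorphic in
that population, and F_IS = 1 − H̄_o/H̄_s.  Allelic richness rarefies each
locus to a common number of gene copies g (default: twice the smallest
per-population per-locus call count) via the hypergeometric expectation
Ar = Σ_a [1 − C(N−N_a, g)/C(N, g)], averaged over loci.

## β-F<sub>ST</sub>

Differentiation uses allele-matching probabilities: M_ii is the probability
that two distinct gene copies drawn from population i match, and M_ij the
cross-population matching probability Σ_a p_ai p_aj.  With matching
probabilities averaged over loci *before* the ratio, the population-specific
estimate is β_i = (M_ii − M_B)/(1 − M_B) with M_B the mean over ordered
population pairs, and the pairwise estimate replaces M_ii with
(M_ii + M_jj)/2 and M_B with M_ij.  Confidence intervals are percentile
bootstrap (2.5 %/97.5 %) over loci, 1000 replicates by default, seeded.
A monomorphic panel makes the ratio 0/0 and raises.  The conventional
interpretation bands are: < 0.05 low, 0.05–0.15 moderate (boundaries
inclusive on the moderate side), > 0.15 considerable.

## AMOVA

Variation is partitioned at the gene-copy level: each diploid sample
contributes two allele values per locus (heterozygotes split 0/1), and
squared-difference sums of squares are accumulated over loci into three
strata — among groups, among individuals within groups, within individuals.
Missing calls are excluded locus-wise from the sums of squares, while
degrees of freedom come from the design (G−1, N−G, N); the two agree exactly
on complete data, which is how the moment identities are tested.  Moment
estimators with the unequal-size coefficient
n″ = 2(N − Σ_g n_g²/N)/(G−1) solve

    MS_within            = σ²_c
    MS_among-individuals = σ²_c + 2σ²_b
    MS_among-groups      = σ²_c + 2σ²_b + n″σ²_a

and percentages are each σ² over their sum.  Negative components are
reported as-is with a warning, never truncated — truncation would hide
pathological inputs, and percentages may then fall outside [0, 100].
`amova_from_ms` applies only the moment equations and percentage step to
externally supplied mean squares, which is how reported AMOVA tables can be
back-solved and checked.

## Phenotypes and trait-linked markers

Root dry matter content is 100·dry/fresh (percent); carotenoid content from
the portable photometer is (sample weight / slurry volume) × device reading
(µg/g).  Descriptives report CV = SD/mean and Shapiro–Wilk normality;
correlations are pairwise-complete Pearson r with two-sided t-test p-values,
flagged at α = 0.05.

Segregation tables report genotype-class counts with percentages rounded
half-up to 2 decimals, matching how such tables are printed; the
favorable-carrier percentage is the sum of the two rounded class
percentages (heterozygotes + favorable homozygotes), the totalling
convention such reports use.  Kruskal–Wallis (tie-corrected, chi-square
reference) tests phenotype differences between genotype classes, with
significance stars at 0.05 / 0.001 / 0.0001.

Phenotype QTL classes default to: CMD mean severity ≤ 2.0 (resistant),
TCC ≥ 15 µg/g by photometer (color chart ≥ 4 when the photometer value is
absent), DMC ≥ 30 % — boundaries inclusive, all configurable; these
defaults are assembled from the trait conventions rather than a single
stated rule, so reported FPR/FNR values depend on them and the package does
not claim to reproduce any particular published FPR/FNR numerically.
Marker QTL+ calls require ≥ 1 favorable allele under the dominant model
(default, the segregation pattern such markers typically show) or a
favorable homozygote under the additive option.  FPR is the percentage of
phenotype-QTL− samples the marker calls QTL+; FNR the converse; a rate with
an empty phenotype class is undefined and reported as absent.

## Synthetic data generator

The generator emulates the study-shaped data: a dense panel (default 92
samples from 4 source populations × 6602 markers), a sparse panel (36
markers: a random subset plus all trait-linked markers), 5 % missingness,
1 % genotyping error, and 12 planted duplicate pairs.  Genotypes follow the
Balding–Nichols drift model — ancestral frequencies Uniform(0.05, 0.95),
population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with dial-able target
F, individual frequencies Q-weighted, dosages Binomial(2, p) — chosen
because the structure and differentiation claims need a generator whose
true F_ST is known.  Ancestry rows are unit vectors when
`admixture_alpha = 0`, otherwise symmetric Dirichlet(α).  Duplicates are
appended copies re-called with a per-allele-copy flip rate equal to the
error rate, so a pair's expected IBS distance ≈ the error rate.  Planted
trait loci carry penetrance/phenocopy rates: carrier status (per effect
model) draws the binary QTL state, and the continuous phenotype is drawn
around class centers separated by the configured effect size (defaults:
2 severity points for CMD, 10 percentage points for DMC, 10 µg/g for TCC;
within-class SD = effect/6), truncated to the correct side of the class
threshold so the planted state is recoverable.  This gives closed-form
FPR/FNR expectations.  Same seed ⇒ bit-identical panels.

What the generator does *not* emulate: linkage disequilibrium, pedigree
structure beyond the planted duplicates, allele-frequency-dependent call
error, genotype-by-environment variation in phenotypes, or informative
missingness.  Passing tests therefore demonstrate correctness of the
estimators under independent-locus, random-missingness conditions, not
robustness to those real-data features.

## Problem sizes and numerical choices

Test and validation runs use desk-scale panels chosen once: duplicate
recovery on 20 panels of 30 samples × 300 loci + 12 planted pairs;
β-F_ST on 2 × 100 samples × 2000 loci; admixture recovery on 120
Dirichlet(0.2)-admixed samples × 500 loci at K = 3, F = 0.2; K selection on
a 4-population, 100 × 300 panel at F = 0.15.  The FPR/FNR check compares the
mean observed-minus-expected deviation over 25 replicate n = 300 cohorts,
since a single cohort's rate has ~4-point sampling SD.

Ties: argmax ties break to the lowest index throughout; consensus-K ties to
the smallest K; merge ties in clustering to the lowest-index pair (SciPy's
deterministic ordering).  Degenerate inputs raise explicit errors rather
than returning silent results: empty matrices, monomorphic panels for GRM
and β-F_ST, populations smaller than two for diversity and AMOVA, and
rarefaction sizes below two gene copies.

## Known limitations

- The admixture EM can converge slowly near boundary optima and is run from
  a single seeded start by default; multi-start is a caller-level loop.
- AMOVA with missing data mixes locus-wise sums of squares with design-level
  degrees of freedom; at high missingness the variance components are
  approximations.
- The gap statistic on classical-MDS embeddings of non-Euclidean distance
  matrices inherits the embedding's truncation of negative eigenvalues.
- β-F_ST confidence intervals resample loci, not individuals; they reflect
  locus-sampling uncertainty only.
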