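# breedqc

Quality control and marker validation for SNP genotyping in plant breeding
programs, built around the workflow used to characterize biofortified cassava
breeding material: a dense reduced-representation panel (thousands of
DArTseq-style SNPs) for diversity analysis, and a sparse KASP-style panel
(tens of SNPs) for routine sample identity checks and trait-linked marker
screening.

It is aimed at breeding-program data analysts who receive dosage-coded
biallelic genotype calls plus phenotypes and need to answer, reproducibly:
Which markers and samples survive QC?  Which samples are duplicates?  How is
the population structured, and how much variation lies between groups?  And
do the trait-linked markers actually predict the phenotype?

## What it computes

- **QC filters** — markers with call rate < 0.85 or MAF < 0.05 removed, then
  samples with call rate < 0.85 (both thresholds configurable).
- **Identity-by-state distance & duplicates** — for samples *i, j* over the
  *L<sub>ij</sub>* loci called in both:
  *d(i,j) = Σ<sub>l</sub> |g<sub>il</sub> − g<sub>jl</sub>| / (2 L<sub>ij</sub>)*
  = 1 − (proportion of alleles shared).  Pairs with *d* ≤ 0.05 are grouped
  into connected components of putative duplicates.
- **Structure** — Ward.D2 hierarchical clustering with elbow / silhouette /
  gap-statistic selection of K; the ADMIXTURE/STRUCTURE likelihood
  *g<sub>il</sub> ~ Binomial(2, Σ<sub>k</sub> q<sub>ik</sub> f<sub>kl</sub>)*
  maximised by EM, with entry-holdout cross-validation over K and a ≥ 0.80
  ancestry cutoff for group membership; Hungarian-matched concordance
  (dissimilarity % and adjusted Rand index) between two panels' clusterings.
- **Diversity** — H<sub>o</sub>, Nei's unbiased H<sub>s</sub>,
  F<sub>IS</sub> = 1 − H̄<sub>o</sub>/H̄<sub>s</sub>, rarefied allelic
  richness, allele-matching β-F<sub>ST</sub> (population-specific and
  pairwise) with percentile-bootstrap CIs over loci, and three-stratum AMOVA
  (between groups / between genotypes within groups / within genotypes) with
  unequal-group-size moment estimators.
- **Trait-linked markers** — genotype-class segregation tables,
  Kruskal–Wallis tests of phenotype differences between classes, and marker
  false-positive / false-negative rates against phenotype QTL+/− classes
  (CMD severity ≤ 2.0, DMC ≥ 30 %, TCC ≥ 15 µg/g by default).
- **Synthetic panels** — a Balding–Nichols generator with planted ancestry,
  duplicates, and trait loci, so every stage is testable with known truth.

## Worked example

```python
from breedqc.popgen import amova_from_ms

# back-solve the two-cluster AMOVA from reported mean squares
# (clusters of 58 and 34 samples; df 1 / 90 / 92)
table = amova_from_ms(
    ms_values=[21438.064, 2832.135, 1839.685],
    df=[1, 90, 92],
    group_sizes=[58, 34],
)
print(table.to_frame().round(2).to_string())
```

prints

```
                                      df         SS        MS   sigma2  pct_variation
between_groups                       1.0   21438.06  21438.06   217.01           8.50
between_individuals_within_groups   90.0  254892.15   2832.14   496.23          19.44
within_individuals                  92.0  169251.02   1839.68  1839.68          72.06
Total                              183.0  445581.23   2434.87  2552.92         100.00
```

i.e. 8.50 % of the molecular variance lies between the two clusters, 19.44 %
between genotypes within clusters, and 72.06 % within genotypes — the
signature of a highly heterozygous, modestly differentiated breeding
population.

An end-to-end run on a synthetic panel:

```bash
breedqc simulate --seed 7 --out sim/
breedqc report --genotypes sim/dense.csv --phenotypes sim/phenotypes.csv --out-dir run/
```

which writes `run/report.json` plus distance, dendrogram (Newick), Q-matrix,
diversity, AMOVA, and trait-marker tables.

## Layout

- `src/breedqc/genotype_io.py` — VCF / call-grid / phenotype / distance /
  Newick I/O and the `GenotypeMatrix` container
- `src/breedqc/qc_filters.py` — call-rate and MAF filtering
- `src/breedqc/relatedness.py` — IBS distance, duplicates, GRM, PCA
- `src/breedqc/structure.py` — Ward clustering, optimal K, admixture EM/CV,
  partition concordance
- `src/breedqc/popgen.py` — diversity, allelic richness, β-F<sub>ST</sub>, AMOVA
- `src/breedqc/trait_validation.py` — phenotype formulas, segregation,
  Kruskal–Wallis, FPR/FNR
- `src/breedqc/synthetic_data.py` — panel generator and worked-example fixtures
- `src/breedqc/cli.py` — `breedqc` subcommands and the full pipeline

See `docs/methods.md` for the statistical details and design choices.
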