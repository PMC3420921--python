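# Methods

## Model and procedure

The pipeline treats a panel of quantitative metabolite measures as a set of
jointly analysed phenotypes. It has five stages.

**1. Quality control.** SNP-level filters (each evaluated on the input
matrix, so filtering order is irrelevant): call missingness > 5%, minor
allele frequency < 0.01, Hardy–Weinberg exact-test P < 10⁻⁶, and imputation
Rsq < 0.30 when an Rsq column is supplied. Sample-level filters: declared
exclusion flags (e.g. lipid-lowering therapy, pregnancy) and > 5% genotype
missingness. MAF is computed from non-missing dosages only and folded to
≤ 0.5. The HWE test conditions on the observed allele counts and sums the
probabilities of all heterozygote counts no more probable than the observed
one; for totals up to 500 the enumeration is exact integer arithmetic
(`math.comb`, big-int division), above that log-gamma weights with a 10⁻¹²
relative tie tolerance. The exact-integer path makes the test reproducible
to the last bit at cohort sizes where enumeration is cheap.

**2. Phenotype preprocessing.** Each metabolite is residualized by OLS on
the covariates (sex, age, genetic PCs; cohort indicators when more than one
cohort is present), then mapped through a rank-based inverse normal
transformation Φ⁻¹((r − ½)/n) with average ranks for ties (Blom's offset
(r − 3/8)/(n + ¼) available by option), and finally standardized so every
column has mean 0 and SD exactly 1 — the INT alone leaves the SD slightly
below 1. Cohorts are pooled before this step; covariates absent from one
cohort (age in a birth cohort) are dropped from the joint adjustment.
Genetic PCs can be computed from the standardized dosage matrix when not
supplied.

**3. Network detection.** The metabolite–metabolite Pearson correlation
matrix (pairwise-complete) is clustered agglomeratively on the distance
1 − r (signed, so anti-correlated metabolites are distant; 1 − |r|
available). The agglomeration is written in-package because deterministic
lexicographic tie-breaking on metabolite names is part of the contract; the
merge list uses the scipy `linkage` layout and is cross-checked against
scipy and against a naive O(n³) re-implementation in the tests. The tree is
cut at an adaptive height: `deep_split` ∈ {0..4} maps to the fraction
{0.95, 0.85, 0.75, 0.65, 0.55} of the merge-height range above the lowest
merge. Because the cut height is strictly decreasing in `deep_split`, the
number of clusters is non-decreasing in it by construction. Clusters below
`min_cluster_size` (default 1, so singletons are allowed) are absorbed into
their cophenetically nearest neighbour. A PAM-like reassignment stage is
deliberately not implemented: the contracts exercised are sensitivity
monotonicity and planted-block recovery, and a fixed-rule cut keeps both
exactly reproducible.

**4. Association.** Univariate: OLS of each metabolite on minor-allele
dosage with intercept, two-sided t test of the slope (vectorized across
metabolites per SNP inside the scan; the per-call path uses
`scipy.stats.linregress`, and the two are tested against each other).
Multivariate: with a single exogenous variable only one canonical pair
exists, so ρ² is the multiple R² of the dosage regressed on the network's
metabolites, λ = 1 − ρ², and F = ((n−k−1)/k)·ρ²/(1−ρ²) on (k, n−k−1) df is
the exact overall-regression F — no multi-set Rao approximation is needed
or implemented. Loadings are structure correlations between each metabolite
and the fitted canonical variate, oriented positively with dosage; raw
weights are also emitted. Missing dosages: complete-case per SNP × network
by default, per-SNP mean imputation by flag. A fit with ρ² within 10⁻¹⁰ of
1 is reported flagged with p = 0 rather than raised, so genome scans never
abort mid-run. Conditional analysis regresses every network metabolite on
the conditioning dosages (collinear columns dropped with a warning) and
re-runs the unchanged multivariate test on the residuals; conditioning on
the causal SNP or a perfect proxy drives ρ² to 0 identically because the
residuals are orthogonal to it.

**5. Scan orchestration.** Bonferroni thresholds divide the genome-wide
base level 5×10⁻⁸ by the number of networks (multivariate) or metabolites
(univariate); values are compared unrounded and reported at 2 significant
figures (4.5×10⁻⁹ for 11 networks, 3.8×10⁻¹⁰ for 130 metabolites). Loci are
greedy clumps: take the most significant remaining SNP (ties to the lower
position), open a 200 kb window centered on it (clipped at position 1),
absorb all significant SNPs inside, repeat. Genomic inflation is the
through-the-origin regression slope of observed on expected −log₁₀(p) order
statistics using the 90% of points with smallest expected quantiles — i.e.
the least significant tests, which excludes true-signal tails. LD between
SNP pairs is computed by EM over haplotype frequencies from rounded
dosages (the double-heterozygote cell is the only phase-ambiguous one);
counts are canonically oriented so the result is bitwise symmetric in its
arguments.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any particular biology:

- **Genotypes.** Per-SNP MAF uniform in `maf_range` (default 0.05–0.5); two
  haplotypes per individual, so genotype counts follow HWE exactly.
  Optional LD blocks by haplotype copying: within a block each site copies
  the previous site's allele with the block's correlation parameter, else
  redraws at the block MAF — correlation decays geometrically with
  intra-block distance, and copying probability 1 gives r² = 1. Positions
  are evenly spaced (default 5 kb) on one synthetic chromosome so 200 kb
  locus logic is exercised. Optional uniform dosage jitter (clipped to
  [0, 2]) emulates imputed dosages; missing calls are planted at
  `missing_rate_genotype` (default 1%).
- **Metabolites.** Unit-variance Gaussian with block covariance: within- and
  between-block correlations from `network_spec`; the default is 11 blocks
  of sizes 24/18/16/14/12/10/9/8/7/6/6 (130 metabolites) at within-r 0.7,
  between-r 0.1 — block counts and sizes on the scale of a serum NMR panel,
  with "tight within, weak between" correlation levels typical of
  lipoprotein-subclass data. The implied matrix is validated positive
  semi-definite and rejected otherwise. Gaussian margins are the matching
  assumption because the analysis operates on inverse-normal transformed
  residuals.
- **Genetic effects.** An effect plants variance fraction f·pattern_m of
  metabolite m's total variance on the chosen SNP (β = √(f_m/var(g)));
  noise is scaled down so each metabolite's genetic-plus-noise variance is
  1. Fractions must sum below 1 per metabolite.
- **Covariates and cohorts.** Sex (Bernoulli ½), age (standard normal), 10
  genetic-PC columns, and a two-cohort label with an additive cohort shift;
  default effect sizes 0.2/0.2/0.5 in SD units — nuisance structure large
  enough that skipping the residualization step visibly mis-calibrates the
  scan.

What the generator does **not** emulate: realistic human LD maps and allele
frequency spectra, relatedness and family structure, non-Gaussian raw
metabolite distributions, batch effects, and genotype uncertainty beyond
uniform jitter. Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under the model's own assumptions, not
that discovery numbers from any particular real cohort would be reproduced.

## Study sizes used by the verification suite

Chosen as the smallest designs that leave the measured quantities with
comfortable margins:

- Null calibration: one cohort pair totalling n = 2000, 2000 SNPs, three
  networks of 5/8/12 metabolites, full pipeline; type-I error at α = 0.05
  judged against the exact binomial 99% interval for the number of tests
  actually run, inflation slope against [0.9, 1.1].
- Pleiotropy power: 50 replicates, n = 5000, a 6-metabolite network with
  within-r 0.6, and 60 causal SNPs per replicate each explaining 1% of
  variance in 4 of the 6 members. Per-locus detection probabilities under
  these conditions are high for both tests (≈0.96 multivariate at 4.5×10⁻⁹,
  ≈0.90 best-univariate at 3.8×10⁻¹⁰), so many loci per replicate are
  needed for the per-replicate count comparison to resolve the asymmetry —
  60 puts the strict-advantage probability per replicate around 0.9 and is
  on the scale of the locus counts real scans of this kind report.
- k = 1 equivalence: 1000 random datasets at n = 200; agreement to 10⁻¹⁰.
- Clustering recovery: n = 6600, the default 11-block/130-metabolite panel,
  adjusted Rand against the planted partition at `deep_split` 4.
- HWE oracle: every genotype triple with total ≤ 200 against an independent
  factorial-enumeration oracle, exactly (shared big-int arithmetic, two
  different formulas).

## Numerical choices and edge cases

- Tie-breaking is lexicographic by metabolite id everywhere in clustering;
  the min-p rule keeps the lexicographically first metabolite on ties.
- Rank-deficient covariate or metabolite designs are rejected with the
  offending columns named; collinear conditioning sets are reduced, not
  rejected, because conditional scans routinely include near-proxies.
- Dosages are rounded to hard calls for HWE counting and LD EM only; QC
  statistics never use imputed values, association handles missingness as
  stated above.
- The inflation regression has no intercept: a calibrated scan must pass
  through the origin on a QQ plot.
- DS-coded VCF round-trips at float32 precision (htslib FORMAT floats); the
  dosage-TSV dialect and GT-coded VCF round-trip bitwise.

## Known limitations

- The dynamic tree cut is a fixed-rule height cut per `deep_split`; it does
  not reproduce any particular published cluster count on real data, only
  the monotonicity and recovery contracts.
- Only one exogenous variable (one SNP) per multivariate test; multi-SNP
  exogenous sets would require the general Wilks/Rao machinery.
- Loadings are in-sample structure correlations; no shrinkage or
  cross-validation is applied.
- The EM for LD assumes biallelic SNPs and unrelated individuals.
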