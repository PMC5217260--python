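# Methods

`methylong` implements a longitudinal childhood blood-methylation
analysis as a reusable pipeline, exercised end to end on a synthetic
data generator with a complete truth manifest. This note documents the
models, the generator, the numerical choices, and what passing tests do
and do not establish.

## Study design being modelled

Four birth cohorts form two disjoint comparison sets of paired samples
per child: a "young" set (cord blood at age 0 vs peripheral blood at
age 4/5) and an "old" set (ages 4 vs 8). Methylation is measured as
beta values, the fraction `β = M/(U + M + α)` of methylated probe
intensity with offset α = 100, so β ∈ [0, 1). The scientific questions
are (i) which CpG sites change with age consistently in both sets
(a-DMSs, split into decreasing `da` and increasing `ia`), (ii) whether
cis genetic variants drive the *change* in methylation (dMeQTL, with
the change score Δβ = older − younger as the phenotype), (iii) whether
maternal smoking in the last trimester shifts the change, (iv) whether
a-DMS methylation levels associate with asthma, and (v) how a-DMS sets
distribute over genomic annotation and disease-gene catalogues.

## Statistical procedures

**Robust per-CpG tests.** Every methylation scan uses a Huber
M-estimator fitted by iteratively reweighted least squares: tuning
constant 1.345 (95% Gaussian efficiency), scale re-estimated each
iteration as 1.4826 × median absolute deviation of residuals,
convergence when no coefficient moves by more than 1e-8 (50-iteration
cap, non-convergence flagged rather than raised). Standard errors use
the standard M-estimator sandwich, which collapses to the OLS formula
when no residual is clipped; p-values are two-sided on a t reference
with n − k degrees of freedom. A batched implementation runs all
phenotypes sharing one design matrix through a single IRLS loop; the
paired a-DMS test is the intercept-only special case applied to
within-child differences. Differencing plus a robust location fit is
the exact paired analogue of regressing on an age indicator and keeps
the degrees of freedom clean.

**Control-probe correction.** Technical variation is estimated from
negative control probes, which carry no biology. PCA runs on the
column-standardized control matrix; each probe column is permuted
independently 10,000 times (the package default; experiments at reduced
scale use 100–200 permutations, see "Problem sizes"), and the k-th PC
is accepted while the plain-ratio permutation p — the fraction of
permutations whose k-th PC variance exceeds the observed one — is below
1e-4, stopping at the first failure since variance ordering makes gaps
uninterpretable. A zero exceedance count is logged as `< 1/n_perm`.
Selected PC scores join the residualization design. The number of
selected PCs is re-derived per dataset rather than fixed.

**Residualization.** Each probe is regressed on the selected control
PCs, cohort, sex, bisulphite-kit batch, array position (categorical,
first level as reference) and the six estimated cell-type proportions;
the adjusted matrix holds the residuals. Residualization is a linear
projection: it is idempotent and leaves residuals orthogonal to every
regressor; exact collinearity is detected up front and reported with
the offending column pair.

**Cell-type deconvolution.** Reference-based deconvolution is reduced
to its core: constrained least squares of a sample's reference-probe
betas on six cell-type mean profiles (monocytes, B, NK, CD4+ T, CD8+ T,
granulocytes) under non-negativity and sum ≤ 1. The program is solved
exactly as NNLS on an augmented system with a slack component and a
weight of 1000 on the sum constraint; a QR reduction makes the
per-sample solve O(k²) when many samples share one reference. Reference
profile *derivation* (probe selection by F-tests, etc.) is out of
scope; profiles are an input.

**a-DMS classification.** With N tested probes, the per-set threshold
is 0.05/N (Bonferroni). Probes significant in both sets are partitioned
by sign agreement: `da` (both negative), `ia` (both positive),
`inconsistent` (opposite). Percentages are reported relative to the
both-significant total.

**dMeQTL mapping.** The Δβ phenotype is computed from the adjusted
matrix; per probe, values outside [q25 − 3·IQR, q75 + 3·IQR] (quantiles
by linear interpolation at position 1 + q(n−1)) are masked. SNPs pair
with a-DMS probes within an inclusive ±250 kb window on 1-based
coordinates. Each pair is tested by OLS of phenotype on allele dosage,
masked samples dropped pairwise; constant dosage after masking flags
the pair untestable. The two old-set cohorts are scanned separately and
pooled by inverse-variance fixed-effect meta-analysis (weights 1/se²);
discovery significance is Benjamini–Hochberg FDR < 0.05 over all tested
pairs; replication in the young set requires the same effect sign and
two-sided nominal p < 0.05. Replication pools both young cohorts: the
generator provides genotypes for every child, so restricting to one
cohort would discard information without changing the design's logic.
Pairs whose SNP lies in the 50 bp probe body upstream of the target
site, or whose dosage correlates at r² > 0.2 with any in-probe SNP
(LD computed from the sample dosage matrix), are removed as probe
artifacts. Cross-sectional MeQTL effects at ages 4 and 8 (old-set
timepoints) are compared by magnitude per pair — weaker/stronger at the
younger age, opposite direction, or an exact tie — and the
weaker/stronger split is tested against one half with a one-sample
proportion z-test whose two-sided p is assembled in log space so
extreme z values do not underflow. The magnitude comparison is plain
(no formal difference test): the reported categories partition all
same-direction pairs, leaving no "not different" class.

**Exposure and disease models.** Maternal smoking (binary, last
trimester) is tested against Δβ of the a-DMS probes with Huber
regression adjusting for maternal age, parity and maternal education
(3-level categorical); FDR is computed within each family
(young-set and old-set smoking separately; asthma per age). Because
the Δβ input is already residualized on cell proportions, the smoking
model does not re-adjust for them. The asthma model follows the
levels-based specification: methylation corrected for control PCs only,
regressed on status plus cohort, sex, batch, array position and the six
cell proportions. Asthma families use the old-set timepoints (ages 4
and 8); the young set's age-4/5 samples are not pooled in, keeping each
family a single cross-section.

**Enrichment.** Folds compare a CpG set's annotation fraction with the
fraction among all tested CpGs (CpH probes excluded from set and
background); significance is a df-1 chi-square (no continuity
correction) of set vs rest, starred *** p < 1e-6, ** p < 1e-3,
* p < 0.01, blank above. Chromatin states over 27 blood cell-type
measurements combine by union (present in ≥ 1). Genes attach to probes
by the single nearest TSS within an inclusive 100 kb window, exact ties
to the lexicographically smallest gene id (logged). Disease-gene
enrichment is a two-sided Fisher exact test of set × catalogue
membership over the universe of genes assigned to ≥ 1 tested probe.

**Report arithmetic.** Percentages print as 100·num/den rounded half
away from zero to one decimal, with two significant digits below 1%.

## The synthetic-data generator

The generator is the definition of the study conditions, not a fixture.
Defaults: 4 cohorts × 150 children, 20,000 probes, 613 negative control
probes, 5,000 SNPs, 5% of probes with decreasing and 3% with increasing
age effects of mean |Δβ| 0.05 per set (per-set magnitudes drawn with
30% relative spread; the 5:3 split makes the consistent-decrease share
62.5% of planted sites), 100 causal SNP–probe pairs with per-allele
change effects drawn uniformly from [0.02, 0.08] (half age-varying),
smoking prevalence 25% with 30 affected CpGs at −0.02 on the young-set
change, asthma prevalence 12% with 5 level-shift CpGs at +0.03.

Construction, per comparison set:

- Baseline probe means follow the bimodal beta-value landscape (35%
  low, 30% intermediate, 35% high). Cell-type profiles deviate from
  baseline at 25% of probes; per-sample mixtures are Dirichlet with a
  granulocyte-dominated mean and concentration 60; the sample's mean
  methylation is the mixture-weighted profile. Deconvolution reference
  probes are 500 cell-type-informative, age-stable probes — planted
  age-effect probes are excluded, as a reference panel drifting with
  age could not separate composition change from methylation change.
- Planted age effects land on intermediate-methylation probes (the only
  ones with headroom for a 0.05 shift) and add to the older timepoint's
  mean; genotype effects add b(age)·dosage with b linear in age for
  age-varying pairs, so both 4-year windows carry the same change
  effect; smoking subtracts from the young-set older timepoint in
  exposed children; asthma shifts both timepoints' levels.
- Each child's two samples share a chip (6 children per chip) with
  randomized well positions; a chip factor with per-probe Gaussian
  loadings (scale 0.15 on the logit scale) shifts target probes and,
  with separate loadings, the control-probe intensities — this is what
  makes the control-PC correction testable.
- Noise is Gaussian on the logit scale, scaled so the beta-scale
  standard deviation is `noise_sd` (default 0.035, in the range of
  array technical noise plus short-term biological variation; the
  change score then has sd ≈ 0.05), then inverse-transformed, keeping
  betas strictly inside [0, 1].
- Genotypes are Hardy–Weinberg draws at MAFs uniform in [0.05, 0.5]
  (so every SNP clears the MAF ≥ 0.01 filter by construction). Causal
  SNPs are placed within the cis window of planted probes; ~30 SNPs sit
  inside probe bodies, half of them in planted probes with causal
  effects, plus LD-partner SNPs copying an in-probe SNP's genotypes
  with 10% re-draws — these exercise the probe-artifact filter.
- The fingerprint panel (65 probes) is genotype-determined and equal at
  both timepoints, driving the pair-concordance QC. Detection p-values
  are benign by default (~0.2% sporadic failures). Annotation
  (island/gene-region partitions, 27-cell-type chromatin tracks with
  mild planted tilts, genes with 14% baseline disease-catalogue
  membership enriched to 20% near planted probes) uses realistic
  marginal fractions; they are configuration, not estimates.
- Young and old comparison sets use disjoint children; all output is a
  deterministic function of the seed.

What the generator does **not** emulate: raw array intensities and
normalization artefacts, probe-specific chemistry (Type I/II), spatial
chip effects, population structure and imputation uncertainty in
genotypes, realistic LD beyond the planted partners, age-dependent
reference-profile shifts (cord vs peripheral blood profiles), and
missing data. Passing recovery tests therefore demonstrate that the
pipeline's inference machinery is correct and calibrated under its
assumed error model — not that real-cohort genome-wide counts would be
reproduced.

## Problem sizes and runtime choices

The demo configuration (20,000 probes, 5,000 SNPs, 150 children per
cohort) runs the full file-backed pipeline in a few minutes on one CPU.
Calibration and recovery experiments use: 20 all-null seeds at
20,000 probes × 150 children/cohort for null calibration; 125
children/cohort (250 pairs) for age-effect recovery; 4,000 probes /
2,000 SNPs / 150 causal pairs for dMeQTL recovery; 100 null and 50
planted-factor replicates at 200 × 600 with 200 permutations for the
PC-selection characteristics. Permutation counts below the 10,000
default are a deliberate economy: with the stopping rule, a zero
exceedance count among 100–200 permutations already satisfies the
p < 1e-4 criterion, and the experiments' conclusions do not change
with more permutations.

## Numerical and design notes

- MAD scale floors at 1e-12; an all-zero residual vector yields
  effect 0, se 0, p 1 rather than NaN.
- Leading PC variances use a full SVD for small matrices and a
  seeded randomized SVD (10 components, 5 power iterations) for large
  ones; both sides of the permutation comparison use the same
  estimator, so any small bias cancels.
- Boundary conventions follow the stated rules strictly: a sample
  failing detection in exactly 10% of probes is kept ("more than"),
  pair concordance r = 0.9 exactly is kept ("< 0.9"), target-site MAF
  exactly 0.10 is kept ("> 10%"), a SNP exactly 250,000 bp away is a
  cis pair (inclusive window).
- Exact-zero effect estimates in the direction tally count as positive
  and are logged; they do not occur with continuous estimates.
- The dMeQTL stage scans only the a-DMS universe from the
  classification step, so a causal QTL probe that misses genome-wide
  significance (for instance, when an opposing genotype effect shrinks
  its mean change) is absent from the scan — the same conditioning a
  real two-stage analysis has. Recovery experiments therefore evaluate
  the dMeQTL machinery on the planted-probe universe.
- Disease-gene enrichment derives its background purely from the
  pipeline's own filters (tested probes minus CpH, genes with ≥ 1
  assigned probe); no external background count is hardcoded.
- The pipeline is resumable: a digest of the data directory and
  parameters is stored per run, and a rerun with unchanged inputs
  returns the stored report without recomputation.

## Known limitations

- The Huber sandwich standard errors are asymptotic; at very small n
  (tens of pairs) the t reference is approximate.
- Deconvolution accuracy degrades if the true composition's profile is
  nearly collinear with another mixture; the generator's profiles are
  well separated, real references less so.
- The permutation PC selection tests PCs in variance order only; a
  technical factor ranked below a biological one would be missed (not
  constructible in the generator, where control probes carry no
  biology).
- LD for the probe-artifact filter comes from sample dosages, which is
  noisy at small n; the r² > 0.2 rule is liberal enough that this
  rarely matters.
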