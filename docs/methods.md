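# Methods

`snpladder` studies how the density of an equally-spaced SNP panel affects
genomic analyses in a population with a small effective size, of the kind
found in closed beef-cattle breeds: linkage disequilibrium (LD) summaries,
the genomic relationship matrix (GRM), Bayesian estimates of genetic
variance under linear and liability-threshold models, and the agreement of
genomic breeding values (GEBVs) across densities. Because no public dataset
of this kind exists, every analysis runs on data from the package's own
simulator, which is first-class, tested code.

## Statistical models

**Linear animal model.** For records $y$,

$$y = Xb + g + e,\qquad g \sim N(0,\, G\,\sigma_g^2),\qquad e \sim N(0,\, I\,\sigma_e^2),$$

where $X$ holds an intercept, market and slaughter-year factors (treatment
coding, first level dropped) and linear plus quadratic age-at-slaughter
covariates; $b$ has a flat prior. The GRM follows VanRaden:

$$G = \frac{(M-2P)(M-2P)'}{2\sum_i p_i(1-p_i)} + 10^{-4} I,$$

with $M$ the minor-allele dosage matrix, $p_i$ the minor-allele frequency of
marker $i$ recomputed from the analyzed cohort for each panel
(`freq_source = cohort`; the alternative of freezing full-panel frequencies
changes results negligibly and is not exposed), and the $10^{-4}$ diagonal
jitter guaranteeing positive definiteness.

Both variances carry independent scaled inverse-chi-square priors with
degree of belief $\nu=-2$ and scale $S=0$ — flat on the variance — so the
conditional posterior degrees of freedom are $n-2$ and $q-2$; at least 3
records/animals are required. The Gibbs sampler draws $b$ from its
multivariate normal conditional, the genetic values in the eigenbasis of
$G$ (one symmetric eigendecomposition per GRM, reused across traits and
chains; since the eigenvectors are orthonormal the coordinates are
conditionally independent — exactly equivalent to the joint draw, verified
against closed-form GLS/BLUP with variances fixed), and each variance from
its scaled inverse-chi-square conditional. The default chain protocol is
110,000 iterations, 10,000 burn-in, thinning 10 (10,000 retained samples);
tests and the acceptance script use shorter chains noted below. Posterior
summaries are means ± SDs over retained samples; the phenotypic variance
$\sigma_p^2=\sigma_g^2+\sigma_e^2$ and the ratio $\sigma_g^2/\sigma_p^2$
are computed per retained sample, never as ratios of means. Monte Carlo
standard errors use batch means (20 batches), and a Geweke-style first-half
vs second-half comparison sets a `converged` flag.

**Threshold model.** Ordinal scores arise from a latent liability
$\eta = Xb + g + e$ with $\sigma_e^2 \equiv 1$ crossing ordered thresholds.
Data augmentation samples $\eta$ from truncated normals on each record's
category interval; in binary mode the single threshold is fixed at 0; in
ordinal mode the first threshold is fixed at 0 and the remaining ones are
drawn uniformly between the flanking liability order statistics
(Albert–Chib update). The reported quantity is
$\sigma_g^2/(\sigma_g^2+1)$. These chains can mix very slowly, and with
denser G matrices the sampler can drift toward quasi-separation (ratio
near 1); both behaviours are surfaced through warnings and the `converged`
flag rather than suppressed, and the chain protocol is configurable for the
very long diagnostic runs such cases need. A liability generated by a
modest number of discrete QTLs (rather than the model's own
infinitesimal process) makes such run-away behaviour more likely at
moderate cohort sizes — visible in `examples/04_threshold_model.py`.

**LD.** For each within-chromosome adjacent marker pair,
$r^2 = D^2 / \big(p_A(1-p_A)\,p_B(1-p_B)\big)$ with $D$ from
maximum-likelihood haplotype frequencies. Genotypes are unphased, so the
frequencies come from the standard two-locus EM over the nine genotype
classes (only double heterozygotes are phase-ambiguous; they are split by
the current coupling/repulsion odds). Convergence tolerance is $10^{-10}$
with a 1,000-iteration cap; non-converged pairs are dropped and counted.
The EM is vectorized across all pairs. A note on an identity that is *not*
exact: when no double heterozygotes are present the EM equals the direct
gamete-count $r^2$, but the squared Pearson correlation of *dosages*
differs from it by the within-individual cross-haplotype covariance; the
two coincide exactly only in special cases (e.g. fully homozygous samples),
and the dosage-correlation estimator is provided separately as
`composite_r2`. Only adjacent pairs are computed; distance bins are
half-open $[lo, hi)$ with an overflow bin, and the overlapping cumulative
ranges $[0,x)$ are available via `cumulative_summary`.

**Equally-spaced panels.** Panel sizes follow the study ladder
100…30,000/all. Selection allocates picks per chromosome proportional to
the chromosome's marker span (largest-remainder rounding, each chromosome
gets one pick when the budget allows), lays an endpoint-inclusive uniform
grid over the span, and takes the nearest marker to each grid point
(distance ties to the lower position; a taken marker is replaced by the
nearest unused one). Per-chromosome allocation was chosen over a single
genome-wide grid so every chromosome stays represented at low densities.

**HWE exact test.** Marker QC uses the Levene–Haldane exact test: condition
on the allele counts, enumerate the conditional distribution of the
heterozygote count, and sum the probabilities of all outcomes no more
probable than the observed one (two-sided, probability-mass ordering).
Monomorphic markers return p = 1. A one-df chi-square version exists as a
cross-check; the exact two-sided p can differ from the symmetric chi-square
tail by up to ~0.05 even at large expected counts, which is inherent to the
orderings, not an accuracy defect. Filters retain markers with MAF > 0.01,
call rate > 0.95 (both read as strict inequalities), HWE p > 0.001 and a
known map position, with removal counts reported under the fixed precedence
no-position → call-rate → MAF → HWE.

**Missing-genotype filling.** A few percent of calls are missing after
simulation masking. Three transparent schemes are provided (per-locus HWE
draws, locus mode, and the conditional mode given the nearest non-missing
flanking marker); none is a reimplementation of haplotype-based imputation.
At 2% missingness the GRM is insensitive to the choice (element correlation
> 0.999 in the test suite), which is why a simple scheme suffices.

**Imputation stand-in.** The low-to-high-density step uses a deliberately
simple predictor: for each untyped marker, the typed flanking marker with
the larger absolute dosage correlation in a disjoint reference cohort
supplies an empirical conditional modal genotype (fallback: the reference
marker mode). It is exactly testable against a brute-force conditional-mode
oracle and is swappable for a real phasing/imputation tool through the same
interface. Its concordance (~70% at a 1-in-3 typed density on synthetic
data) is far below a haplotype-based imputer's, yet the downstream GRM
stays highly correlated with the truth (r_A ≈ 0.97), which is the point the
imputation arm of the pipeline exercises. Imputed columns that come out
monomorphic are excluded from the GRM denominator.

## The synthetic-data generator

The generator emulates a Japanese-Black-like population: 29 autosomes of
86 Mb (~2.5 Gbp) carrying ~40,000 chip markers, elevated long-range LD from
a small effective size (~30), two carcass traits with heritabilities around
0.5–0.7, market/year fixed effects, and ages 15.3–43.0 months.

**Demography.** Forward Wright–Fisher simulation of biallelic markers with
Haldane-model recombination (1 cM/Mb default; crossover counts Poisson in
map length, positions uniform) and allele-flip mutation, in three phases:

1. *Ancestral*: 150 diploids for 100 generations — builds LD that decays
   with distance (a single small-Ne phase produces drift LD that is flat in
   distance over 0–1 Mb, which is wrong in shape);
2. *Bottleneck*: 30 diploids for 10 generations — inflates long-range LD,
   the signature of the breed's recent decline in effective size;
3. *Expansion*: 400 diploids for 6 generations — models the large slaughter
   population fed by a small breeding nucleus. Without it, cohorts drawn
   straight from the 60-haplotype bottleneck pool are so inter-related that
   a 100-SNP GRM is already nearly identical to the full-density GRM and
   the density ladder collapses.

Founder allele frequencies are uniform on (0.35, 0.5) and the mutation rate
is $2\times10^{-3}$ per locus per gamete — deliberately high for a base-pair
rate because it stands in for chip ascertainment (commercial chips carry
SNPs selected to be polymorphic). These defaults keep ≥95% of markers at
MAF > 0.01. Marker positions are uniform per chromosome; dosages are
polarized to the cohort minor allele once at sampling time and inherited by
all marker subsets; a second cohort (the imputation reference) reuses the
first cohort's polarization so both share one coding.

**Traits.** The carcass-weight-like trait has 3 large QTLs (effect SD 12)
on a 300-QTL polygenic background (effect SD 1), target $h^2=0.55$; the
marbling-like trait is purely polygenic (300 small QTLs), target
$h^2=0.68$, observed as a 12-category score through empirical-quantile
thresholds that produce a right-heavy distribution. The residual variance
is set so the realized $\mathrm{var}(g)/(\mathrm{var}(g)+\sigma_e^2)$
equals the target exactly for the sampled cohort. Liabilities equal to a
threshold go to the upper category.

**Large-QTL placement.** By default QTL positions are uniform. Under
uniform placement, the expected fraction of genetic variance captured by a
sparse panel is the same for concentrated and polygenic architectures, so
the empirical contrast — a large-QTL trait reaching a given fraction of its
full-panel genetic variance at sparser densities — does not appear. The
known large carcass-weight QTLs are GWAS-ascertained: they were mappable
precisely because chip SNPs tag them strongly, i.e. they sit in long
haplotype blocks. The generator therefore offers
`placement="extended_ld"`, which pins the large QTLs to the marker with the
highest mean r² to markers 0.3–3 Mb away, one per chromosome; the
carcass-weight preset uses it. With this placement the contrast is
reproducible (8/8 paired seeds in the acceptance suite).

**What the generator does not emulate.** No selection, no pedigree
structure or sire families, no X chromosome, no genotyping error, no
MAF-dependent ascertainment curve, uniform recombination. Passing tests
therefore demonstrate correctness of the estimators and the direction and
rough magnitude of density effects — not the numeric values a particular
real population would give.

## Numerical and design choices

- GRM construction refuses monomorphic markers (zero denominator
  contribution) — filter first.
- `r_A` ("all elements") correlates the full flattened matrices, so
  off-diagonals count twice and the diagonal once.
- Eigendecomposition failure (non-positive-definite G) raises an error
  advising a larger jitter rather than silently regularizing.
- Fill and sampler seeds, QTL seeds and cohort seeds are all derived
  deterministically from the single pipeline seed; two runs with the same
  config are byte-identical.
- Locus-mode fills break ties toward the smaller dosage; grid-rule distance
  ties break toward the lower position. Both are arbitrary but frozen and
  tested.
- Market-year structure: the source design is ambiguous between separate
  factors and a combined market-year class; separate factors are
  implemented (2 markets × 10 years by default, giving a 13-column design).
- Ordinal categories are taken from the observed score values, which
  implicitly merges empty interior categories (with a warning).

## Problem sizes used by tests and the acceptance script

The package's own study sizes are scaled down from the emulated population
so the whole suite runs quickly on one CPU: unit tests use 3–5 chromosomes
with 900–5,000 markers and cohorts of 100–500 animals; sampler-validation
chains run 4,000–30,000 iterations; the acceptance script
(`scripts/acceptance.py`) runs five 80-Mb chromosomes, 6,000 markers, 400
study animals, 200 reference animals, a 5-step ladder and 6,000-iteration
chains. These sizes were chosen once as the smallest at which the studied
patterns are clearly resolved; all protocols scale up through the config
objects.

## Known limitations

- The threshold-model sampler inherits the method's slow mixing; results
  with `converged=False` should be re-run with far longer chains.
- The naive imputation stand-in is not competitive with haplotype-cluster
  methods and exists to exercise the evaluation logic.
- `extended_ld_strength` subsamples neighbours (15 per marker) for speed,
  so extremely fine distinctions between candidate blocks are noisy.
- GEBV agreement across panels is computed on the same animals used for
  fitting (as in the emulated design, which had no validation cohort), so
  absolute accuracies are optimistic by construction.
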