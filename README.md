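# snpladder

How many equally-spaced SNPs does a genomic evaluation actually need?
`snpladder` is a simulation-backed pipeline for answering that question in
populations with a small effective size — the situation of closed beef
breeds, where strong long-range linkage disequilibrium (LD) means a sparse,
cheap marker panel may capture most of the genetic variance. It is aimed at
animal-breeding researchers and students who want a fully reproducible,
testable version of the classic density-ladder study: simulate a
cattle-like population, apply SNP quality control, and walk a ladder of
equally-spaced panels measuring what each density preserves.

## What it computes

For genotype dosages $M$ (minor-allele counts) with per-marker frequencies
$p_i$, the genomic relationship matrix is VanRaden's

$$G = \frac{(M-2P)(M-2P)'}{2\sum_i p_i(1-p_i)} + 10^{-4}I ,$$

and phenotypes follow the animal model $y = Xb + g + e$ with
$g \sim N(0, G\sigma_g^2)$, fitted by Gibbs sampling with flat priors on
$b$ and on both variances (scaled inverse-chi-square, $\nu=-2$, $S=0$).
Ordinal traits (e.g. a 1–12 marbling score) are also fitted with a
liability threshold model ($\sigma_e^2\equiv 1$, reporting
$\sigma_g^2/(\sigma_g^2+1)$). Per panel density the pipeline reports:

- adjacent-pair LD: $r^2 = D^2/(p_A q_A\, p_B q_B)$ from two-locus EM
  haplotype frequencies, with distance-binned summaries;
- correlations $r_D$, $r_N$, $r_A$ of the panel's G matrix with the
  full-density G (diagonal, upper triangle, all elements);
- posterior variance components and the share of full-density genetic
  variance the panel explains;
- correlation and regression slope of the panel's GEBVs on the full-density
  GEBVs (slopes below 1 = under-dispersion of sparse-panel GEBVs);
- optionally, an imputation arm: predict the untyped markers from a
  reference cohort, then re-fit.

The simulator (module `snpladder.simdata`) generates the study conditions:
a three-phase Wright–Fisher demography (ancestral population, recent
bottleneck at Ne≈30, expansion), ~40K markers genome-wide by default,
a carcass-weight-like trait with three large QTLs plus polygenes, and a
marbling-like polygenic ordinal trait. See `docs/methods.md` for the models,
assumptions and design choices.

## Worked example

`examples/05_panel_ladder_pipeline.py` runs the whole study at demo scale
(3,000 markers, 300 animals, a 4-step ladder) and prints:

```
panel  n_markers  mean_r2   r_N  carcass_weight_pct_sigma_g2  carcass_weight_gebv_corr  carcass_weight_gebv_slope  marbling_score_pct_sigma_g2
  100        100    0.054 0.663                       72.363                     0.856                      0.673                       39.060
  500        500    0.115 0.899                       92.631                     0.974                      0.862                       85.422
 1500       1500    0.142 0.975                       99.398                     0.996                      0.979                      101.732
  all       2948    0.148 1.000                      100.000                     1.000                      1.000                      100.000
```

Reading the rows: with only 100 equally-spaced SNPs the mean adjacent-pair
r² drops to 0.05, the G matrix correlates 0.66 with the full-density G, and
the linear model recovers 72% of the carcass-weight genetic variance —
while the purely polygenic marbling trait only reaches 39%, because its
variance is not concentrated in well-tagged major QTLs. By 1,500 SNPs both
traits are essentially at the full-panel values and the GEBV regression
slope approaches 1 (no more shrinkage of sparse-panel GEBVs). The run also
writes `ladder.tsv`, LD/GRM figures and a JSON manifest with every seed.

The other examples each demonstrate one capability: simulation and LD decay
(01), QC and the GRM (02), Gibbs GBLUP against the closed-form BLUP oracle
(03), the threshold model including its slow-mixing failure mode (04), and
imputation from a low-density panel (06).

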