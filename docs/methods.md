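# Methods

This note documents the statistical procedures the package implements, the
assumptions behind the synthetic-cohort generator, the numerical choices
made where the underlying study leaves the method open, and the limits of
what the synthetic tests demonstrate.

## Aneuploidy scoring

Input is a per-sample table of read counts over the 39 autosomal
chromosome arms (1p–22q, excluding the acrocentric short arms 13p, 14p,
15p, 21p and 22p, which carry almost no uniquely mappable sequence). The
arm universe and approximate GRCh38 arm lengths are bundled statically in
`melanoliq.arms`; only relative lengths enter the computation.

A sample is evaluable when it has at least 90,000 mapped reads. Arm read
counts are normalized to fractions of the on-target total, and each arm is
standardized against a reference panel of healthy blood donors (HBDs):
z_a = (f_a − μ_a)/σ_a, with the panel mean and sample SD (divisor n−1
throughout). Arms with zero panel SD are excluded and logged rather than
imputed. Whenever a scored sample is itself a panel member, leave-one-out
panel statistics are used; with 9–20 member panels, scoring a member
against statistics that include it would visibly deflate its z-scores.

The squared z-scores are summed over usable arms. A raw Σz² over ~39 arms
has null expectation close to the number of arms, which cannot support a
positivity threshold of 3; the reported *aneuploidy score* therefore
standardizes the raw sum against the leave-one-out raw sums of the panel
members: score = (raw − mean of member LOO sums)/SD of member LOO sums.
Under the null this score has mean ≈ 0 and SD ≈ 1 (checked by simulation),
making the conventional cutoff of 3 a ≈3-sigma call. Both the raw sum and
the normalized score are reported. Positivity is score ≥ 3 (inclusive) and
requires QC pass; a QC failure is "not evaluable", never negative.

## Methylation scoring

Input is a region × sample count matrix from methylation-dependent
restriction-enzyme sequencing, with regions restricted to autosomes.

1. **Digestion QC**: a library fails when fewer than 20% of its first two
   million reads pass the enzyme-recognition filter (`lpnpi_qc` consumes a
   precomputed summary; no read-level processing is done here).
2. **Region filter**: keep regions with a non-zero count in at least 75% of
   all samples *and* in all nine HBD controls ("data" means non-zero reads;
   regions without reads carry no signal in this assay). Both conditions
   are applied jointly; the completeness denominator includes the HBDs.
3. **Normalization**: counts-per-million over the retained regions, then
   log2(x+1). The study does not state its normalization; CPM+log2 is the
   field default for count matrices of this type and is isolated in one
   function (`normalize_counts`) so an alternative can be substituted.
4. **z-scores and summary scores**: per-region z against the nine-HBD panel
   (leave-one-out for HBD members, as above; zero-SD regions excluded).
   Σz² over all retained regions is the genome-wide score; Σz² over the
   melanoma DMR set is the melanoma-specific score.
5. **DMR discovery**: two-group moderated t between HBDs and high-ctDNA
   patients (aneuploidy score ≥ 3; discovery refuses to run on an empty
   selection), with empirical-Bayes variance shrinkage: the ensemble of
   region-wise pooled variances is fit by moment matching on the log scale
   (digamma/trigamma inversion), giving a prior df d0 and prior variance
   s0²; the posterior variance (d0·s0² + df·s²)/(d0+df) enters the t
   statistic, with p-values on df+d0 degrees of freedom and
   Benjamini–Hochberg adjustment at FDR < 0.1. The implementation
   reproduces the Bioconductor limma eBayes fit to machine precision
   (frozen oracle values in the test suite). A variance ensemble that
   cannot support the prior fit (e.g. all-zero variances) falls back to the
   ordinary pooled t with a warning; a complete-shrinkage fit (d0 = ∞) uses
   normal p-values.
6. **Cutoff**: the "altered methylation" call compares the melanoma score
   to the upper limit of the 95% confidence interval of the leave-one-out
   HBD scores. Two readings are implemented behind `cutoff_mode`:
   `ci_mean` (default) — mean + t·SD/√n, the CI of the *mean* HBD score,
   matching the study's wording and its observed high altered rate; and
   `prediction` — mean + t·SD·√(1+1/n), a prediction interval for a new
   healthy sample. The default is deliberately permissive: by construction
   it flags roughly a fifth of healthy donors themselves (≈2 of 9 in null
   simulations), while the prediction cutoff flags at most one. Users who
   need healthy-donor specificity should use `prediction`; the package
   tests the donor-specificity calibration under that mode.
7. **PCA**: regions ranked by variance of normalized values across all
   samples, top 50% kept, centered per region, SVD via scikit-learn;
   three components with explained-variance ratios are reported.

The HBDs serve both DMR discovery and cutoff estimation, as in the study;
this circularity inflates the apparent separation of patients from donors
and is the main reason the altered-rate should not be read as a validated
specificity. Discovery on a held-out donor split is possible by passing a
subset of HBD ids to `DMRFinder` and the rest to the cutoff.

## ddPCR

Droplets are independent partitions, so a channel with k positive of n
droplets implies λ = −ln(1 − k/n) mean copies per droplet; all-positive
channels saturate and raise an error advising dilution. Replicate wells are
pooled by summing positives and totals before correction
(maximum-likelihood pooling). VAF = λ_mut/(λ_mut+λ_wt), zero when both
channels are empty. Detection requires ≥ 3 mutant-positive droplets — the
field-standard limit-of-detection convention, exposed as `min_droplets`
because the study does not print its rule. The per-patient "dominant" VAF
is the maximum over detected assays; when nothing is detected the VAF is
reported as 0 (the convention of the study's cohort table, whose range
starts at 0).

## CTC enumeration and DLA recovery

Expected CTCs in the leukapheresis product extrapolate the peripheral-blood
CellSearch concentration (count per 7.5 mL) to the processed blood volume.
Measured totals extrapolate the concentration in the analyzed product
aliquot (CellSearch can process only 1–2 mL of product) to the whole
product volume. Recovery is their ratio as a percentage; it can exceed 100%
through counting noise. Recovery is undefined — reported as not evaluable,
never 0% — when no CTCs are expected, and recovery statistics are computed
in CTC-positive patients only. Detection summaries count patients with at
least one CTC per platform.

## Cohort statistics

- Spearman ρ on average ranks, pairwise deletion of incomplete pairs
  (logged); exact permutation p for n ≤ 9, t approximation otherwise.
- Mann–Whitney U, two-sided; exact enumeration when n_x·n_y ≤ 400 without
  ties, otherwise the tie-corrected normal approximation (no continuity
  correction, so identical samples give p = 1).
- Fisher's exact test with the probability-mass two-sided convention (sum
  of tables no more probable than the observed, relative tolerance 1e-7);
  sample odds ratio reported; a zero margin gives p = 1 by convention.
- The square-root transform is display-only; statistics are computed on
  untransformed values (rank statistics are invariant regardless).
- A paired Wilcoxon signed-rank mode is provided for paired
  blood-vs-product comparisons.
- No multiple-testing correction is applied across the correlation panel
  (matching the source analysis); the report stores raw p-values and a
  significance flag at α = 0.05, to be read with that caveat.

**Simon two-stage design.** Exhaustive search over (r1, n1, r, n) with
n ≤ n_max (default 60). The design stops at stage 1 when responses ≤ r1
among n1 patients and declares the treatment promising when total responses
exceed r among n. Exact operating characteristics come from the two-stage
binomial convolution P(promising | p) = Σ_{x>r1} Bin(x; n1, p)·P(X₂ > r−x;
n−n1, p). Feasible designs satisfy attained α ≤ nominal and power ≥ 1−β;
the *optimal* design minimizes E[N|p0] = n1 + (1−PET(p0))(n−n1), the
*minimax* design minimizes n first. Ties break toward smaller E[N]/n, then
smaller n1, then the smallest feasible r (maximal power; r does not affect
E[N]). At the study's operating point (p0 = 0.4, p1 = 0.7, α = 0.05,
β = 0.2) the optimal design is r1/n1 = 3/7, r/n = 11/20: maximal sample
size 20, attained α = 0.0450, power 0.8118. The search is cross-checked
against an independent brute-force oracle and Monte Carlo simulation in the
test suite.

## Synthetic-cohort generator

The study deposited no raw data, so a seeded generator emulates its data
streams with one latent driver per patient: the tumor fraction tf of the
cfDNA pool.

- **Tumor fraction**: a point mass at 0 (weight 0.10; patients without
  detectable circulating tumor material) plus a Beta(0.45, 4.5) component
  truncated at 0.56. The mixture median is ≈0.032 and the maximum ≈0.56,
  matching the printed cohort median (3.18%) and range (0–55.8%) of the
  dominant-mutation VAF, to which tf is equated (diploid genome, clonal
  heterozygous mutation — the simplest consistent mapping).
- **Arm counts**: baseline arm proportions follow bundled arm lengths;
  donors add small lognormal noise (SD 0.02 on the log scale) and counts
  are multinomial over 500,000 reads. Tumors alter 25% of arms with copy
  numbers drawn from {0,1,3,4}; a patient's arm proportion is
  baseline·((1−tf) + tf·c/2), renormalized. With noise set to 0 the
  generator returns the deterministic largest-remainder apportionment, so
  degenerate-case tests see exact baseline fractions.
- **Methylation**: region means from a normalized Gamma(2,1) weight vector
  over 5,000 regions; counts negative-binomial (dispersion 0.05) with
  library sizes varying ±2-fold; 200 true DMR means scaled by
  (1−tf) + tf·3 in patients (tumor-derived hypermethylation mixing into
  the pool). The real assay's 38,610-region universe and its specific 118
  DMRs are not reproduced — region identities here are synthetic.
- **ddPCR**: λ per channel from tf and 10,000 cfDNA copies split across
  20,000 droplets; positives Binomial(droplets, 1−e^(−λ)). No
  false-positive droplets are simulated.
- **CTCs and clinical covariates**: CTC concentration is lognormal with
  log-mean increasing in log tumor volume (slope 1, SD 1.2, ≈0.05/mL at
  100 cm³); the peripheral-blood count is Poisson over 7.5 mL. The DLA
  product receives Binomial(expected, recovery) cells with recovery ~
  Beta(2.9, 7.1) (mean 0.29, the study's median CTC recovery); CellSearch
  counts a 1.5 mL aliquot with its own efficiency (Beta mean 0.15, chosen
  so extrapolated recovery matches the study's ≈4% CellSearch figure) and
  flow cytometry counts the whole product at Beta mean 0.95 (so its
  recovery matches the ≈28% figure). MNC recovery uses Beta(7, 3) (mean
  0.70). Setting a Beta's second parameter to 0 collapses the draw to
  exactly 1 — the lossless limit used by calibration tests. Tumor volume is
  lognormal around 25·e^{4.5√tf} cm³ clipped to the printed 2–736 range;
  LDH = 164 + 0.8·volume + noise clipped to 164–1074 U·L⁻¹; lesion count is
  1 + Poisson(volume/40); processed blood volume is uniform on 2.4–6.8 L
  and product volume on 46–121 mL.

Everything derives from a single `numpy` Generator seeded from the config,
so identical configs give bit-identical cohorts.

**What the generator does not emulate.** Real donor panels have correlated,
GC- and mappability-driven arm biases rather than independent lognormal
noise; real methylation signal is region-specific with both hyper- and
hypomethylation; ddPCR has rain and false positives; CTC counts are more
overdispersed across patients than a lognormal-Poisson chain. In
particular, the aliquot-extrapolation geometry the study itself describes
(CellSearch analyzing 1–2 mL of a ≈93 mL product at ≈4% recovery) caps
simulated CellSearch-on-DLA detection *below* peripheral-blood detection,
whereas the study observed an increase (35% → 50%); that observed increase
is not derivable from the study's own printed recovery figures, and the
generator does not force it. Passing tests therefore demonstrate the
correctness and calibration of the computations, not clinical performance
of the assays.

## Problem sizes used in tests

The default test suite runs the generator at its study-scale defaults
(20 patients, 20-donor arm panel, 9-donor methylation panel, 5,000 regions,
500,000 reads, 20,000 droplets) and uses a 50-patient cohort with tumor
fractions on a [0, 0.5] grid for recovery/monotonicity calibration, three
replicate cohorts for DMR power/FDR, and 100–200 replicates for droplet and
null-score calibrations; the Simon search uses its full n ≤ 60 space.
These sizes make every calibration check well-resolved while the whole
suite completes in well under a minute.

## Known limitations

- The region universe, the 118-DMR list and all per-patient values of the
  source cohort are unavailable; per-patient reproduction requires the
  user-supplied supplementary table (see `tests/test_acceptance.py`).
- The `ci_mean` cutoff default reproduces the study's permissive behavior
  and should not be used where healthy-donor specificity matters (use
  `prediction`).
- Sex chromosomes are out of scope for aneuploidy scoring; no read-level
  (FASTQ/BAM) processing is performed anywhere.
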