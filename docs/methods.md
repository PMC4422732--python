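# Methods

## The problem

Standard genotype calling assumes each biallelic site carries 0, 1 or 2
copies of the minor allele.  On the mitochondrial genome this assumption
fails: a cell contains hundreds to thousands of mtDNA copies, and mutant and
wild-type molecules can co-exist within an individual (heteroplasmy), so
allele dosage is a continuous fraction.  Calling algorithms designed for
nuclear SNPs therefore discard exactly the signal of interest.  This package
implements the alternative: work directly on the raw allele intensities of
the genotyping array and use a continuous per-individual summary of allele
balance as the association covariate.

## Model

For probe *j* and individual *i*, let Ā and B̄ be the mean raw intensity
over the chip's *n* replicate measures for the major (A) and minor (B)
allele channel.  The covariate is the centered log intensity ratio

    z_ij = log2((Ā + ε) / (B̄ + ε)) − μ_j ,

with μ_j the per-probe mean over unmasked individuals and ε = 1 intensity
unit guarding zeros symmetrically (equal channels give z = 0 exactly).  For
each lipid trait y (TC, HDL, LDL, TG, in mg/dL) and each probe, we fit by
ordinary least squares

    y_i = β0 + β_SNP · z_ij + β_sex · 1[female_i] + β_age · (age_i − mean age) + e_i ,

with male as the sex baseline.  Significance of β_SNP comes from a Wald
test; the reference distribution is Student-t with n − 4 degrees of freedom
(exact under normal errors; at cohort sample sizes it is indistinguishable
from the normal that "Wald test" usually implies).  Within each chip,
p-values are Bonferroni-adjusted by the number of probes tested on that
chip, and a probe is declared significant at p_adj ≤ α = 0.05.  Chips are
never pooled — vendors measure intensity on incomparable scales — but
significant hits report the nominal p-values of probes at the same genomic
position and allele pair on the other chips ("overlap").

Because z falls as the minor-allele fraction rises, β_SNP < 0 means the
minor allele is associated with a *higher* trait level, β_SNP > 0 with a
lower one.  Total cholesterol is never measured independently here; it is
always the combination TC = HDL + LDL + 0.2 · TG.

## Quality control chain

Fixed order, enforced by `qc.run_qc`:

1. **Probe exclusions** (on the raw tensor).  Probes not mappable on genome
   Build 38 are removed (a manifest flag; no liftover is performed).  Probes
   whose fraction of raw measures at or above the vendor saturation cap
   exceeds 5% are removed as saturated ("upper bound").  A probe failing
   both rules counts once, as unmappable.
2. **Background subtraction.**  Per individual, the 5% quantile of all
   pooled measures (all probes × both channels × replicates) is subtracted
   from every measure; results are clamped at 0.  The quantile uses linear
   interpolation between order statistics (numpy's default, the "type 7"
   convention) for bit-reproducibility.
3. **Quantile normalization** across individuals within a chip (the Bolstad
   rank-mean method): sort each individual's pooled vector, average across
   individuals at each rank, map every measure to the reference value at
   its rank.  Ties receive the reference value interpolated at their
   average rank, matching limma's `normalizeQuantiles(ties = TRUE)`; a test
   cross-checks against limma itself.  With tie-free data every
   individual's sorted vector is identical afterwards; with ties the tied
   values share the mean of their ranks' reference values.
4. **Log ratios** as above, ε = 1.
5. **Iterative outlier masking**, per probe: compute median and scaled MAD
   (1.4826 × MAD) of unmasked ratios; mask |z − median| > k · scaled MAD
   with k = 5; repeat to a fixed point, at most 10 iterations.  Probes with
   zero MAD mask only values off the median beyond 1e−8.  The procedure is
   idempotent and permutation-equivariant.  Probes left with all values
   masked (or fewer than two at centering) are dropped with a log entry.
6. **Centering** of unmasked ratios per probe (and of age per chip sample);
   residual means are zero within 1e−9.

Bookkeeping follows the identities kept = input − UB − noB38 and
I_tot = I_SNP × 2 × sample size × kept probes (I_SNP = replicate measures
per allele); both are asserted on every report.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, per
individual × probe: carrier status Bernoulli(maf) (maf scalar or
per-probe), heteroplasmy fraction h ~ Beta(a, b) among carriers (defaults
a = b = 2, mid-range; optionally forced to full homoplasmy), h = 0
otherwise.  Channel means are background + brightness·(1−h) and
background + brightness·h (defaults 50 and 1000), each replicate measure
multiplied by unit-mean log-normal noise with CV `noise_cv` (default 0.1),
clipped to the vendor cap (default 65535); gross corruptions replace a
measure with Uniform(0, cap) at rate `outlier_rate`.  Sex is
Bernoulli(0.5), age uniform on 31–85 years, type-2 diabetes
Bernoulli(0.07); diabetic individuals are excluded from analysis, mirroring
a population cohort that screens out insulin-related confounding.
Phenotypes follow the fitted model with z_true defined on background- and
noise-free means with the same ε as QC, so the generative effect scale is
the fitted covariate scale; defaults (mg/dL) put HDL ≈ 51/62 (m/f),
LDL ≈ 139, TG ≈ 145 with a negative sex effect, SDs 13/34/85 — the
magnitudes of middle-aged European cohort tables.  Lipids are truncated at
zero (negligible at default parameters).  TC is always derived, never
drawn.  All randomness flows from one seed through fixed per-stage
sub-streams, so partial pipelines replay identically.

What the generator does **not** emulate: linkage and haplogroup structure
among mtSNPs, population stratification, batch effects beyond the global
background term, probe-specific cross-hybridization, or the empirical age
distribution (only its range).  Passing tests therefore validate the
pipeline's statistical behavior under the stated generative model, not
performance on any real cohort.

## Validation studies and problem sizes

* **Null calibration**: 10,000 probes with no phenotype effect (chips of
  1,000 probes, 300 individuals each) pushed through the full chain;
  nominal p-values are checked for KS-uniformity and for empirical size
  0.05 within the 3·SE binomial band.
* **Family-wise error**: 100 null chips of 411 probes × 300 individuals;
  the fraction with any Bonferroni-significant probe must not exceed
  0.05 + 3·SE.
* **Effect recovery**: 100 replicates of a 120-probe chip, 2,000
  individuals, β_SNP = 3 on HDL; the 95% CI must cover the truth in ≥ 90%
  of replicates, the mean estimate must land within 10% of the truth, and
  the causal probe should be the chip's top hit.
* **Bookkeeping rebuild**: four synthetic chips built to the published
  four-chip design (probe totals, unmappable counts, saturated probes
  planted at the cap, published sample sizes and replicate counts, and the
  published number of gross outlier ratios planted as ±30 log2-unit
  corruptions); exclusion counts, kept totals, masked counts and I_tot are
  then recomputed by the pipeline.

Two validation-design choices deserve explanation:

* **Zero background in the recovery study.**  The 5%-quantile background
  estimate is biased upward by measurement noise, leaving a residual offset
  in the denominator of log2(A/B).  That offset compresses the homoplasmic
  cluster relative to the generative z_true and shifts the fitted slope by
  tens of percent — a property of imperfect background removal, not of the
  estimator.  Recovery of β on the log-ratio scale is therefore measured at
  zero chip background, where the generative and fitted covariate scales
  coincide.  Null and FWER studies keep the nonzero-background default: a
  monotone covariate distortion cannot break the null.
* **Common heteroplasmy at the recovery chip.**  Every third probe of the
  recovery chip (including the causal one) draws h ~ Beta(2,2) in every
  individual; the rest are near-homoplasmic (carrier frequency 0.01).  The
  homoplasmic majority pins the per-individual background quantile at the
  true background, while the heteroplasmic block fills the
  quantile-normalization reference with intermediate intensities so the
  rank mapping is close to the identity on the causal probe's values.  With
  a *rare* variant in near-noise-free synthetic intensities, the robust
  outlier stage flags the few carriers as outliers — correctly, by its own
  rule: they are 10+ robust SDs from the probe median.  On real arrays the
  intensity noise floor is far higher and heteroplasmic signals far
  subtler, so this masking is a feature of clean synthetic data; it is the
  reason effect recovery is validated where the covariate varies in most
  individuals.

## Numerical choices

| quantity | value | note |
|---|---|---|
| background quantile | 0.05 | linear interpolation (type 7) |
| log-ratio ε | 1.0 intensity unit | symmetric; z = 0 for equal channels |
| outlier rule | k = 5, scale 1.4826, ≤ 10 iterations | MAD = 0 probes use abs. tol. 1e−8 |
| saturation cutoff | 5% of raw measures at/above cap | applied before normalization |
| minimum n per probe | 30 after masking | probe skipped below this |
| Wald reference | Student-t, n − 4 df | two-sided |
| Bonferroni factor | probes tested per chip × phenotype | capped at 1 |
| significance | p_adj ≤ 0.05 | per chip |

Degenerate inputs: constant-z probes raise a rank-deficiency error and are
skipped with a log entry; empty cohorts return empty tables; an exact fit
(zero residuals) reports the smallest positive p rather than 0.

## Known limitations

* The upper-bound (saturation) rule and the iterative outlier rule are this
  package's explicit, configurable operationalizations; the original
  chemistry-level rules live in vendor pipelines and are not public in
  detail.
* Quantile normalization snaps isolated intermediate intensities toward the
  reference distribution's nearest mass; when heteroplasmy is rare the
  covariate is monotonically but not linearly related to the underlying
  allele fraction.  Association direction and detection are unaffected;
  absolute effect sizes on the log-ratio scale are conservative.
* With the default nonzero background, ratios for homoplasmic individuals
  are heavy-tailed (small random denominators), and the robust detector
  masks roughly 1–2% of ratios on synthetic chips — visible in the analysis
  drivers' QC tables.  This exceeds the sub-0.05% rates typical of real
  chips, where background removal is aided by vendor-specific controls.
* Each chip simulates its own cohort; overlap of individuals across chips
  is not modeled (the scan never pools individuals across chips, so this
  only affects cross-chip overlap realism).
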