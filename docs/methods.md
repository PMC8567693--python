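# Methods

This note documents the models, the synthetic cohort the package ships for
testing, the numerical choices, and what the test suite does and does not
establish about real data.

## Mediation model

The mediation engine (`placentamed.mediation`) fits two ordinary
least-squares models on z-scaled variables, with the confounder set C
(log pre-pregnancy BMI by default) in both:

    mediator model:  M = α₂ + a·G + g_m·C + ε₂
    outcome model:   Y = α₃ + c′·G + b·M + g_y·C + ε₃

Linear models without an exposure–mediator interaction give the exact
decomposition ACME = a·b, ADE = c′, total = a·b + c′; the package asserts
ACME + ADE = total to 1e-9 at the point estimates.  Intervals are
quasi-Bayesian: `n_sims` coefficient vectors are drawn from N(estimate,
coefficient covariance) of each fit independently, the effect formulas are
applied per draw, and 2.5/97.5 percentiles are reported.  Two-sided
p-values are twice the smaller tail fraction of draws at or beyond zero;
when no draw crosses zero the value is reported as the resolution bound
2/n_sims with an explicit flag, rather than an exact zero.

Proportion mediated is the ratio of the point estimates.  Per-draw ratios
are unstable when the total effect is near zero, so draws with
|total| < 1e-10 are excluded from the proportion CI and tallied
(`n_prop_excluded`); the same principle is applied across replicate
simulations — per-replicate proportions are dropped when the replicate's
|total estimate| < 0.1 — because a ratio with a null denominator carries no
information about mediation share.

### Sensitivity to sequential ignorability

Sequential ignorability (no unmeasured confounding of the M→Y relation) is
relaxed through ρ = corr(ε₂, ε₃).  For the linear system the ACME at a
given ρ is

    ACME(ρ) = (a·s₁/s₂)·[ r̃ − ρ·sqrt((1 − r̃²)/(1 − ρ²)) ]

where s₁, s₂ are residual SDs of the total-effect outcome model
(Y ~ G + C) and the mediator model, and r̃ is the correlation of those two
residual series.  Two identities anchor the implementation and are tested:
ACME(0) equals the baseline a·b estimate exactly (a Frisch–Waugh–Lovell
consequence), and the curve crosses zero exactly at ρ = r̃, which is the
reported `rho_zero_crossing`.

## Polygenic scores

QC removes variants with call rate < 0.95, MAF < 0.01 (founders),
Hardy–Weinberg p < 1e-5 (1-df chi-square on founder genotype counts),
imputation DR2 < 0.7 where available, and any non-autosomal record.
Clumping is the greedy index-variant algorithm: sort by ascending p (ties
by chromosome, then position — deterministic), claim everything within
±1000 kb at r² ≥ 0.1, repeat.  r² is computed from the target cohort's own
maternal dosages: base and target come from the same population here, and
no external LD panel is assumed.  Scores are Σ dosage × |β| over the
BP-increasing allele orientation (equivalent up to a constant to
alt-dosage × signed β, so z-scores are identical), z-scaled with the n−1
variance; a zero-variance score is returned as flagged zeros, never NaN.
The "selected" threshold is the one maximizing adjusted R² against the
analysis trait — placental weight z in the pipeline, since that is the
association the downstream analysis interrogates; all four thresholds are
always reported.  Allele matching against the VCF requires an exact
(effect, other) = (alt, ref) or (ref, alt) match with sign flip; strand
flips are never attempted and unmatched rows (palindromic ones called out)
are dropped with a warning.

## Haplotype transmission

At each SNP, if mother or child is homozygous the split of the child's
alleles into maternal-transmitted and paternal-transmitted is Mendelian
arithmetic.  At double heterozygotes the child haplotype with the longer
exact contiguous match to either maternal haplotype — extending outward
from the focal site within a window of ±25 variants (configurable) — is
taken as maternal; an exact tie leaves the site unresolved, excluded from
all three counts and tallied per pair.  This longest-flanking-match rule is
an approximation to full local-haplotype-sharing inference; it is exact
when phasing is correct and recombination within the window is absent,
which is precisely the regime the synthetic cohort generates, and the test
suite verifies 100% accuracy of resolved calls there.  The paternal
transmitted allele is the child allele not attributed to the mother, so it
is identified from the mother–child pair alone and is reported for duos
too (a `father_present` flag accompanies it); father genotypes are never
consulted.

Window width trades tie rate against robustness: at realistic variant
density (thousands of SNPs) ties are absent; in very sparse panels a
window can be truncated at the array edge and ties become possible, which
is why unresolved counts are surfaced rather than imputed.

## Phenotypes

PP = SBP − DBP; MAP = DBP + PP/3.  BP observations are averaged with equal
weights within early (< 20 w), middle (20 ≤ w < 34) and late (≥ 34 w)
gestation; a record missing a period is flagged and excluded from analyses
requiring it.  Eligibility removes chronic hypertension, hypertensive
disorders of pregnancy, and deliveries before 34 completed weeks.  Birth
and placental weight are standardized against a reference chart keyed by
completed (floored) gestational week × fetal sex × binarized parity; the
chart is an input, and the packaged chart is a synthetic fixture covering
weeks 34–42.  z-scaling uses the n−1 variance throughout; constant input
warns and returns zeros.

## Growth velocity

Each fetus's EFW series (≥ 4 observations spanning ≥ 6 weeks; otherwise
excluded with a logged reason) is fit with a cubic smoothing spline whose
penalty is selected by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`); with exactly 4 points the
λ→0 limit (interpolating natural cubic spline) is used, since GCV needs 5.
Weekly EFW is evaluated on the integer-week grid strictly inside the
observation span — no extrapolation — and velocity at week w is the
increment ending at w, so Σ velocity telescopes exactly to the EFW change
across the grid.  Velocities are z-normalized cross-sectionally per week
(complete-case per week; fetuses whose grid lacks the week are missing,
not zero).  Tertile strata cut at the empirical 1/3 and 2/3 quantiles with
ties to the lower stratum, and the per-week regressions use the stratum as
a numeric 1–3 covariate, so the estimate reads as change per stratum
increase; eight tests (weeks 22–36, every 2 weeks) are Bonferroni
controlled at 0.05/8 = 6.25e-3.

A known accuracy limit, quantified against generator truth: with 6–12
visits and 5% multiplicative EFW noise, GCV occasionally under-smooths
(small-sample λ collapse), and cohort-wide weekly-velocity RMSE sits
around 0.55–0.6 of the true-velocity SD.  The suite pins it below 0.7;
velocity estimates are informative but individually noisy, which is why
inference runs on cross-sectional regressions, not per-fetus values.

## Association battery and power

All analysis variables are z-scaled, so a simple-regression estimate is the
Pearson correlation (asserted to 1e-12).  Linear-vs-quadratic model choice
is by AIC with Shapiro–Wilk residual normality logged; a global linear-model
validation statistic is not reimplemented.  The minimum sample size for a
regression F test solves the noncentral-F power equation with numerator df
u, denominator df n − u − 1 and noncentrality f²·n, by exact bisection on
n (power is monotone in n, and minimality — power ≥ target at n, < target
at n − 1 — is asserted).  f² defaults to R²/(1−R²); because some analysts
pass R² directly as f², both conventions are computed and reported by
`sample_size_conventions` (defaults α = 0.05, power = 0.80, R² = 0.15
give n = 47 and n = 55 respectively).

## The synthetic cohort

The generator (`placentamed.synthetic`) stands in for a real birth cohort
whose data sit behind an access agreement.  Its defaults are the study
conditions: 93 mother–child pairs (with fathers), path coefficients
a = −0.396, b = 0.661, c′ = −0.049 on z scales, SNP heritabilities
0.0569/0.04/0.0496/0.0438 for SBP/DBP/MAP/PP, and a GWAS base sample of
136 000 used to scale emitted effect-size noise.

What it emulates, and how:

- **LD structure**: haplotypes in blocks (600 × 5 variants by default,
  blocks 2 Mb apart — outside the clumping window); within a block all
  variants share one MAF drawn from (0.05, 0.5) and adjacent variants are
  coupled by a copying Markov chain with copy probability sqrt(r²), giving
  adjacent r² at the configured target (0.8 default).
- **Transmission**: each parent receives two pool haplotypes; the child one
  maternal and one paternal haplotype chosen uniformly, with no
  recombination inside the region.  This keeps transmitted-haplotype truth
  exact and makes the haplotype-sharing resolver testable; it is a
  deliberate simplification of real meioses.
- **Causal architecture**: one causal variant per causal block (60 blocks
  by default), placed on the block index position so clumping retains all
  of them; per-variant effects scaled so the genetic liability explains h²
  of the trait.  Emitted summary statistics carry the generating β plus
  sampling noise at the GWAS base size; null variants carry standard-normal
  z-scores so p-value thresholding behaves realistically.
- **Mediation structure**: mediator and outcome are built on z scales from
  the liability, a log-normal BMI confounder and Gaussian residuals whose
  SDs complete unit variance; infeasible coefficient combinations raise at
  configuration time.  Gram-scale weights are back-transformed through the
  packaged chart, so chart adjustment is an exact inverse in the noiseless
  case (asserted to 1e-9).
- **Measured BP**: built around a liability with a small PGS share (0.02
  default), consistent with a null score–pressure association at n = 93;
  visit series follow a mid-pregnancy dip and late rise with 6 mmHg visit
  noise, and SBP > DBP is guaranteed by construction (DBP plus a positive
  pulse pressure).
- **Fetal growth**: per-fetus logistic EFW curves (scale ~4600 g, midpoint
  ~31 w) whose parameters vary independently of the mediation system; after
  week 30 the weekly increment is shifted by velocity_link × mediator z
  (30 g/week per SD by default), so a smaller placenta slows late growth.
  Visits: 6–12 per fetus, first at 12–16 w, last at 36–38 w (checkups are
  weekly beyond 36 w), jittered around integer weeks, with 5%
  multiplicative measurement noise.  The default link magnitude was chosen
  so the late-gestation standardized velocity decrement per score tertile
  is of the size a cohort of ~90 can just resolve at the Bonferroni
  threshold — the regime of interest for the late-emergence analysis.

What it does **not** emulate: recombination and phasing switch errors,
imputation uncertainty (DR2 is emitted as 1.0), population structure,
assortative mating, fetal-genotype direct effects distinct from the
transmitted-allele bookkeeping, gestational-age-dependent confounding, and
visit-frequency differences between practices.  Passing tests therefore
demonstrate that the estimators recover known truth under clean phased
data with linear effects — not that any real cohort satisfies those
assumptions.

## Problem sizes and reproducibility

Every stochastic component takes an explicit seed; one pipeline seed fans
out to per-stage child seeds via `numpy.random.SeedSequence`, and identical
config + seed reproduces byte-identical outputs (asserted).  The test
suite's simulation-heavy checks use compact cohorts (20–60 blocks) and
replicate counts of 40–500 chosen to keep the full suite around a minute
while leaving binomial tolerances meaningful; the acceptance script runs
100 calibrated replicates of the full n = 93 measurement chain, which
takes well under a minute on one CPU.

## Known limitations

- The proportion mediated is a ratio estimator; across replicates its mean
  exceeds the ratio of mean effects by a Jensen-type inflation of a few
  percentage points at n = 93.  Both the per-replicate average (with the
  stability exclusion) and the ratio-of-means are computable from the
  replicate table; the acceptance script reports the former.
- The haplotype-sharing resolver assumes correct phase; switch errors
  would silently mis-attribute transmission rather than raise.
- The packaged variant panels and reference chart are synthetic stand-ins
  that reproduce published marginal counts (class sizes 18/12/11 and
  21/30/16; seven DBP-discordant PP-associated SNPs), not real variant
  annotations or national chart values; analyses of real cohorts must
  supply their own tables.
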