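# Methods

## The problem

A diagnostic accuracy study compares a binary index test T against a
gold-standard disease status D, reporting sensitivity Sn = P(T=1|D=1)
and specificity Sp = P(T=0|D=0). In practice the gold standard is often
applied selectively — typically more often to test-positive patients —
so D is observed only for a verified subset (V=1). Estimating Sn/Sp
from verified patients alone (complete case analysis, CCA) is then
biased: with verification probabilities λ1 = P(V=1|T=1) and
λ0 = P(V=1|T=0), the large-sample limit of the CCA sensitivity is
λ1·Sn / (λ1·Sn + λ0·(1−Sn)), which overstates Sn whenever λ1 > λ0 and
correspondingly understates Sp. This is partial verification bias
(PVB). When verification depends only on the observed test result, D is
missing at random (MAR) given T, and the bias is correctable.

## Estimators

All estimators consume subject-level (T, D, V) data and reduce to a
2×2 T×D cross table; Sn = TP/(TP+FN), Sp = TN/(FP+TN).

* **FDA** — full data analysis on completely verified data; the
  benchmark, available only in simulation.
* **CCA** — the naive verified-only estimate; included as the
  bias-uncorrected reference.
* **Begg–Greenes (BG)** — Bayes inversion: with s_t the size of test
  stratum t (verified or not) and d_t the verified-stratum disease
  rate, Sn = s1·d1/(s1·d1 + s0·d0) and
  Sp = s0·(1−d0)/(s1·(1−d1) + s0·(1−d0)). Under MAR, d_t consistently
  estimates P(D=1|T=t).
* **IPWE** — Horvitz–Thompson weighting: each verified subject
  contributes weight 1/PS to its cell, where the propensity
  PS = P(V=1|T) is fitted by logistic regression of V on T. With a
  binary test the model is saturated (PS = stratum verification
  proportion) and IPWE coincides with BG on every dataset — an exact
  identity the test suite checks; it is the main internal cross-check
  between two independently coded correction routes.
* **MI** — multiple imputation: a logistic model of D on T is fitted to
  the verified subjects; for each of m imputations a coefficient vector
  is drawn from the asymptotic normal of the fit and missing D values
  are drawn Bernoulli (proper imputation). The fit uses White-style
  data augmentation — per outcome class, pseudo-observations at the
  predictor mean ± SD with total pseudo weight p+1 — the stabilisation
  the logistic method of standard MI software applies. This matters at
  low prevalence, where a nearly empty verified stratum would otherwise
  produce degenerate rate draws; it is also why MI retains a marked
  negative Sn bias at low prevalence and small n while BG does not.
* **IPB / SIPW / SIPW-B** — the weighted-resampling correctors, below.

## Weighted resampling

For verified subjects, IPW_i = 1/PS_i and the scaled weights
SIPW_i = IPW_i / ΣIPW form a probability vector. A resample draws
subjects with replacement with these probabilities; any resample whose
T×D table has an empty cell is discarded and redrawn. The per-resample
Sn/Sp are averaged over b valid resamples to give the point estimate.

* **IPB** (inverse probability bootstrap) resamples to the verified
  size n1 — a weighted bootstrap of the verified subset only.
* **SIPW** resamples to the full size n, restoring a complete dataset
  whose distribution estimates that of the unobserved full data; the
  restored samples can feed any downstream complete-data analysis.
* **SIPW-B** first rebalances the diseased weight mass: diseased IPWs
  are multiplied by the observed control:case ratio n_{D=0}/n_{D=1}
  (counted among verified subjects), then by k/RelSize where k is the
  post-update ratio of non-diseased to diseased total weight. After
  normalisation the diseased probability mass is exactly
  1/(1+RelSize), so a RelSize of 1 mimics a 1:1 case–control design.
  This trades Sp precision for Sn precision, which pays off at low
  prevalence.

Normalisation is always over all verified subjects, so the scaled
weights sum to one — the balancing algebra guarantees the mass
identity exactly, and both are asserted to 1e−12 in tests.

### Numerical implementation

Resampling is vectorised: all b resamples are drawn at once by
inverse-CDF lookup (searchsorted) over the scaled-weight CDF, and
invalid resamples are redrawn in batches (budget: 1000 rounds, then an
error naming the degeneracy). One RNG substream drives each (scenario,
repetition); results are reproducible from the master seed and
identical regardless of how scenarios are distributed. A subject-level
single-resample API (`draw_valid_resample`) exists for callers who
need the restored datasets themselves.

## Simulation design

Complete data are multinomial over the four (T,D) cells with
probabilities π1 = Sn·p, π2 = (1−Sn)·p, π3 = (1−Sp)(1−p),
π4 = Sp(1−p). MAR verification masks D with per-subject Bernoulli
draws, λ1 = 0.8 and λ0 = 0.4 by default. A generated pair is kept only
if the complete table and the PVB verified-only table both have four
nonzero cells; the verified-table check is an interpretation (every
estimator needs it), and the low-prevalence CCA means it implies match
the published ones, supporting that reading. The retry budget is
10,000 attempts per dataset.

The study grid crosses p ∈ {0.4, 0.1} with six (Sn, Sp) pairs
(Sn ∈ {0.3, 0.6, 0.9} × Sp ∈ {0.6, 0.9}) at n ∈ {200, 1000}; reference
settings are B = 500 repetitions, b = 1000 resamples, m = 100
imputations, R = 1000 bootstrap replicates.

What the generator does *not* emulate: covariate-dependent (or MNAR)
verification, multi-category or continuous tests, and clustered or
paired designs. Passing tests therefore demonstrate correctness under
test-result-driven MAR verification only; on real data the MAR-given-T
assumption is untestable and substantive.

## Performance evaluation

For B repetitions, bias = mean(θ̂) − θ and SE = the between-estimate
standard deviation (B−1 denominator). **Evaluating the resampling
correctors:** their per-run b-averaged point estimate has a conditional
expectation equal to the IPWE estimate of the same dataset, so the SD
of per-run averages would simply re-measure IPWE's precision. The
published comparison of these correctors instead treats the pooled
per-resample estimates (B×b of them) as the estimate population: the
grand mean is unchanged, while the SE additionally carries the
within-dataset single-resample dispersion — the precision a consumer
of one restored dataset actually experiences, and the quantity that
separates IPB (small resamples of size n1) from SIPW/SIPW-B (full-size
resamples). `run_scenario` follows that convention for IPB, SIPW and
SIPW-B; all other methods are summarised over their B per-run
estimates.

## Confidence intervals

Wald intervals for the CCA proportions; nonparametric bootstrap
percentile intervals (whole records resampled, so the missingness
pattern travels with the data; linear-interpolation quantiles,
recorded in the interval metadata) for BG, IPWE, SIPW and SIPW-B;
Rubin's rules for MI, with total variance W̄ + (1+1/m)·B_v and
degrees of freedom (m−1)(1 + W̄/((1+1/m)B_v))², degenerating to a
normal interval when B_v = 0; and IPB's native percentile interval
read directly off its stored per-resample estimates. BG has no
self-contained interval formula here, so it shares the bootstrap
percentile route. For clinical analyses the number of imputations
defaults to the rounded percentage of incomplete cases.

## Design choices and degenerate inputs

* Missing D uses an explicit sentinel (−1), and construction fails if
  D is present while V=0 or absent while V=1 — MAR bookkeeping errors
  are loud, not silent.
* Cross-table cells are reals so weighted (IPWE) counts reuse the one
  Sn/Sp code path; zero denominators raise errors naming the undefined
  measure. No continuity corrections anywhere.
* A test stratum that is entirely verified or entirely unverified makes
  the propensity logit separate; this is reported with guidance rather
  than returning boundary propensities. PS = 1 is accepted only where a
  caller supplies weights explicitly (a fully verified stratum
  contributes unit weights to IPWE).
* Clinical-shaped fixtures: the two published clinical datasets' cell
  counts are available only as a figure, so the shipped profiles are
  synthetic, matching the published margins exactly (650 subjects /
  344 verified; 900 / 88) with invented verified-stratum rates; they
  exercise the pipeline shape, not the published point estimates.

## Problem sizes used in the checks

The acceptance reproduction runs the headline scenario (p=0.4, Sn=0.3,
Sp=0.6, n=1000) at the reference B=500 and b=1000, and the two
low-prevalence spot checks at their reference settings. The
grid-wide parameter-recovery property runs all twelve n=1000 settings
at B=500 with b=100: the pooled bias is insensitive to b, so a smaller
resample count per dataset buys the full grid at equal fidelity for
the bias check. Interval property checks use R in the 100–200 range,
where percentile endpoints are already stable to well within the
asserted tolerances.

## Known limitations

* The propensity and imputation models condition on T only, matching
  the binary-test setting; no covariates are supported.
* SIPW-B's rebalancing invalidates prevalence-dependent quantities
  (PPV, NPV, accuracy) in the restored samples; use SIPW when those
  are needed downstream.
* MI results at low prevalence are sensitive to the imputation engine's
  stabilisation details; the augmentation used here reproduces the
  standard engine's behaviour but other engines will differ in the
  second decimal.
* Bootstrap percentile intervals around SIPW/SIPW-B nest a full
  resampling estimate inside each bootstrap replicate; with large R and
  b this is the most expensive path in the package.
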