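# Methods

## The POPAN super-population model

The sampled population is open: birds enter (recruit or immigrate), leave
(die or emigrate permanently) and are detected imperfectly at T = 10
annual mist-netting sessions. The POPAN parameterization of the
Jolly–Seber model posits a super-population of N individuals, of which a
fraction β₀ is present before the first session and fractions β₁…β_{T−1}
enter in each inter-session interval (Σβ = 1). Present birds survive each
interval with apparent survival φᵢ and, while present, are detected at
session i with capture probability pᵢ. Apparent survival confounds death
with permanent emigration; entry confounds birth with immigration.

### Likelihood

Writing ψᵢ for the probability of being present and never yet detected at
session i (ψ₁ = β₀; ψᵢ₊₁ = ψᵢ(1 − pᵢ)φᵢ + βᵢ), the probability of first
detection at i is πᵢ = ψᵢ pᵢ. The log-likelihood of the observed history
set factorizes into

* a first-capture component: binomial in N over ever-detected birds, with
  the unmarked counts uᵢ multinomial on the πᵢ;
* a Cormack–Jolly–Seber recapture component over the reduced m-array,
  with cell probabilities q_{ij} = pⱼ ∏ φ (survive) ∏ (1 − p) (evade) and
  per-cohort never-seen-again remainders.

The implementation (`petrelpop.popan.popan_loglik`) evaluates exactly the
log joint probability of the observed unordered histories, which is
verified in the test suite against brute-force enumeration of every
individual's latent entry session, death interval and detection pattern
(agreement to 1e-10 on all small instances, T ≤ 6 in spot checks).

### Parameter structures and counting

Each of φ, p and the entry vector is either constant (".") or
time-dependent ("t"), giving eight candidate models. The constant-entry
model shares one value b across β₁…β_{T−1} and sets β₀ = 1 − (T−1)b by
subtraction; this is the convention under which the best-supported model
φ(.)p(t)b(.) has 13 parameters (1 + 10 + 1 + N). Identifiable-parameter
counts subtract one for each classic Jolly–Seber confounding: the
terminal φ·p product when survival and capture are both time-dependent,
and the initial entry/capture confounding when entry and capture are both
time-dependent. A numerical Hessian rank is computed as a cross-check,
but the analytic count is authoritative (rank estimates are
tolerance-sensitive near boundaries).

### Fitting and uncertainty

Optimization runs on transformed scales — logit for probability blocks,
a scaled logit for the shared entry parameter (so b ∈ (0, 1/(T−1)) and
β₀ stays positive), multinomial logit for time-dependent entry, and
N = n + f₀ with f₀ (never-detected birds) on a log scale. Ten dispersed,
seeded starting points feed L-BFGS-B; ties resolve to the best
log-likelihood. Standard errors come from the inverse of a
central-difference Hessian by the delta method. Probability parameters
get logit-scale Wald intervals back-transformed; N gets a lognormal
interval on f₀, whose lower bound cannot fall below the number observed —
in recovery simulations at the study's parameter values this interval
covers the true N ≈ 95% of the time, against a nominal 95%.

AICc uses effective sample size n = 145, the number of distinct
individuals ever captured. Absolute AICc levels depend on which
data-dependent constants a program keeps, so only AICc *differences*
(hence Akaike weights) are comparable across implementations. Model
averaging follows the standard formulas: N̄ = Σ wᵢ N̂ᵢ, unconditional
SE = Σ wᵢ √(SEᵢ² + (N̂ᵢ − N̄)²), symmetric Wald CI rounded to whole birds,
and the model-variation percentage is the share of the unconditional
variance contributed by spread among the model point estimates.

### Reconstructing per-occasion data from the printed m-array

The shipped dataset is a reduced m-array (releases per year, first
recaptures by year) plus the total of 145 first captures. Unmarked
captures derive as uᵢ = Rᵢ − (column sum at i), with the final year's u
taken from the total; this reconstruction is internally exact (the 64
recaptures implied by releases-minus-new over 2007–2015 equal the
m-array's in-range column events). The study, however, reports 77
recapture events against the table's 73 — the residual 4 (most plausibly
same-session repeat captures, which annual sessions collapse anyway)
cannot be recovered from a reduced table, and the reconstruction is
flagged with a validation warning rather than altered.

On this reconstruction the best-supported model estimates φ = 0.75,
b = 0.07 and p from 0.11 to 0.39, and the eight-model average gives
N ≈ 273 (95% CI ≈ [217, 330]). The N profile likelihood is extremely
flat — values 20 birds away sit within 0.2 log-units of the maximum — so
the point estimate of N is sensitive to exactly those few unresolvable
events and to optimizer stopping rules, while φ, b, p and the model
ranking are stable. Parameter-recovery simulations (500 replicates at the
estimated values) show the estimator itself is essentially unbiased
(relative bias of N̂ below 1%).

## Goodness of fit

The TEST2/TEST3 decomposition screens the CJS assumptions from individual
histories: TEST3.SR (newly vs previously marked × re-encountered later or
not; transience), TEST3.SM (first re-encounter next session vs later),
TEST2.CT (encountered at i or not, among birds known alive around the
transition, × encountered at i+1 or not; trap-dependence) and TEST2.CL
(timing of the next encounter among birds that skipped a session). Each
per-occasion 2×2 table contributes a Pearson chi-square; tables with any
expected cell below 2 are dropped (in the spirit of low-expected-count
pooling), degrees of freedom are summed, and the global statistic is the
component sum. Exact published GOF statistics require the raw histories,
which were never deposited; the suite instead verifies *calibration* —
under a simulated CJS-consistent process the global test rejects at
α = 0.05 between 2% and 9% of the time over 400 replicates — and power
against an injected transient excess.

## Biometrics

Per-trait dimorphism uses SDI = 100·(male mean − female mean)/male mean,
reported to 0.1%. Within-population sex comparisons use the classic
equal-variance two-sample t (df = n₁ + n₂ − 2, matching the study's
df = 119); comparisons against literature populations, where only mean,
SD and n are available, use the Welch statistic with Satterthwaite df
computed from summaries. Bonferroni-adjusted critical p-values are α/m to
3 decimals. All tests are two-sided.

The discriminant sexing function is classic linear DFA with equal priors:
per-class classification functions Σ⁻¹μ_k with constants −½μ_kᵀΣ⁻¹μ_k on
the unbiased pooled within-group covariance, fitted to a seeded,
sex-stratified 80% training split. A record is assigned the class with
the larger function value; exact ties go to female. The study's printed
coefficient set is shipped as a data constant for reference, with a
caveat: its two constants are mutually inconsistent with the printed
per-sex trait means (the implied boundary places the female mean vector
on the male side), so it is not used as ground truth anywhere. Observed
classification rates are instead validated as a property: on synthetic
birds drawn from the per-sex summaries the held-out accuracy must fall in
[0.75, 0.90], bracketing both the ≈ 0.85 accuracy implied by the
Mahalanobis separation of the trait means and the study's observed 80.2%.

Repeatability is the one-way random-effects intra-class correlation from
the ANOVA decomposition, ICC = (MSB − MSW)/(MSB + (k−1)MSW), with the
between-bird F-test p-value; it is cross-checked against an independent
variance-components computation and against pingouin in the tests.

## Phenology

Both logger dialects normalize to a wet fraction per 10-minute bin: the
counts dialect divides positive 3-second tests by 200; the state-change
dialect integrates wet time within bins exactly. Night is taken from the
light record where available (a bin is night if dark on the majority of
days at that clock slot, which is robust to occasional burrow days) or
from clock hours (19:00–07:00) for simulated traces.

A colony visit is a maximal run of fully dry night bins strictly longer
than 4 h — the threshold is the longest continuous flight observed when
all birds are at sea, and "strictly dry" is the default (a permissive
mode tolerating brief wet ticks per bin is available, since field
practice on this point varies). A burrow day is a calendar day whose
immersion record is dry throughout while at least 80% of its daylight
bins are dark; the 80% operationalizes "heavy light interference or no
light by day" and is configurable because no published value exists.
Adjacent night-visit and burrow-day segments merge into one visit.
First arrival is the earliest visit per bird after a season start
(cross-bird mean ± SD in days); incubation bouts are maximal runs of
consecutive burrow days, in whole days.

Nest outcomes follow a fixed taxonomy (successful, chick-lost, egg-lost,
adult-killed, no-egg, empty, active-not-confirmed). A chick present
during the fledging period (on/after 1 May of the closing year, or an
explicit fledging observation) makes a season successful; a chick that
disappears earlier is chick-lost, never successful. Breeding success is
fledged over confirmed-active nests (an egg or chick was seen);
attendance-only and inaccessible nests stay out of the denominator. An
adult found dead matters for the taxonomy only when an egg was confirmed
(adult-killed); a predated adult with no confirmed egg leaves the season
no-egg — this is what reproduces the published active counts (7, 5, 8, 7)
across the four monitored seasons.

## Synthetic generators

Generator defaults are the study's published conditions: N = 293,
φ = 0.76, b = 0.07 and p = 0.25 (mid-range of the yearly estimates) for
encounter histories; the per-sex trait means/SDs (49 males, 72 females)
for biometrics, with traits independent because no correlations were
published, and field quantization applied (0.5 mm wing, 0.01 mm
otherwise); seven birds arriving Normal(day 267, SD 12) with night visits
of 4.5–8 h every 1–4 nights for activity; the empirical outcome
frequencies of the monitored burrows for nests; and the published isotope
group summaries (8.19 ± 0.32 vs 7.37 ± 0.60, n = 10 and 8) for two-group
samples. Latent truth (entry/death times, true sexes, scripted visits,
drawn outcomes) is always returned alongside the observables and never
written into the observable files. Every stochastic call requires an
explicit integer seed and uses a single generator derived from it.

What the generators do *not* emulate: individual heterogeneity in
capture or survival, trap response, trait correlations, logger clock
drift and light shading artefacts, and observer-dependent measurement
bias. Passing recovery tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to these field
realities.

## Numerical and reporting conventions

Occasions are calendar years, 1-based in reports with year labels.
Percentages are reported to 0.1, bird counts rounded to integers,
probabilities to 2 decimals in reports. Mean breeder percentages average
the unrounded yearly percentages over the years with nest data
(2011–2016). Chi-square tables reduced to zero degrees of freedom yield
an undefined p (NaN), not an error. Optimizer settings: L-BFGS-B,
ftol 1e-12/gtol 1e-8 on the transformed scale, 10 multi-starts (3 in
large simulation studies, where the constant-parameter likelihood is
well-behaved); simulation sizes in the test suite (400 GOF replicates,
500 recovery replicates, 500 birds per sex for the sexing property) keep
the whole suite around a minute while leaving Monte-Carlo error well
inside the asserted bands.

## Known limitations

* The super-population point estimate from the reduced m-array is
  ill-determined by design of the input (flat profile); treat N's
  interval, not its point value, as the scientific result.
* The GOF components use one specific, documented table construction;
  other programs pool differently, so printed statistics from other
  software will differ even on identical data.
* The discriminant function is linear with equal priors; no
  cross-validation beyond the single stratified split used in the study
  design is implemented.
* Light-based night inference assumes the deployment is long enough for
  per-clock-slot majorities to be meaningful (a week or more).
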