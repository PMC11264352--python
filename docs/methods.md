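# Methods

## Multi-state mark–resight model

The core model is the standard two-observable-state Arnason–Schwarz
model, written as a hidden Markov model over latent states
{1 = failed/non-breeder, 2 = successful breeder, dead}. The likelihood
of one encounter history is conditioned on the state at first capture;
per interval a bird in state *r* survives with probability Φʳₜ and,
*given survival*, transitions with probability ψʳˢₜ
(survive-then-move ordering — the alternative move-then-survive ordering
is not implemented and every output states the convention); per
occasion after first capture a live bird in state *s* is detected with
probability pˢₜ, and the dead state emits "not detected" with
probability 1. States are treated as observed without error when the
bird is detected.

**Trap-dependence.** Colony-faithful birds are more detectable the year
after a sighting ("trap-happiness"). The canonical correction here is a
detection-augmented HMM: p at occasion *t* carries a trap class that is
*first-after-release* iff the bird was detected at the most recent
active occasion before *t* with no active occasion in between, and
*later* otherwise. The classic history-splitting transform (one segment
per release, recapture "age" classes on p) is also provided for
export/parity; the two formulations are provably equivalent by the chain
rule and the Markov property, and the test suite verifies equality to
1e-10 over every history of length ≤ 5.

**Inactive occasions.** A season with no field effort is kept as an
occasion with p fixed to 0. Time-dependent survival then spreads the
two-year survival product over two nominal intervals; both are flagged
jointly confounded and excluded from any verdict. Likewise, in fully
time-dependent models the final-interval survival and final-occasion
detection are identifiable only as a product and are flagged.

**Fitting.** Parameters live on the logit scale under treatment-coded
design matrices built from declarative effect structures (subsets of
State, Time, Sex, TrapClass with interactions; `A*B` expands to
`A + B + A:B`). Optimisation is L-BFGS-B with an analytic
forward–backward gradient (verified against finite differences),
default 5 jittered multistarts (tests and the cascade use 1; the
likelihood surfaces here are well behaved), and a gradient tolerance of
1e-8 (the optimizer may terminate earlier on relative function
decrease; the gradient norm is recorded on the fit). Standard errors
come from the inverse observed information (central differences of the
analytic gradient) mapped through the delta method; SEs are flagged
unreliable at boundary estimates.

**Model selection.** AICc = −2logL + 2K + 2K(K+1)/(ESS−K−1), with K the
number of estimable coefficients and ESS the number of weighted
release-intervals (each bird contributes one unit per interval from its
first capture to the study end). The ESS convention for multi-state
data is not uniquely standardised across programs; it is a constant per
dataset, so ΔAICc between models is affected only through the
small-sample correction term, and the convention is recorded in every
manifest. Deviance is reported as −2logL with no saturated-model
subtraction. The selection cascade fixes nuisance structure stepwise:
all p candidates under fully parameterised Φ and ψ (defaults
Φ(State×Time), ψ(State×Time); sex can be added via `full_phi`/`full_psi`),
then ψ candidates under the chosen p, then the ranked Φ table. Ties in
AICc are broken by smaller K, then spec name.

**Goodness of fit.** The trap-dependence diagnostic builds, for each
interior active occasion *t* and departure state, a 2×2 table of
(detected at previous active occasion) × (detected at *t*) among birds
first caught before *t* and seen again after *t* (hence known alive at
*t*). Since the state at *t* is unobservable for undetected birds,
stratification uses the state at the bird's most recent detection — a
defined stand-in for the full multi-state test batteries of dedicated
GOF software, whose printed statistics this module does not claim to
reproduce. Components with any expected cell below 2 are pooled
Cochran-style into a single leftover table; the pooled statistic is the
sum of component Pearson χ² with one df each, and the signed sum of
(observed − expected) in the detected/detected cell gives the direction
(positive = trap-happiness). Simulation shows a null rejection rate
within [0.02, 0.08] at α = .05 and essentially full power against 2×
trap-happiness at n = 2000.

## Costly-year classification

Verdicts use the ±1 SE interval-overlap rule: *costly* when the state-2
interval lies wholly below the state-1 interval, *beneficial* when
wholly above, *equal* otherwise. A z-test alternative exists behind a
flag but the SE-overlap rule is the reporting default. Note the rule's
operating characteristics: for two equal-SE estimates the disjointness
threshold is ≈1.41 standard deviations of the difference, i.e. a ≈8%
chance per truly-equal year of a spurious non-equal verdict. This is a
property of the rule itself, accepted deliberately; tests therefore
check near-certain detection of a large injected deficit plus a bounded
spurious rate rather than exclusivity. Compound (inactive-year) and
terminal intervals are never classified. Early-vs-late period contrasts
report both the exact Wilcoxon rank-sum and Welch's t.

## Time–energy budgets

Tracks (timestamp, lon/lat, depth from pressure, optional dynamic
acceleration; sampling 1–330 s) are classified per sample by priority
rules: depth > 1 m → dive; great-circle ground speed > 5 m/s → fly;
within 200 m of the colony → rest on land; else surface swim.
Position-less (accelerometer) deployments use depth plus dynamic
acceleration thresholds (fly ≥ 0.6, rest ≤ 0.05, middle band = swim).
All thresholds are configurable and logged; they are defaults from
common seabird biologging practice, and the threshold classifier is a
deliberate, simpler stand-in for spectral accelerometer classification
— a fidelity limitation when transferring to real accelerometer data.
Budgets weight each inter-sample interval by its duration; gaps longer
than 600 s are excluded from the denominator, deployments under 24 h of
labelled time are excluded (the study's inclusion filter), and mostly
unlabelled deployments are flagged unusable. DEE (kJ/day) is
24 · Σₐ fₐ·MRₐ over pooled fractions of the whole 24–72 h recording
(per-24 h blocks are not normalised separately). Mass-specific DEE is
deliberately not computed. Metabolic rates ship with **no defaults**:
they are doubly-labelled-water-calibrated physiology and must be given
with a provenance note; the examples use clearly-labelled synthetic
rates (20/40/60/100 kJ/h).

## DEE covariate layer

Candidate linear models are every hierarchical subset of
`DEE ~ Year * BroodSize * BroodAge * AdultAge` with two-way interactions
only (113 models for four mains: an interaction enters only with both
mains), ranked by AICc with K = coefficients + 1 (residual variance) and
ESS = n. Models within 2 ΔAICc are retained for sensitivity re-analysis;
model averaging is deliberately not performed (correlated covariates
make averaged coefficients hard to interpret). Adjusted year means are
predictions at the continuous covariates' sample means; pairwise year
contrasts use the studentized-range (Tukey–Kramer) adjustment on the
residual df, which can never fall below the unadjusted t-test p.
Residual assumptions are checked with Shapiro–Wilk and Breusch–Pagan at
α = .05 (the specific tests are this package's documented choice); a
failure triggers a log-transformed refit carrying a transform flag.
Productivity and apparent-survival analyses use Poisson and
binomial/logit GLMs with Type-II likelihood-ratio term tests (Wald is
available behind a flag); complete separation is flagged and refit with
a small ridge penalty, and those LR statistics are approximate. Only
fixed-effects models are fitted: duplicated-individual data with zero
individual variance yields equivalent inference, matching the
zero-variance random effect found in the motivating dataset.

## Synthetic data

Generators cover every pipeline input with known truth and byte-exact
seed determinism.

* **Encounter histories.** Uniform recruitment over active occasions
  (an optional ramp emulates staggered banding), initial state
  Bernoulli(0.5), then per interval survive → transition → detect with
  trap-class-aware p and p = 0 at inactive occasions. Never-detected
  birds are dropped, mirroring real data's conditioning on first
  capture.
* **Tracks.** Piecewise-constant activity schedules; rest pins to the
  colony point, flight moves at 15 m/s with persistent heading, swimming
  at 0.5 m/s random walk, dives are 2–40 m excursions at swim-speed
  drift; Gaussian position jitter and random fix-dropping emulate GPS
  error. The generator does not emulate spatially realistic oceanography,
  weather-driven behaviour or individual heterogeneity, so passing
  recovery tests demonstrates correctness of the classification and
  budget arithmetic, not field-grade classifier accuracy.
* **DEE records.** Covariates uniform over the observed field ranges
  (brood size 1–5, brood age 7–41 d, adult age 0–15 y);
  DEE = year mean + age slope · age + Gaussian noise. The four-year
  preset uses year means 1376/1722/1678/1301 kJ/day with n = 13/13/22/10,
  an age slope of −15 kJ/day/yr and sd 150 kJ/day. Because the year
  means enter as intercepts at age 0, covariate-adjusted means sit
  ≈ slope × mean(age) below them; year *ordering* is the preserved,
  tested quantity.

The `middleton_like` preset bundles 17 annual occasions (one inactive),
two states, sex-structured detection with 2× trap-happiness, and the
four-year DEE scenario.

## Problem sizes and numerical choices

Simulation-based checks run at: parameter recovery 100 replicates of
n = 3000, T = 10; structure-selection cascade 50 replicates of n = 3000;
GOF null calibration 500 datasets of n = 600 (acceptance script: 200)
and power 100 datasets of n = 2000 (script: 50); energetics 100 noisy
tracks (script: 50); GLM calibration 500 seeds. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands.
Likelihood equality against the enumeration oracle is asserted to
1e-10; closed-form MLE agreement to 1e-8; probabilities are kept off
the boundary in random draws ([0.2, 0.95]) so the oracle comparison is
well conditioned. AICc requires ESS > K + 1 and raises otherwise.
Degenerate inputs (all-zero detection, single-level factors, empty
periods, sub-24 h deployments, complete separation) raise or flag
rather than silently proceeding.

## Known limitations

* Two observable states only; no state uncertainty (multi-event), dead
  recoveries, random effects or overdispersion-ĉ machinery.
* The GOF diagnostic is a defined contingency stand-in, not a
  re-implementation of the full dedicated test batteries.
* The activity classifier is threshold-based; spectral accelerometer
  classification is out of scope.
* Apparent survival confounds mortality with permanent emigration, as
  in any single-site mark–resight design.
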