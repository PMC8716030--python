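# Methods

## Model

Acute ocular severity is observed at two visits per patient — the initial
ophthalmological presentation and the worst-condition follow-up visit — and
graded 0–3. For modelling, grades 2 (severe) and 3 (very severe) are pooled
into one state because both denote extensive ocular-surface inflammation and
carry the chronic-phase risk; the process is the progressive three-state
illness–death graph 0→1, 0→2, 1→2 with state 2 absorbing and no recovery
transitions (the observed cross-tabulation has an empty lower triangle).

Time is clock-forward: day 0 is disease onset (first erythema) and all
entries, events and censorings are days since onset. The Markov assumption
is that transition intensities depend on the current state and t, not on the
history of arrival. Each transition has a proportional-hazards intensity
α_qr(t|x) = α_qr0(t)·exp(β_qr′x) with its own unrestricted baseline; the
three transitions are fitted as separate models, which for transition-specific
covariate effects is equivalent to a joint stratified fit.

### Counting-process construction

A two-visit record is expanded into at-risk intervals:

* While in state 0 a patient contributes intervals (0, t] for *both*
  competing transitions 0→1 and 0→2; at most one of them ends in an event
  (competing risks are exclusive).
* A patient presenting in state 1 or 2 has their transition placed at the
  presentation day; a patient worsening after presentation has the event at
  presentation day + initial-to-worst elapsed days.
* Entering state 1 opens a delayed-entry (left-truncated) interval for 1→2
  until progression or the final follow-up examination (censoring).
* Intervals that would have zero length (presentation on day 0, or a worst
  visit on the presentation day) have their exit shifted by +0.5 day; the
  half-day offset keeps entry < exit without reordering any distinct days.
* Patients examined by an ophthalmologist before erythema developed have
  negative presentation days; they cannot be placed on the onset clock and
  are dropped from the multi-state analysis only (they stay in the
  descriptive layer), matching the 230 → 227 cohort flow.
* Records with a missing covariate are rejected (complete-case analysis);
  records whose worst grade is below the initial grade are data errors.

### Estimation

The per-transition Cox model maximises the delayed-entry partial likelihood
with Newton–Raphson and step-halving on an internally standardized covariate
scale. Convergence requires score max-norm ≤ 1e-6 (or relative
log-likelihood change < 1e-9, capped at 50 iterations). Tied event times use
the Breslow approximation by default — matching the default of the
commercial software that produced the published table — with Efron available
by flag; the two coincide on tie-free data. Inference is Wald: covariance
from the inverse observed information, 95% CIs exp(β ± 1.96·se), two-sided
p-values, no multiplicity adjustment. A monotone or quasi-separated partial
likelihood (a standardized coefficient running past 8, or a standardized
standard error above 50) is flagged non-converged with the direction of
divergence; constant covariate columns are dropped with a warning and
reported as NaN.

The Breslow cumulative baseline hazard dÂ_qr0(u) = d_qr(u)/Σ_{i∈R(u)}
exp(β′x_i) reduces exactly to the Nelson–Aalen estimator at β = 0. Transition
probabilities are the product integral P(s,t) = ∏_{u∈(s,t]} (I + dÂ(u)),
with Nelson–Aalen increments off-diagonal and negative row sums on the
diagonal (Aalen–Johansen); each factor is a stochastic matrix, so the
estimate is row-stochastic to machine precision, has P(s,s) = I, and gives
monotone absorption probabilities. An event time with an empty risk set
contributes no increment (the probability mass is frozen; logged as a
warning). Model-based prediction for a covariate profile rescales the
Breslow increments by exp(β′profile) per transition before the same product
integral; a rescaled increment row exceeding total mass 1 is renormalised so
every factor remains stochastic (only possible for extreme profiles in small
risk sets).

The four-panel stratified display crosses age at onset (cut-off 45 years, a
clinical choice) with NSAIDs exposure. Because the study describes
stratified estimation by subsetting, the nonparametric per-stratum
Aalen–Johansen estimate is the default for the four panels; Cox-based
profile prediction is provided as the labelled alternative
(`predict_from_cox`), since the published figure's construction is ambiguous
between the two. The headline grid is integer days 0–30 from onset — the
window the study identifies as containing essentially all progression.

### Descriptive layer

Patients are grouped by worst-condition grade as Grade 0 / Grade 1 /
Grade 2/3; hypothesis tests compare Grade 0/1 against Grade 2/3. Continuous
variables use the Wilcoxon rank-sum test: the exact permutation distribution
of the midrank sum for combined n ≤ 20, otherwise a normal approximation
with tie-corrected variance and 0.5 continuity correction (the behaviour of
the major commercial implementations). Categorical variables use Fisher's
exact test with the probability-mass ordering (two-sided p = total
conditional probability of margin-fixed tables no more probable than the
observed one); r×c tables are handled by exhaustive Freeman–Halton
enumeration over the free cells with a 10^7-table budget, far above any
table arising here. Mid-p and tail-doubling conventions would give different
values and are deliberately not used.

Covariate percentages use all patients of a group as denominator. The
chronic-outcome variables (ocular sequelae, visual disturbance, dry eye) use
the non-missing patients of the group: the 0/3/7 missing-outcome patients
are excluded from those denominators, while deceased patients keep their
recorded outcomes. This is the only accounting under which the published
outcome percentages (e.g. 46/86 = 53.5% sequelae in Grade 2/3) are
internally consistent, and it is asserted in the tests.

## Synthetic data

### The deterministic study fixture

`make_study_fixture()` rebuilds a 247-record cohort reproducing every
printed count at once: the 17 filter exclusions with their outcome tables
(7 late-worst-visit patients, all severe with sequelae; 10 late-presentation
patients, 1/5/4 by grade with one death), the eligible 230 with the exact
initial×worst cross-tabulation, per-group covariate counts, outcome counts,
the per-group and pooled medians and ranges of age, subscore, presentation
day and follow-up, the 213/230 two-week presentation share, and the three
negative-presentation-day patients. The split of those three (one
mild-initial who stayed mild, one severe-initial, one very-severe-initial)
is the unique reconstruction consistent with 227 analyzable subjects and
100/68/23 transition events.

What the fixture does *not* carry is real joint structure: the publication
prints margins and per-group counts only, so attribute combinations within a
group are filled by fixed rotating-offset assignments, and continuous values
are near-linear integer ramps anchored at the printed medians/ranges and
spread across the group by stride permutations (so that the conventions do
not manufacture covariate–time associations or separation). Consequently
hazard ratios fitted to the fixture are conventions, not reproductions of
the published estimates, and nothing downstream treats them as such. All
conventions are listed in the returned manifest.

### The stochastic simulator

`simulate_cohort()` draws cohorts from exactly the process the analysis
assumes: covariates from the pooled printed margins (sex 134/230 female,
TEN 69/230, NSAIDs 70/230, etc.; age from a normal with mean 55 and SD 18
truncated to the printed 5–90 range; subscore 1 + Binomial(10, 0.45),
matching the printed medians ~5 on 1–11), competing exponential times out of
state 0 (Weibull shape available), a clock-forward exponential 1→2 hazard
after mild-state entry, an independent exponential censoring time (mean 30
days) and a lognormal presentation delay (median 4 days). Generating log
hazard ratios default to the published per-transition point estimates, and
the severe/very-severe grade split uses the printed worst-grade margin
(30/93 very severe). Chronic outcomes are sampled conditionally on the worst
state at the printed per-group frequencies.

Records are written in the registry's two-visit format such that the
reconstructed counting process coincides exactly with the simulated
trajectory: a first transition occurring before the scheduled presentation
is recorded as the presentation itself (symptom-triggered referral), which
is also why a trajectory can never straddle three distinct observed states.
Simulated day values are kept continuous rather than rounded to integers so
the generating model is exactly the fitted model; the deterministic fixture
uses integer days like the registry.

Baseline rates were calibrated once to the study's printed event structure
and then frozen: α01 = 0.159, α02 = 0.060, α12 = 0.0040 per day give a
median state-0 exit of ≈4.2 days (the printed median presentation delay is
4 days), a ≈1.4:1 split of state-0 exits between mild and severe (printed
events 100:68), ≈22% of mild-state entrants progressing (printed 23/100)
and ≈22% of subjects censored in state 0.

What the simulator deliberately does not emulate: visit-driven interval
censoring (states change at exactly observed days), mortality as a competing
endpoint, recovery transitions, within-state-2 grade dynamics beyond a
labelling draw, and real joint covariate dependence (covariates are drawn
independently). Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not robustness
to the observation scheme of real registry data.

## Parameter recovery and its limits

With cohorts of n = 500 the mild→severe transition carries roughly 50 events
against nine covariates, and the partial-likelihood MLE of a log hazard
ratio is then noticeably inflated: across replicates the geometric mean of
the recovered NSAIDs hazard ratio is ≈4.1 against the generating 3.83
(≈+8% on the hazard-ratio scale, ≈+0.08 on the log scale). This is the
well-known finite-sample bias of Cox regression with few events per
covariate, not an implementation artifact: the same data refitted with an
independent survival package agree to <1e-4, the bias shrinks toward zero at
n = 2000–8000, and the 95% Wald CIs still cover the generating value at
≈93–94%. Recovery checks at moderate n and the CI-coverage band are asserted
in the test suite; the strict "geometric mean within ±3 Monte-Carlo standard
errors" form of the check cannot be met at n = 500 by any unpenalised
partial-likelihood fit, because the systematic small-sample inflation
exceeds the Monte-Carlo band of a 200-replicate mean, and the corresponding
test documents this by failing.

## Problem sizes and numerical choices

The test suite runs the full fixture pipeline, 200 recovery replicates of
n = 500, and consistency checks at n = 2000 (homogeneous-process
Aalen–Johansen vs the matrix exponential of the generating intensity matrix,
within a 3.5·√(0.25/n) binomial envelope); the acceptance script uses 400
replicates of n = 500. Tolerances: row-stochasticity and Chapman–Kolmogorov
to 1e-10; Kaplan–Meier reduction and Breslow/Nelson–Aalen identities to
1e-12; agreement with the independent Cox implementation to 1e-6; exact
tests equal to enumeration oracles to 1e-9 relative. Newton–Raphson is
initialised at β = 0; ties in the Wilcoxon exact enumeration use midranks;
all simulations are driven by explicit integer seeds and are byte-for-byte
reproducible.
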