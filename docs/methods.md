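# Methods

`oncnet` implements a claims-to-inference pipeline for studying how an
oncologist's departure changes the network position of the colleagues
who remain, using annual physician patient-sharing networks built from
Medicare-style fee-for-service claims. Because the original claims
files require a data use agreement and are not redistributable, the
package pairs the measurement-and-inference pipeline with a synthetic
claims generator that plants known ground truth at every stage. This
note records the model, the generator's design, the parameters that
matter, and the numerical choices.

## The measurement pipeline

**Patient cohort.** A beneficiary enters the cohort when a diagnostic
biopsy during the study years (2016–2019 by default) is followed by two
cancer diagnosis codes of the same cancer family (breast C50.x, lung
C34.x, colorectal C18.x/C19/C20) on separate days within 12 months;
there is no cancer diagnosis in the 12 months before the biopsy
(incident disease); age at biopsy is 66–99 completed years (boundaries
inclusive); and enrollment is continuous from 12 months before to 12
months after the biopsy. Exclusion reasons are evaluated in that fixed
order and the first failure is recorded, so attrition tables are
reproducible. Two interpretation choices are ours: the two confirmatory
codes must lie strictly after the biopsy day, and they must match the
biopsy's cancer family.

**Physician cohort.** Every physician with at least one encounter with
a cohort patient inside that patient's care window (3 months before to
12 months after biopsy) is profiled. Specialty comes from the first
three NPPES-style taxonomy codes (medical oncology, radiation
oncology, surgery, in that priority); physicians with surgical
taxonomy additionally need a cancer-directed surgical procedure on a
cohort patient, otherwise they are kept as non-oncologists — present
in the networks, absent from the analytic cohort. The analytic cohort
is restricted to oncologists with at least one carrier claim in every
study year ("present throughout"); an oncologist who departs exactly
once is retained in the years before the departure, and oncologists
with departures in more than one calendar year are excluded outright.

**Departure detection.** For each oncologist-year, carrier claims are
ordered by service date (ties by claim id; billing ZIP is constant
within a day by construction) and transitions — positions where the
billing ZIP differs from the previous claim's — are counted. A single
ZIP transition in a calendar year marks a move. Because multi-site
practices (e.g. rural outreach) produce many ZIP transitions, the
sequence is also mapped to hospital referral regions (HRRs); a single
HRR transition likewise marks a move. The default rule is the union of
the two criteria, with the ZIP rule taking precedence for labeling;
`mover_rule` can restrict to either. The departure ZIP is the
plurality billing ZIP over the claims before the final transition
(lexicographic tie-break), and departure rurality is that ZIP's RUCA
dichotomy.

**Networks and node measures.** One undirected network per calendar
year connects physicians who shared at least one cohort patient that
year; the edge weight is the count of unique shared patients. Node
strength (sum of incident weights) and the linchpin score use the
weights; local transitivity and Burt's constraint are computed on the
unweighted skeleton, matching the statement that weights enter the
strength and linchpin calculations. The linchpin score of an
oncologist with specialty s is the weight-fraction of their
other-specialty neighbors who have no tie to specialty s other than
the focal oncologist (an unweighted variant is a configuration
switch); "linchpin oncologists" are the top 15% of scores within their
specialty, thresholded at the order statistic of rank
floor(0.85·n)+1 so exact ties at the threshold are all flagged.
Transitivity is undefined below degree 2, constraint and linchpin at
degree 0; undefined values propagate as missing and are never imputed.
A tie present in consecutive years is *persistent*, one absent the
prior year is *new*; node strength is decomposed over the two subsets.
Patient volume is the count of unique cohort patients seen in the
year.

**Exposure and outcomes.** A retained oncologist is *connected* to an
oncologist departing in year y when the pair's shared-patient counts
over years y−1 and y sum to at least k (default 2; a stricter variant
requires ≥ k in each year; sensitivity thresholds 3–5 are supported
and exposure counts are non-increasing in k). Connection counts are
kept overall, for same-specialty movers, and for movers flagged as
linchpins in their last full year. Outcomes are one-year changes
(year minus year−1) in strength, transitivity, constraint, linchpin
score and volume, for observation years 2017–2019.

**Inference.** Baseline (2016) covariates are compared between ever-
and never-connected physicians with standardized mean differences:
pooled-SD form for continuous covariates, proportion-variance form for
binary ones, and for K-category covariates the Mahalanobis form over
K−1 category-proportion differences with the average multinomial
covariance (singular covariances raise, never silently regularized).
A logistic propensity model of ever-connected status uses every
covariate with unweighted SMD ≥ 0.1; ATE-form IPTW weights (1/p and
1/(1−p)) feed the outcome models as design weights. Each outcome model
is a linear mixed model of the outcome change on the connection count
with crossed random intercepts for HRR (geographic clustering) and
physician (repeated annual measures), fitted separately for rural and
urban practices. Significance uses a Bonferroni threshold of 0.05/5 =
0.01 across the five outcome families, with matching 99% Wald
intervals. The pre/post analysis of persistent- and new-tie strength
around 2018–2019 departures uses a weighted paired t-test whose
standard error is inflated through the Kish effective sample size
n_eff = (Σw)²/Σw², with n_eff − 1 (possibly fractional) degrees of
freedom; with equal weights it reduces exactly to the classical
paired t-test.

The weighted crossed-intercept model is fitted in-package by profiled
REML (no installed Python library accepts design weights with crossed
random intercepts). The marginal covariance σ²(W⁻¹ + ZGZ′) is handled
with the Woodbury identity; because the within-factor Gram blocks are
diagonal, the inner system reduces to a Schur complement the size of
the smaller factor, so fitting is O(n) in observations. Components
with fewer than two levels, or confounded with the residual (one
observation per level), are dropped with a warning; with none left the
fit degenerates to weighted least squares, which reproduces OLS under
equal weights. The implementation agrees with statsmodels MixedLM
(variance-components formulation) to ~1e−5 on unweighted crossed data.

## The synthetic generator

The generator emulates: a ZIP→HRR→RUCA geography (half-up-rounded
rural share; RUCA codes 4–10 rural by default, configurable); an
oncologist workforce apportioned to the published specialty mix
7150:3229:8495 by largest remainder, with sex, taxonomy lists, a home
HRR/ZIP and a log-normal "attractiveness" that drives care-team
demand; beneficiaries with demographics, cancer types, enrollment
spans and planted eligibility violations (exact largest-remainder
allocation per violation category); day-granular carrier and inpatient
claims induced by per-patient care teams (medical oncologist and
surgeon always, radiation oncologist with cancer-type-dependent
probability, one primary-care physician) drawn within the home HRR
with a small cross-HRR leakage; and mover trajectories.

Design choices that make the planted truth exactly recoverable:

* **Billing ZIP is a pure function of the calendar date** per
  physician. Date-ordered claim sequences therefore realize the
  intended transition pattern regardless of claim volume, and same-day
  claims always agree. Monthly anchor office visits (billed to planted
  non-cohort patients, so they never enter the networks) guarantee
  activity on both sides of every move. Multi-site trajectories visit
  the secondary site in months 4 and 8 only: at least two transitions
  per year (never mistaken for a move) while the primary site keeps
  the plurality of claims, so measured rurality equals the home ZIP's.
* **Calendar years are exchangeable.** Patients are allocated evenly
  across diagnosis years and their encounters stay within the
  diagnosis year; workforce exits are matched by same-specialty
  entrants the following year. Without this, cohort-accrual edge
  effects and shrinking workforce capacity produce size-proportional
  strength drifts that masquerade as departure effects.
* **Movement changes geography only.** A mover's care-team
  participation is stationary through and after the departure year, so
  under a zero effect plan, exposure to a departure is exchangeable
  with non-exposure and the null calibration of the downstream models
  is meaningful. Planted mover connections are likewise stationary
  relationships (the pair shares patients in every study year).
* **Effects are integer patient-sharing events.** Per connection, the
  volume effect adds new single-physician or single-partner patients
  and the strength effect adds shared-patient weight through "hub"
  patients seen only by the focal physician and non-oncologist
  partners — never by other analyzed oncologists and never by movers,
  so planting cannot change anyone's exposure count or leak outcome
  signal across physicians. Fractional effects are realized by
  stochastic rounding (floor plus Bernoulli). The planted
  relationships persist from the departure year to the study end: the
  effect is a one-time level shift, fully visible in the
  departure-year change and absent from later changes.
* **Sharing is concentrated in referral communities.** Physicians
  belong to stable practice clusters (~`community_size` members) within
  their HRR, and a patient's surgeon, radiation oncologist and
  primary-care physician come from the medical oncologist's community
  with probability `community_prob`. Pairwise shared-patient counts are
  therefore high and stable within communities rather than thin and
  marginal across the whole market — as in real referral networks.
  This matters statistically: pairs that cross the ≥2 shared-patient
  connection threshold by chance have both years' sharing conditioned
  upward (a regression-to-the-mean artifact that masquerades as a
  departure effect); concentrating sharing makes almost all connections
  stable relationships for which the conditioning is immaterial.
* **Confounding** enters by selecting mover connections with
  probability tilted by the physician's standardized log
  attractiveness (slope `confounding_strength`), on top of the natural
  tendency of high-volume physicians to share more patients with
  everyone, movers included.

Defaults: 200 oncologists + 100 non-oncologists, 4,000 patients, 10
HRRs × 5 ZIPs, 30% rural ZIPs, 10% movers (half clean single-site
moves, the rest within-HRR and cross-HRR multi-site moves), 2%
multi-year movers, 2% attrition, about 4 connections per mover,
attractiveness sigma 0.35 and confounding slope 0.5 — the last two
calibrated so the baseline ever-vs-never imbalance matches the
published cohort's scale (unweighted SMD ≈ 0.65 for node strength
against a printed 0.642). A four-year default study runs in seconds.

## Validation experiments (`oncnet.experiments`)

The published regression tables cannot be reproduced without the
restricted claims, so the pipeline is validated by construction:

* **Recovery** — a 2,000-oncologist confounded study (ten regional
  markets, six connections per departure) with a planted rural effect
  of 8.0 strength points and 1.3 patients per connection (urban
  effects null); the IPTW-weighted rural models must cover the planted
  values with their 99% CIs, and every propensity covariate's weighted
  SMD must fall below 0.1. Across seeds the rural estimate lands at
  8.0–9.3 with full CI coverage, the urban estimate stays null, and
  the maximum weighted SMD is ~0.02. Runs in ~1 minute.
* **Null calibration** — 200 replicates of a 240-oncologist study with
  zero effects and zero planted confounding; the planted-effect
  stratum's exposure coefficient covers zero in ≥95% of replicates
  (measured 95–99.5%; the urban stratum, reported alongside, measures
  95.5–100%). IPTW design weights enter the mixed model as precision
  weights, which can understate Wald standard errors when outcome
  noise scales with practice size; weight truncation
  (`weight_truncation=(1, 99)`) is available as a sensitivity option,
  and cluster-robust alternatives are out of scope.
* **Oracle equivalence** — strength, transitivity, constraint and
  linchpin agree exactly with brute-force reimplementations on 1,000
  random graphs of ≤12 nodes (and with igraph where defined).
* **Detection fidelity** — sensitivity 1 for single-site, within-HRR
  and cross-HRR-multi-site trajectories, false-positive rate 0 for
  non-movers and outreach practices, multi-year movers flagged for
  exclusion; exact by the trajectory construction above.
* **t-test calibration** — exact reduction to the classical paired t
  under equal weights, and a type-I error within 0.01 of the nominal
  5% over 5,000 null replicates with right-skewed weights (measured
  0.044–0.052; the fractional-df t reference is mildly conservative).

## What the synthetic study does and does not show

Passing these experiments shows the pipeline measures what the
generator planted under conditions that mimic the study's scale,
confounding structure, geography and claim mechanics. It does not show
that real claims behave like the generator: real patient-sharing has
heavier-tailed volumes, seasonal and secular trends, windows that
straddle calendar years, coding noise in taxonomy and diagnosis
fields, and departures entangled with retirements and organizational
change, none of which are emulated. The planted effect sizes are
constants per connection; real effects are heterogeneous.

## Known limitations

* Wald intervals with design weights can run slightly narrow (the
  model treats IPTW weights as precision weights), as quantified
  above; the recovery estimate carries a small upward tendency
  (~+0.4 on a planted 8.0) from residual threshold-crossing
  selection, well inside the 99% interval width.
* `EffectPlan.noise_scales` perturbs effects before truncation at
  zero, so very small planted effects with large noise are biased
  upward; the default is no noise.
* The exact weighting of the original linchpin score is not restated
  in the source describing it; both weighted (default) and unweighted
  forms are provided without asserting which matches the original
  implementation.
* Same-day claims are ordered by claim id — a reproducible but
  arbitrary convention; it never affects transition counts because
  same-day claims share a ZIP.
* Whether a single ZIP change within one HRR counts as a departure is
  ambiguous in the motivating description; the union rule (default)
  counts it, and `mover_rule="hrr"` does not.
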