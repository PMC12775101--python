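# oncnet

Physician patient-sharing networks and the impact of oncologist
departures, from Medicare-style claims.

When an oncologist leaves a practice, the colleagues who remain absorb
patients, build new referral relationships, or consolidate existing
ones — and rural care teams, with thinner specialist coverage, absorb
departures differently than urban ones. `oncnet` implements the full
observational pipeline for studying this from administrative claims:

* **annual patient-sharing networks** — physicians are linked in a
  calendar year by the number of unique cohort patients both billed,
  restricted to each patient's care window around a diagnostic biopsy;
* **node measures** — node strength s_i = Σ_j w_ij, local transitivity
  C_i (fraction of neighbor pairs that are themselves connected),
  Burt's constraint c_i = Σ_j (p_ij + Σ_q p_iq p_qj)², and the
  **linchpin score** L_i: the weight-fraction of an oncologist's
  other-specialty neighbors with no tie to the oncologist's specialty
  except through them — a high L_i marks a locally irreplaceable
  specialist;
* **departure detection** — an oncologist moved in a year when their
  date-ordered carrier-claim billing ZIP changed exactly once, or,
  to accommodate multi-site practices, when the hospital referral
  region (HRR) of those ZIPs changed exactly once;
* **exposure–outcome analysis** — retained oncologists' year-over-year
  changes Δy_it in strength, transitivity, constraint, linchpin score
  and patient volume are regressed on their count of connections E_it
  to departing oncologists (pairs sharing ≥ 2 patients over the
  departure year and the year before):

      Δy_it = β₀ + β₁ E_it + u_HRR(i) + v_i + ε_it

  a linear mixed model with crossed random intercepts for HRR and
  physician, weighted by inverse-probability-of-treatment (IPTW)
  weights from a propensity model of ever being connected, stratified
  by practice rurality, with a Bonferroni threshold p < 0.01 (99% CIs)
  across the five outcomes; plus a Kish-corrected weighted paired
  t-test for pre/post changes in persistent- and new-tie strength.

The claims files such a study uses are not publicly redistributable,
so the package includes a first-class **synthetic claims generator**
(`oncnet.synthetic_claims`) that emulates the study end to end —
geography crosswalks, taxonomy codes, eligibility violations, care
teams, mover billing trajectories — and plants known per-departure
effects and confounding, with ground-truth labels for every stage.
`docs/methods.md` describes the model and the generator in detail.

## Worked example

```python
import oncnet
from oncnet.config import SimulationConfig, EffectPlan

cfg = SimulationConfig(
    n_patients=8000, n_hrrs=4, zips_per_hrr=4,
    specialty_counts={"medical oncology": 152,
                      "radiation oncology": 68, "surgery": 180},
    n_other_physicians=200,
    mean_connections_per_mover=6.0,
    effects=EffectPlan(rural_strength_effect_per_connection=8.0,
                       rural_volume_effect_per_connection=1.3,
                       confounding_strength=0.5),
)
study, result = oncnet.run_study(cfg, seed=42)
print(len(result.retained), int(result.connected.sum()))
print(result.models_frame()[["stratum", "outcome", "coef",
                             "ci_low", "ci_high", "significant"]])
```

This simulates four years of claims for 400 oncologists in which every
connection to a departing colleague adds, for rural physicians, 8
points of node strength and 1.3 patients in the departure year, with
confounded exposure. The run prints 384 retained oncologists, 246 of
them ever connected to one of the 40 detected departures, and the
fitted per-connection changes:

```
stratum      outcome   coef  ci_low  ci_high  significant
  rural     strength  7.498   3.872   11.123         True
  rural       volume  1.231  -0.092    2.553        False
  urban     strength  0.984  -0.982    2.950        False
  urban       volume  0.325  -0.390    1.040        False
  ...
```

The rural 99% CIs cover the planted effects while the urban strata,
where nothing was planted, stay null — the estimator recovers what the
generator hid (at this small scale the volume effect is detectable but
not significant at the Bonferroni threshold). The IPTW step shrinks
the baseline imbalance (unweighted SMD 0.59 for node strength between
ever- and never-connected physicians) below 0.1 for every propensity
covariate, and `result.paired_frame()` shows the pre/post tie-level
strength tests — in this run retained rural oncologists gained
new-tie strength after a departure (mean change 6.19, p < 0.001)
while urban oncologists did not.

## Command line

Each pipeline stage reads and writes plain CSV directories:

```bash
oncnet simulate --config config.yaml --seed 7 --out data/
oncnet cohort   --in data/ --out out/
oncnet movers   --in data/ --rule union --out out/
oncnet analyze  --in data/ --k 2 --out out/
oncnet report   --in out/
```

`analyze` writes per-year edge lists (`network_<year>.csv`), node
metrics (`metrics_<year>.csv`), the physician-year analysis table, the
balance table, the fitted models and the paired tests; `report`
renders them.

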