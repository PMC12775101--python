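"""Canonical validation experiments.

The original claims files are not publicly available, so the package's
headline regression results are validated by construction instead:
parameter recovery of a planted rural per-connection effect, null
calibration of the 99% confidence intervals, IPTW covariate balance on
confounded data, and type-I calibration of the weighted paired t-test.
These functions define the study conditions for those experiments in
one place; the test suite and the acceptance script both run them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import largest_remainder, spawn_rng
from .config import AnalysisConfig, EffectPlan, SimulationConfig
from .errors import FitFailureError
from .inference import fit_outcome_model, fit_propensity, weighted_paired_ttest
from .pipeline import run_measurement
from .synthetic_claims import simulate_study

#: specialty mix of the emulated oncologist cohort (medical oncology,
#: radiation oncology, surgery), as published counts
COHORT_SPECIALTY_COUNTS = {"medical oncology": 7150, "radiation oncology": 3229,
                           "surgery": 8495}

#: planted per-departure effects for the recovery experiment: the rural
#: strength effect is the recovery target, the volume effect matches the
#: magnitude reported for rural practices, urban effects are left null
RECOVERY_EFFECTS = EffectPlan(
    rural_strength_effect_per_connection=8.0,
    rural_volume_effect_per_connection=1.3,
    confounding_strength=0.5,
)


def scaled_specialty_counts(n_oncologists: int) -> dict:
    names = list(COHORT_SPECIALTY_COUNTS)
    alloc = largest_remainder(
        np.array([COHORT_SPECIALTY_COUNTS[s] for s in names], float), n_oncologists
    )
    return dict(zip(names, (int(a) for a in alloc)))


def recovery_config(n_oncologists: int = 2000) -> SimulationConfig:
    """Study conditions for the parameter-recovery experiment: regional
    markets of ~200 oncologists and ~6 connections per departure, so
    planted relationships dominate the chance crossings of the
    shared-patient threshold."""
    return SimulationConfig(
        n_patients=n_oncologists * 20,
        n_hrrs=max(2, n_oncologists // 200),
        zips_per_hrr=5,
        specialty_counts=scaled_specialty_counts(n_oncologists),
        n_other_physicians=n_oncologists // 2,
        mean_connections_per_mover=6.0,
        effects=RECOVERY_EFFECTS,
    )


def null_config(n_oncologists: int = 240) -> SimulationConfig:
    """Study conditions for one null-calibration replicate: no planted
    effects, no planted confounding."""
    return SimulationConfig(
        n_patients=n_oncologists * 20,
        n_hrrs=max(2, n_oncologists // 24),
        zips_per_hrr=3,
        specialty_counts=scaled_specialty_counts(n_oncologists),
        n_other_physicians=n_oncologists // 2,
        mover_fraction=0.12,
        mean_connections_per_mover=5.0,
        effects=EffectPlan(),
    )


@dataclass
class RecoveryResult:
    rural_strength: object
    rural_volume: object
    urban_strength: object
    balance: object
    n_retained: int

    def rural_ci_covers(self, target: float = 8.0) -> bool:
        m = self.rural_strength
        return m.ci_low <= target <= m.ci_high


def run_recovery(seed: int, n_oncologists: int = 2000) -> RecoveryResult:
    """Simulate a confounded study with the planted rural effects and fit
    the IPTW-weighted outcome models the pipeline reports."""
    cfg = recovery_config(n_oncologists)
    study = simulate_study(cfg, seed)
    res = run_measurement(
        study.claims, study.patients, study.physicians, study.crosswalk,
        cfg.years, fit_models=False,
    )
    prop = fit_propensity(
        res.baseline, res.connected,
        truncation=AnalysisConfig().weight_truncation,
    )
    kw = dict(weights=prop.weights)
    from .inference import balance_table

    return RecoveryResult(
        rural_strength=fit_outcome_model(res.analysis, "strength", stratum="rural", **kw),
        rural_volume=fit_outcome_model(res.analysis, "volume", stratum="rural", **kw),
        urban_strength=fit_outcome_model(res.analysis, "strength", stratum="urban", **kw),
        balance=balance_table(res.baseline, res.connected, weights=prop.weights),
        n_retained=len(res.retained),
    )


def run_null_calibration(seed: int, n_replicates: int = 200,
                         n_oncologists: int = 240) -> dict:
    """Replicate the pipeline under a zero-effect, zero-confounding plan
    and record how often the 99% CIs cover zero."""
    cfg = null_config(n_oncologists)
    covers = {"rural": 0, "urban": 0}
    done = 0
    for r in range(n_replicates):
        rep_seed = int(spawn_rng(seed, 7, r).integers(0, 2**31 - 1))
        study = simulate_study(cfg, rep_seed)
        res = run_measurement(
            study.claims, study.patients, study.physicians, study.crosswalk,
            cfg.years, fit_models=False,
        )
        try:
            w = fit_propensity(
                res.baseline, res.connected,
                truncation=AnalysisConfig().weight_truncation,
            ).weights
        except FitFailureError:
            w = None
        for stratum in covers:
            m = fit_outcome_model(
                res.analysis, "strength", weights=w, stratum=stratum
            )
            covers[stratum] += m.ci_low <= 0.0 <= m.ci_high
        done += 1
    return {
        "n_replicates": done,
        "rural_coverage": covers["rural"] / done,
        "urban_coverage": covers["urban"] / done,
    }


def run_ttest_type1(seed: int, n_replicates: int = 5000, n_pairs: int = 50,
                    alpha: float = 0.05) -> dict:
    """Type-I error of the Kish-corrected weighted paired t-test under a
    null of no pre/post change, with IPTW-like right-skewed weights."""
    rng = spawn_rng(seed, 8)
    rejections = 0
    for _ in range(n_replicates):
        pre = rng.normal(100, 25, size=n_pairs)
        post = pre + rng.normal(0, 10, size=n_pairs)
        weights = np.exp(rng.normal(0, 0.6, size=n_pairs))
        res = weighted_paired_ttest(pre, post, weights)
        rejections += res.p_value < alpha
    rate = rejections / n_replicates
    se = np.sqrt(alpha * (1 - alpha) / n_replicates)
    return {"n_replicates": n_replicates, "rejection_rate": rate,
            "binomial_se": se}


def equal_weight_ttest_check(seed: int, n_pairs: int = 30) -> dict:
    """Weighted paired t-test with equal weights vs scipy's classical
    paired t-test: the two must agree exactly."""
    rng = spawn_rng(seed, 9)
    pre = rng.normal(50, 10, size=n_pairs)
    post = pre + rng.normal(1, 5, size=n_pairs)
    ours = weighted_paired_ttest(pre, post, np.ones(n_pairs))
    ref = stats.ttest_rel(post, pre)
    return {
        "t_ours": ours.t_stat,
        "t_scipy": float(ref.statistic),
        "p_ours": ours.p_value,
        "p_scipy": float(ref.pvalue),
        "max_abs_diff": max(
            abs(ours.t_stat - float(ref.statistic)),
            abs(ours.p_value - float(ref.pvalue)),
        ),
    }
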