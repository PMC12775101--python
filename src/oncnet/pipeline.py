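"""End-to-end orchestration: claims -> cohorts -> networks -> measures ->
exposures -> weighted models.

`run_measurement` consumes a claim bundle (synthetic or read from disk)
and produces every analysis artifact; `run_study` additionally runs the
generator first. Both are deterministic given (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort_builder, exposure_outcome, inference, mover_detection
from .config import AnalysisConfig, SimulationConfig
from .errors import FitFailureError
from .network_builder import build_annual_network, classify_ties
from .network_measures import compute_node_metrics
from .synthetic_claims import SyntheticStudy, simulate_study

log = logging.getLogger(__name__)


@dataclass
class StudyAnalysis:
    years: tuple
    eligibility: pd.DataFrame
    patient_cohort: pd.DataFrame
    profiles: pd.DataFrame
    movers: pd.DataFrame
    retained: set
    networks: dict
    tie_classes: dict
    metrics_by_year: dict
    analysis: pd.DataFrame
    baseline: pd.DataFrame
    connected: pd.Series
    propensity: object
    balance: pd.DataFrame
    models: list = field(default_factory=list)
    paired: pd.DataFrame = None
    paired_tests: list = field(default_factory=list)

    def models_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stratum": m.stratum,
                    "outcome": m.outcome,
                    "exposure": m.exposure,
                    "k": m.k,
                    "coef": m.coef,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "p_value": m.p_value,
                    "significant": m.significant,
                    "n_obs": m.n_obs,
                    "n_physicians": m.n_physicians,
                }
                for m in self.models
            ]
        )

    def paired_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stratum": t.stratum,
                    "tie_subset": t.tie_subset,
                    "mean_change": t.mean_change,
                    "sd_change": t.sd_change,
                    "n": t.n,
                    "n_eff": t.n_eff,
                    "t_stat": t.t_stat,
                    "p_value": t.p_value,
                }
                for t in self.paired_tests
            ]
        )


def _metrics_with_volume(
    net, tie_cls, specialty_map, volume_lookup, year, everyone, cfg
):
    m = compute_node_metrics(
        net,
        specialty_map,
        tie_classes=tie_cls,
        linchpin_weighted=cfg.linchpin_weighted,
        linchpin_pct=cfg.linchpin_top_pct,
    )
    m["volume"] = m["physician_id"].map(
        lambda p: volume_lookup.get((p, year), 0)
    )
    missing = sorted(set(everyone) - set(m["physician_id"]))
    if missing:
        pad = pd.DataFrame(
            {
                "physician_id": missing,
                "year": year,
                "strength": 0.0,
                "transitivity": np.nan,
                "constraint": np.nan,
                "linchpin": np.nan,
                "strength_persistent": 0.0 if tie_cls is not None else np.nan,
                "strength_new": 0.0 if tie_cls is not None else np.nan,
                "linchpin_flag": False,
                "volume": 0,
            }
        )
        m = pd.concat([m, pad], ignore_index=True)
    return m


def run_measurement(
    claims: pd.DataFrame,
    patients: pd.DataFrame,
    physicians: pd.DataFrame,
    crosswalk: pd.DataFrame,
    years,
    cfg: AnalysisConfig | None = None,
    exposures=("exposure_any",),
    fit_models: bool = True,
) -> StudyAnalysis:
    """Run the measurement-and-inference half of the pipeline."""
    cfg = (cfg or AnalysisConfig()).validate()
    years = tuple(years)

    eligibility = cohort_builder.select_patient_cohort(claims, patients, years)
    cohort = cohort_builder.eligible_cohort(patients, eligibility)
    profiles = cohort_builder.identify_oncologists(claims, physicians, cohort)
    onc_ids = profiles.loc[profiles["is_oncologist"], "physician_id"]
    movers = mover_detection.classify_movers(
        claims,
        physicians[physicians["physician_id"].isin(set(onc_ids))],
        crosswalk,
        years,
        rule=cfg.mover_rule,
    )
    retained = cohort_builder.select_retained_cohort(profiles, movers, years)
    profiles = cohort_builder.compute_covariates(
        profiles, claims, cohort, crosswalk, movers
    )
    specialty_map = dict(zip(profiles["physician_id"], profiles["specialty"]))

    networks = {y: build_annual_network(claims, cohort, y) for y in years}
    tie_classes = {
        y: classify_ties(networks[y], networks[y - 1]) for y in years[1:]
    }

    win = cohort_builder.window_encounters(claims, cohort)
    win = win.assign(year=win["service_date"].dt.year)
    volume_lookup = (
        win.groupby(["physician_id", "year"])["patient_id"].nunique().to_dict()
    )
    metrics_by_year = {
        y: _metrics_with_volume(
            networks[y],
            tie_classes.get(y),
            specialty_map,
            volume_lookup,
            y,
            retained,
            cfg,
        )
        for y in years
    }

    movers_annot = exposure_outcome.annotate_movers(
        movers, metrics_by_year, specialty_map
    )
    analysis = exposure_outcome.build_analysis_table(
        metrics_by_year,
        movers_annot,
        networks,
        profiles,
        retained,
        years,
        k=cfg.connection_threshold,
        pooled=cfg.pooled_connection_window,
    )

    prof_idx = profiles.set_index("physician_id")
    first = analysis.drop_duplicates("physician_id").set_index("physician_id")
    baseline = pd.DataFrame(
        {
            "male": (first["sex"] == "M").astype(float),
            "specialty": first["specialty"],
            "rural": first["rural"].astype(float),
            "volume_category": first["volume_category"],
            "baseline_strength": first["baseline_strength"],
            "baseline_transitivity": first["baseline_transitivity"],
            "baseline_constraint": first["baseline_constraint"],
            "baseline_linchpin": first["baseline_linchpin"],
            "panel_pct_hispanic": prof_idx["panel_pct_hispanic"].reindex(first.index),
            "panel_pct_nh_black": prof_idx["panel_pct_nh_black"].reindex(first.index),
            "panel_pct_nh_white": prof_idx["panel_pct_nh_white"].reindex(first.index),
        }
    )
    connected = exposure_outcome.ever_connected(analysis)

    propensity = None
    weights = None
    balance = inference.balance_table(baseline, connected)
    try:
        propensity = inference.fit_propensity(
            baseline,
            connected,
            smd_threshold=cfg.smd_threshold,
            truncation=cfg.weight_truncation,
        )
        weights = propensity.weights
        balance = inference.balance_table(baseline, connected, weights=weights)
    except FitFailureError as exc:
        log.warning("propensity step skipped: %s", exc)

    out = StudyAnalysis(
        years=years,
        eligibility=eligibility,
        patient_cohort=cohort,
        profiles=profiles,
        movers=movers_annot,
        retained=retained,
        networks=networks,
        tie_classes=tie_classes,
        metrics_by_year=metrics_by_year,
        analysis=analysis,
        baseline=baseline,
        connected=connected,
        propensity=propensity,
        balance=balance,
    )

    if fit_models and len(analysis):
        alpha = inference.bonferroni_threshold(cfg.alpha_family, cfg.n_outcome_tests)
        for stratum in ("rural", "urban"):
            for outcome in exposure_outcome.OUTCOMES:
                for exposure in exposures:
                    try:
                        out.models.append(
                            inference.fit_outcome_model(
                                analysis,
                                outcome,
                                exposure=exposure,
                                weights=weights,
                                stratum=stratum,
                                k=cfg.connection_threshold,
                                alpha=alpha,
                            )
                        )
                    except FitFailureError as exc:
                        log.warning(
                            "model %s/%s/%s skipped: %s", stratum, outcome, exposure, exc
                        )
        out.paired = exposure_outcome.build_paired_strength_table(
            metrics_by_year, analysis, profiles, weights=weights
        )
        if out.paired is not None and len(out.paired):
            for stratum in ("rural", "urban"):
                sub = out.paired[out.paired["rural"] == (stratum == "rural")]
                if len(sub) < 3:
                    continue
                for subset in ("persistent", "new"):
                    try:
                        out.paired_tests.append(
                            inference.weighted_paired_ttest(
                                sub[f"pre_{subset}"],
                                sub[f"post_{subset}"],
                                sub["weight"],
                                stratum=stratum,
                                tie_subset=subset,
                            )
                        )
                    except Exception as exc:
                        log.warning("paired test %s/%s skipped: %s", stratum, subset, exc)
    return out


def run_study(
    sim_config: SimulationConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    seed: int = 0,
    exposures=("exposure_any",),
    fit_models: bool = True,
) -> tuple[SyntheticStudy, StudyAnalysis]:
    """Generate a synthetic study and run the full measurement pipeline."""
    sim_config = sim_config or SimulationConfig()
    study = simulate_study(sim_config, seed)
    result = run_measurement(
        study.claims,
        study.patients,
        study.physicians,
        study.crosswalk,
        sim_config.years,
        cfg=analysis_config,
        exposures=exposures,
        fit_models=fit_models,
    )
    return study, result
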