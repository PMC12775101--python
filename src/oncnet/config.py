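"""Study configuration: the synthetic generator's knobs and the analysis
settings.

The defaults describe the study conditions emulated throughout the test
suite: four calendar years of claims, an oncologist workforce mixed
across medical oncology / radiation oncology / surgery in the observed
18,874-cohort proportions, a ZIP->HRR->RUCA geography with a configurable
rural share, and planted mover trajectories and per-departure effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .errors import InvalidConfigError

SPECIALTIES = ("medical oncology", "radiation oncology", "surgery")
TRAJECTORY_KINDS = (
    "non_mover",
    "outreach_multisite",
    "single_site_move",
    "within_hrr_move",
    "cross_hrr_multisite_move",
    "multi_year_move",
)
RACE_CATEGORIES = ("Hispanic", "NH-Black", "NH-White", "Other")
CANCER_TYPES = ("breast", "lung", "colorectal")

#: NPPES-style taxonomy codes used by the generator and the cohort builder.
TAXONOMY = {
    "medical oncology": ("207RX0202X", "207RH0003X"),
    "radiation oncology": ("2085R0001X",),
    "surgery": ("208600000X", "2086X0206X"),
    "other": ("207R00000X", "207Q00000X"),
}

#: RUCA codes treated as rural when dichotomizing (configurable stand-in
#: for the population/commuting based categorization).
DEFAULT_RURAL_RUCA = frozenset(range(4, 11))


@dataclass
class EffectPlan:
    """Per-departure effects planted on retained physicians connected to a
    mover, applied additively in the departure year only.

    Units: `rural_strength_effect_per_connection` is extra shared-patient
    weight (node-strength points) per mover connection for rural retained
    physicians; `rural_volume_effect_per_connection` is extra unique cohort
    patients; `urban_transitivity_effect` is the expected number of open
    neighbor pairs closed per connection for urban retained physicians.
    `confounding_strength` is the log-odds slope tying a physician's latent
    panel-size propensity to being selected as a mover connection.
    `noise_scales` maps {"strength", "volume", "transitivity"} to the SD of
    a zero-mean perturbation of the per-connection effect before integer
    rounding.
    """

    rural_strength_effect_per_connection: float = 0.0
    rural_volume_effect_per_connection: float = 0.0
    urban_transitivity_effect: float = 0.0
    confounding_strength: float = 0.0
    noise_scales: dict = field(default_factory=dict)

    def is_null(self) -> bool:
        return (
            self.rural_strength_effect_per_connection == 0
            and self.rural_volume_effect_per_connection == 0
            and self.urban_transitivity_effect == 0
        )


@dataclass
class SimulationConfig:
    years: tuple = (2016, 2017, 2018, 2019)

    # geography
    n_hrrs: int = 10
    zips_per_hrr: int = 5
    rural_fraction: float = 0.3
    rural_ruca_codes: frozenset = DEFAULT_RURAL_RUCA

    # physicians; default specialty mix is the cohort mix 7150:3229:8495
    # apportioned to 200 oncologists by largest remainder.
    specialty_counts: dict = field(
        default_factory=lambda: {
            "medical oncology": 76,
            "radiation oncology": 34,
            "surgery": 90,
        }
    )
    n_other_physicians: int = 100
    male_fraction: float = 0.70

    # mover planting
    mover_fraction: float = 0.10
    mover_kind_mix: dict = field(
        default_factory=lambda: {
            "single_site_move": 0.5,
            "within_hrr_move": 0.2,
            "cross_hrr_multisite_move": 0.3,
        }
    )
    outreach_fraction: float = 0.10  # of non-movers
    multi_year_mover_fraction: float = 0.02
    attrition_fraction: float = 0.02  # stop billing after the second year
    mean_connections_per_mover: float = 4.0

    # patients
    n_patients: int = 4000
    age_range: tuple = (66, 99)
    cancer_type_mix: dict = field(
        default_factory=lambda: {"breast": 0.563, "lung": 0.25, "colorectal": 0.187}
    )
    radiation_prob_by_cancer: dict = field(
        default_factory=lambda: {"breast": 0.8, "lung": 0.6, "colorectal": 0.3}
    )
    race_mix: dict = field(
        default_factory=lambda: {
            "NH-White": 0.87,
            "NH-Black": 0.07,
            "Hispanic": 0.02,
            "Other": 0.04,
        }
    )
    ineligible_fractions: dict = field(
        default_factory=lambda: {
            "no_confirmatory_dx": 0.03,
            "prevalent": 0.03,
            "age": 0.02,
            "enrollment": 0.02,
        }
    )

    # care-team process; the attractiveness spread is calibrated so the
    # baseline imbalance between ever- and never-connected physicians
    # matches the observed cohort (unweighted SMD ~0.5-0.8 for volume
    # and strength)
    cross_hrr_leakage: float = 0.05
    attractiveness_sigma: float = 0.35
    # physicians practice in stable referral communities within their
    # HRR; a patient's remaining team members come from the medical
    # oncologist's community with this probability. Concentrated sharing
    # makes pairwise patient counts high and stable, as in real referral
    # networks, rather than spreading single shared patients thinly.
    community_size: int = 8
    community_prob: float = 0.85

    effects: EffectPlan = field(default_factory=EffectPlan)

    def validate(self) -> "SimulationConfig":
        if self.n_hrrs < 1 or self.zips_per_hrr < 2:
            raise InvalidConfigError("need n_hrrs >= 1 and zips_per_hrr >= 2")
        if not 0 <= self.rural_fraction <= 1:
            raise InvalidConfigError("rural_fraction must be in [0, 1]")
        if not self.specialty_counts or sum(self.specialty_counts.values()) <= 0:
            raise InvalidConfigError("specialty_counts must be non-empty and positive")
        for s in self.specialty_counts:
            if s not in SPECIALTIES:
                raise InvalidConfigError(f"unknown specialty {s!r}")
        if not 0 <= self.mover_fraction <= 1:
            raise InvalidConfigError("mover_fraction must be in [0, 1]")
        if len(self.years) < 2 or list(self.years) != list(
            range(self.years[0], self.years[0] + len(self.years))
        ):
            raise InvalidConfigError("years must be >= 2 consecutive calendar years")
        if sum(self.ineligible_fractions.values()) >= 1:
            raise InvalidConfigError("ineligible fractions must sum below 1")
        eff = self.effects
        if (
            eff.rural_strength_effect_per_connection
            or eff.rural_volume_effect_per_connection
        ) and self.rural_fraction == 0:
            raise InvalidConfigError("rural effects planted but rural_fraction is 0")
        if eff.urban_transitivity_effect and self.rural_fraction == 1:
            raise InvalidConfigError("urban effect planted but rural_fraction is 1")
        return self


@dataclass
class AnalysisConfig:
    """Settings for the measurement half of the pipeline."""

    mover_rule: str = "union"  # {"zip", "hrr", "union"}
    connection_threshold: int = 2  # >= k shared patients over the 2-year window
    pooled_connection_window: bool = True  # pooled vs per-year threshold
    linchpin_weighted: bool = True
    linchpin_top_pct: float = 0.15
    smd_threshold: float = 0.1
    alpha_family: float = 0.05
    n_outcome_tests: int = 5
    # optional symmetric truncation of IPTW weights at percentiles,
    # e.g. (1, 99): capping the weight tails tightens Wald-interval
    # coverage slightly but trades away some covariate balance
    weight_truncation: Optional[tuple] = None

    def validate(self) -> "AnalysisConfig":
        if self.mover_rule not in {"zip", "hrr", "union"}:
            raise InvalidConfigError("mover_rule must be zip, hrr or union")
        if self.connection_threshold < 1:
            raise InvalidConfigError("connection_threshold must be >= 1")
        if not 0 < self.linchpin_top_pct < 1:
            raise InvalidConfigError("linchpin_top_pct must be in (0, 1)")
        return self


def _from_mapping(cls, data: dict):
    known = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> tuple[SimulationConfig, AnalysisConfig]:
    """Read a YAML config file with optional `simulation:` and `analysis:`
    sections; absent keys fall back to the defaults above."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = dict(raw.get("simulation", {}))
    if "effects" in sim_raw:
        sim_raw["effects"] = _from_mapping(EffectPlan, sim_raw["effects"])
    if "years" in sim_raw:
        sim_raw["years"] = tuple(sim_raw["years"])
    if "age_range" in sim_raw:
        sim_raw["age_range"] = tuple(sim_raw["age_range"])
    if "rural_ruca_codes" in sim_raw:
        sim_raw["rural_ruca_codes"] = frozenset(sim_raw["rural_ruca_codes"])
    sim = _from_mapping(SimulationConfig, sim_raw).validate()
    ana = _from_mapping(AnalysisConfig, dict(raw.get("analysis", {}))).validate()
    return sim, ana


def dump_config(sim: SimulationConfig, ana: AnalysisConfig, path) -> None:
    payload = {"simulation": asdict(sim), "analysis": asdict(ana)}
    payload["simulation"]["rural_ruca_codes"] = sorted(sim.rural_ruca_codes)
    payload["simulation"]["years"] = list(sim.years)
    payload["simulation"]["age_range"] = list(sim.age_range)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
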