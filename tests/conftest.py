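import pytest

from oncnet.config import EffectPlan, SimulationConfig
from oncnet.pipeline import run_measurement
from oncnet.synthetic_claims import simulate_study


def tiny_config(**over):
    base = dict(
        n_patients=400,
        n_hrrs=4,
        zips_per_hrr=3,
        specialty_counts={
            "medical oncology": 10,
            "radiation oncology": 5,
            "surgery": 12,
        },
        n_other_physicians=10,
    )
    base.update(over)
    return SimulationConfig(**base)


def small_config(**over):
    base = dict(
        n_patients=1600,
        n_hrrs=6,
        zips_per_hrr=3,
        specialty_counts={
            "medical oncology": 30,
            "radiation oncology": 14,
            "surgery": 36,
        },
        n_other_physicians=40,
        effects=EffectPlan(
            rural_strength_effect_per_connection=8.0,
            rural_volume_effect_per_connection=1.3,
            confounding_strength=0.5,
        ),
    )
    base.update(over)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config(), seed=20)


@pytest.fixture(scope="session")
def small_result(small_study):
    cfg = small_study.config
    return run_measurement(
        small_study.claims,
        small_study.patients,
        small_study.physicians,
        small_study.crosswalk,
        cfg.years,
        fit_models=False,
    )
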