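import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ehrsubtype.synth_cohort import (
    SubtypeProfile,
    SynthConfig,
    simulate,
    strong_signal_config,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="patient .* has no pre-index events")


@pytest.fixture(scope="session")
def preset_cohort():
    """A moderate strong-signal cohort shared across unit tests."""
    cfg = strong_signal_config(n_patients=800, seed=42)
    records, truth = simulate(cfg)
    return cfg, records, truth


def light_outcome_config(
    n_patients: int,
    hazards: tuple[float, ...],
    seed: int = 0,
    pre_index_prob: float = 0.0,
    comorbidity_hazard: float = 0.0,
) -> SynthConfig:
    """A sparse-history config for outcome-focused tests: one signature code
    per subtype, few visits, hazards given per subtype."""
    subtypes = tuple(
        SubtypeProfile(
            subtype_id=s,
            signature_codes=(f"C{s:03d}",),
            signature_prevalence=0.9,
            background_prevalence=0.02,
            visit_rate=0.5,
            death_hazard=h,
            hospitalisation_hazard=0.0,
            comorbidity_hazards=(
                {"C009": comorbidity_hazard} if comorbidity_hazard else {}
            ),
            pre_index_comorbidity_prob=(
                {"C009": pre_index_prob} if pre_index_prob else {}
            ),
        )
        for s, h in enumerate(hazards)
    )
    w = 1.0 / len(hazards)
    return SynthConfig(
        n_patients=n_patients,
        n_practices=4,
        mixture_weights=tuple([w] * len(hazards)),
        subtypes=subtypes,
        vocab_size=10,
        years_history=2.0,
        horizon_days=365,
        seed=seed,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
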