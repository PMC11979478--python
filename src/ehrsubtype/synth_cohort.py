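"""Synthetic longitudinal EHR cohorts with planted latent subtypes.

The generator emulates the structure the downstream pipeline needs: each
patient belongs to one of a few latent subtypes; visits arrive as a Poisson
process over the years before the (first heart-failure) index date; at every
visit the subtype's signature codes fire with high probability and the shared
background codes with low probability; post-index outcomes (death, HF
hospitalisation, comorbidity onsets) are exponential with subtype-specific
hazards, administratively censored at the observation horizon.

It is deliberately simple — constant hazards and a homogeneous visit process —
so that every downstream estimate has a closed-form truth to be tested against.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field

import numpy as np

from .ehr_data import CodedEvent, PatientRecord

HF_HOSPITALISATION_CODE = "HF_HOSP"

_CODE_TYPE_CYCLE = ("diagnosis", "procedure", "medication")


@dataclass
class SubtypeProfile:
    """Generative parameters of one latent subtype.

    Rates are per person-year; probabilities are per visit (signature /
    background firing) or per patient (pre-index comorbidity planting).
    """

    subtype_id: int
    signature_codes: tuple[str, ...]
    signature_prevalence: float = 0.9
    background_prevalence: float = 0.05
    age_mean: float = 75.0
    age_sd: float = 8.0
    visit_rate: float = 1.2  # expected visits per year of history
    death_hazard: float = 0.2
    hospitalisation_hazard: float = 0.3
    comorbidity_hazards: dict[str, float] = field(default_factory=dict)
    pre_index_comorbidity_prob: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for p in (self.signature_prevalence, self.background_prevalence):
            if not 0 <= p <= 1:
                raise ValueError("prevalence probabilities must lie in [0, 1]")
        for h in (
            self.death_hazard,
            self.hospitalisation_hazard,
            *self.comorbidity_hazards.values(),
        ):
            if h < 0:
                raise ValueError("hazards must be non-negative")
        for p in self.pre_index_comorbidity_prob.values():
            if not 0 <= p <= 1:
                raise ValueError("pre-index planting probabilities must lie in [0, 1]")


@dataclass
class SynthConfig:
    n_patients: int
    n_practices: int
    mixture_weights: tuple[float, ...]
    subtypes: tuple[SubtypeProfile, ...]
    vocab_size: int
    years_history: float = 5.0
    horizon_days: int = 365
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.n_practices < 2:
            raise ValueError("n_practices must be at least 2")
        if len(self.mixture_weights) != len(self.subtypes):
            raise ValueError("one mixture weight per subtype required")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        n_signature = sum(len(s.signature_codes) for s in self.subtypes)
        if self.vocab_size < n_signature or self.vocab_size <= 0:
            raise ValueError(
                "vocab_size must cover all signature codes and be positive"
            )
        for s in self.subtypes:
            s.validate()

    @property
    def codes(self) -> list[str]:
        return [f"C{i:03d}" for i in range(self.vocab_size)]

    def background_codes(self) -> list[str]:
        sig = {c for s in self.subtypes for c in s.signature_codes}
        return [c for c in self.codes if c not in sig]


@dataclass
class GroundTruth:
    """Latent subtype label for every generated patient."""

    labels: dict[str, int]

    def __getitem__(self, patient_id: str) -> int:
        return self.labels[patient_id]

    def as_array(self, patient_ids: list[str]) -> np.ndarray:
        return np.asarray([self.labels[p] for p in patient_ids])


def strong_signal_config(
    n_patients: int = 2000,
    n_subtypes: int = 3,
    seed: int = 0,
    signature_prevalence: float = 0.9,
    background_prevalence: float = 0.05,
    vocab_size: int = 60,
    n_signature_codes: int = 8,
    n_practices: int = 10,
) -> SynthConfig:
    """The canonical strong-signal preset: equally weighted subtypes, each with
    its own block of signature codes firing at 0.9 per visit against a 0.05
    background, well-separated outcome hazards, and one planted pre-index
    comorbidity per subtype to exercise the prevalent-case exclusion rule."""
    codes = [f"C{i:03d}" for i in range(vocab_size)]
    death = [0.45, 0.25, 0.10]
    hosp = [0.55, 0.30, 0.12]
    conditions = ["C050", "C051", "C052"]
    subtypes = []
    for s in range(n_subtypes):
        sig = tuple(codes[s * n_signature_codes : (s + 1) * n_signature_codes])
        subtypes.append(
            SubtypeProfile(
                subtype_id=s,
                signature_codes=sig,
                signature_prevalence=signature_prevalence,
                background_prevalence=background_prevalence,
                age_mean=70.0 + 4.0 * s,
                age_sd=8.0,
                visit_rate=1.2,
                death_hazard=death[s % len(death)],
                hospitalisation_hazard=hosp[s % len(hosp)],
                comorbidity_hazards={conditions[s % len(conditions)]: 0.4},
                pre_index_comorbidity_prob={conditions[s % len(conditions)]: 0.3},
            )
        )
    weights = tuple([1.0 / n_subtypes] * n_subtypes)
    return SynthConfig(
        n_patients=n_patients,
        n_practices=n_practices,
        mixture_weights=weights,
        subtypes=tuple(subtypes),
        vocab_size=vocab_size,
        years_history=5.0,
        horizon_days=365,
        seed=seed,
    )


def _code_type(code: str) -> str:
    # deterministic across processes (str hash randomisation would not be)
    return _CODE_TYPE_CYCLE[zlib.crc32(code.encode()) % 3]


def generate_cohort(config: SynthConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Draw a cohort (pre-index histories only) from the configured mixture.

    Fully reproducible for a given ``config.seed``.  Outcomes are added by
    :func:`generate_outcomes`; :func:`simulate` chains the two.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    background = config.background_codes()
    history_days = int(round(config.years_history * 365.25))
    records: list[PatientRecord] = []
    labels: dict[str, int] = {}

    subtype_draw = rng.choice(
        len(config.subtypes), size=config.n_patients, p=config.mixture_weights
    )
    practice_draw = rng.integers(0, config.n_practices, size=config.n_patients)

    for i in range(config.n_patients):
        profile = config.subtypes[subtype_draw[i]]
        pid = f"P{i:06d}"
        labels[pid] = profile.subtype_id

        index_date = dt.date(2010, 1, 1) + dt.timedelta(
            days=int(rng.integers(0, 8 * 365))
        )
        age = int(np.clip(rng.normal(profile.age_mean, profile.age_sd), 36, 100))
        registration_start = index_date - dt.timedelta(days=history_days + 90)

        n_visits = rng.poisson(profile.visit_rate * config.years_history)
        n_visits = min(n_visits, history_days - 1)
        visit_offsets = list(
            rng.choice(np.arange(1, history_days), size=n_visits, replace=False)
        )
        # planted pre-index comorbidities (prevalent cases for the exclusion
        # rule) are recorded at clinical encounters: at an existing visit when
        # the patient has any, otherwise at one newly created encounter that
        # also runs the ordinary per-visit recording process
        planted: dict[int, list[str]] = {}
        for code, prob in profile.pre_index_comorbidity_prob.items():
            if rng.random() < prob:
                if visit_offsets:
                    off = int(visit_offsets[rng.integers(len(visit_offsets))])
                else:
                    off = int(rng.integers(1, history_days))
                    visit_offsets.append(off)
                planted.setdefault(off, []).append(code)
        visit_offsets.sort()

        events: list[CodedEvent] = []
        for off in visit_offsets:
            date = index_date - dt.timedelta(days=int(off))
            for code in profile.signature_codes:
                if rng.random() < profile.signature_prevalence:
                    events.append(
                        CodedEvent(date, code, _code_type(code), "primary_care")
                    )
            fired = rng.random(len(background)) < profile.background_prevalence
            for code, f in zip(background, fired):
                if f:
                    events.append(
                        CodedEvent(date, code, _code_type(code), "primary_care")
                    )
            for code in planted.get(int(off), []):
                events.append(CodedEvent(date, code, "diagnosis", "primary_care"))

        records.append(
            PatientRecord(
                patient_id=pid,
                sex="female" if rng.random() < 0.5 else "male",
                birth_year=index_date.year - age,
                practice_id=f"G{int(practice_draw[i]):03d}",
                registration_start=registration_start,
                index_date=index_date,
                death_date=None,
                events=events,
            )
        )
    return records, GroundTruth(labels)


def _exp_days(rng: np.random.Generator, hazard_per_year: float) -> float:
    """One exponential event time in days for a per-person-year hazard."""
    if hazard_per_year <= 0:
        return np.inf
    return rng.exponential(365.25 / hazard_per_year)


def generate_outcomes(
    records: list[PatientRecord],
    truth: GroundTruth,
    config: SynthConfig,
    seed: int | None = None,
) -> list[PatientRecord]:
    """Plant post-index outcomes in place and return the records.

    Death, HF hospitalisation and each configured comorbidity get independent
    exponential times at the patient's subtype hazard.  Hospitalisations and
    comorbidity onsets are recorded only if they fall before death and within
    the observation horizon; death beyond the horizon leaves the patient alive
    (administratively censored).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    profiles = {s.subtype_id: s for s in config.subtypes}
    for rec in records:
        profile = profiles[truth[rec.patient_id]]
        t_death = _exp_days(rng, profile.death_hazard)
        if t_death <= config.horizon_days:
            rec.death_date = rec.index_date + dt.timedelta(days=int(np.ceil(t_death)))
        else:
            rec.death_date = None
        death_cut = t_death

        t_hosp = _exp_days(rng, profile.hospitalisation_hazard)
        if t_hosp <= min(death_cut, config.horizon_days):
            rec.events.append(
                CodedEvent(
                    rec.index_date + dt.timedelta(days=int(np.ceil(t_hosp))),
                    HF_HOSPITALISATION_CODE,
                    "procedure",
                    "secondary_care",
                )
            )
        for code, hazard in profile.comorbidity_hazards.items():
            t = _exp_days(rng, hazard)
            if t <= min(death_cut, config.horizon_days):
                rec.events.append(
                    CodedEvent(
                        rec.index_date + dt.timedelta(days=int(np.ceil(t))),
                        code,
                        "diagnosis",
                        "primary_care",
                    )
                )
        rec.events.sort(key=lambda e: e.date)
    return records


def simulate(config: SynthConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a full cohort: pre-index histories plus post-index outcomes."""
    records, truth = generate_cohort(config)
    generate_outcomes(records, truth, config)
    return records, truth


def write_truth(truth: GroundTruth, path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        sorted(truth.labels.items()), columns=["patient_id", "subtype_id"]
    ).to_csv(path, index=False)
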