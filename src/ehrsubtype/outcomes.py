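"""Prognostic and clinical characterisation of patient clusters.

Given cluster labels for a (validation) cohort, this module produces the
evaluation battery: per-cluster one-year Kaplan-Meier cumulative incidence for
all-cause mortality and HF hospitalisation (with exponential-Greenwood bands
and the between-cluster incidence range at the horizon as the separation
summary), pre-index prevalence matrices with the 30%-spread rule for picking
discriminative characteristics, and post-index comorbidity incidence that
excludes prevalent cases (patients already carrying the condition before the
index date).

Outcome extraction conventions: death is a single-event analysis censored at
the horizon; hospitalisation is the first post-index HF-hospitalisation event,
censored at death or the horizon, whichever comes first; condition onset is
handled like hospitalisation for the named condition code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ehr_data import PatientRecord
from .survival import SurvivalCurve, km_cumulative_incidence
from .synth_cohort import HF_HOSPITALISATION_CODE

OUTCOMES = ("death", "hf_hospitalisation", "condition_onset")


def extract_time_to_event(
    records: list[PatientRecord],
    outcome: str,
    horizon: float = 365.0,
    condition: str | None = None,
    hospitalisation_code: str = HF_HOSPITALISATION_CODE,
) -> tuple[np.ndarray, np.ndarray]:
    """Follow-up days from index and event indicator per patient."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    if outcome == "condition_onset" and condition is None:
        raise ValueError("condition_onset requires a condition code")
    code = hospitalisation_code if outcome == "hf_hospitalisation" else condition
    times, flags = [], []
    for rec in records:
        death_t = (
            (rec.death_date - rec.index_date).days
            if rec.death_date is not None
            else np.inf
        )
        if outcome == "death":
            if death_t <= horizon:
                times.append(death_t)
                flags.append(True)
            else:
                times.append(horizon)
                flags.append(False)
            continue
        onset = next(
            (
                (e.date - rec.index_date).days
                for e in rec.post_index_events()
                if e.code == code
            ),
            np.inf,
        )
        cut = min(death_t, horizon)  # death before onset censors the analysis
        if onset <= cut:
            times.append(onset)
            flags.append(True)
        else:
            times.append(cut if np.isfinite(cut) else horizon)
            flags.append(False)
    return np.asarray(times, dtype=np.float64), np.asarray(flags, dtype=bool)


def per_cluster_curves(
    records: list[PatientRecord],
    labels: dict[str, int],
    outcome: str,
    horizon: float = 365.0,
    alpha: float = 0.05,
    condition: str | None = None,
) -> tuple[dict[int, SurvivalCurve], float]:
    """One KM incidence curve per cluster plus the between-cluster range of
    cumulative incidence at the horizon (the separation summary)."""
    curves: dict[int, SurvivalCurve] = {}
    clusters = sorted(set(labels.values()))
    for c in clusters:
        members = [r for r in records if labels.get(r.patient_id) == c]
        if not members:
            warnings.warn(f"cluster {c} is empty; skipped", stacklevel=2)
            continue
        t, e = extract_time_to_event(
            members, outcome, horizon=horizon, condition=condition
        )
        curves[c] = km_cumulative_incidence(t, e, horizon=horizon, alpha=alpha)
    incidences = [cv.incidence_at(horizon) for cv in curves.values()]
    spread = float(max(incidences) - min(incidences)) if incidences else 0.0
    return curves, spread


@dataclass
class PrevalenceMatrix:
    """Pre-index carrier proportions per (code, cluster) with per-code spread."""

    codes: list[str]
    clusters: list[int]
    proportions: np.ndarray  # shape (n_codes, n_clusters)

    @property
    def spread(self) -> np.ndarray:
        return self.proportions.max(1) - self.proportions.min(1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.proportions,
            index=self.codes,
            columns=[f"cluster_{c}" for c in self.clusters],
        )
        df.index.name = "code"
        return df


def prevalence_matrix(
    records: list[PatientRecord],
    labels: dict[str, int],
    code_universe: list[str],
) -> PrevalenceMatrix:
    """Proportion of each cluster's patients carrying each code before index."""
    clusters = sorted(set(labels.values()))
    cluster_index = {c: j for j, c in enumerate(clusters)}
    sizes = np.zeros(len(clusters))
    carriers = np.zeros((len(code_universe), len(clusters)))
    code_index = {c: i for i, c in enumerate(code_universe)}
    for rec in records:
        if rec.patient_id not in labels:
            continue
        j = cluster_index[labels[rec.patient_id]]
        sizes[j] += 1
        for code in set(rec.pre_index_codes()):
            i = code_index.get(code)
            if i is not None:
                carriers[i, j] += 1
    with np.errstate(invalid="ignore"):
        props = np.where(sizes > 0, carriers / sizes, 0.0)
    return PrevalenceMatrix(list(code_universe), clusters, props)


def select_discriminative_codes(
    matrix: PrevalenceMatrix, min_spread: float = 0.30
) -> list[tuple[str, float]]:
    """Codes whose prevalence spread across clusters is at least ``min_spread``
    (default 30 percentage points), ordered by spread descending, ties broken
    lexicographically."""
    spread = matrix.spread
    chosen = [
        (code, float(s))
        for code, s in zip(matrix.codes, spread)
        if s >= min_spread
    ]
    return sorted(chosen, key=lambda cs: (-cs[1], cs[0]))


def post_index_incidence(
    records: list[PatientRecord],
    labels: dict[str, int],
    condition: str,
    horizon: float = 365.0,
    alpha: float = 0.05,
) -> tuple[dict[int, SurvivalCurve], float]:
    """Per-cluster incidence of a condition after index, excluding prevalent
    cases (patients with any pre-index record of the condition)."""
    all_codes = {e.code for r in records for e in r.events}
    if condition not in all_codes:
        raise KeyError(f"condition code {condition!r} absent from the cohort")
    at_risk = [
        r for r in records if condition not in set(r.pre_index_codes())
    ]
    return per_cluster_curves(
        at_risk,
        labels,
        "condition_onset",
        horizon=horizon,
        alpha=alpha,
        condition=condition,
    )
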