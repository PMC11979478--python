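"""Configuration-driven orchestration of the full subtyping workflow.

One run executes: ingest -> eligibility filters -> practice-level
derivation/validation split -> vectoriser fit on derivation (Transformer or
TF-IDF) -> prediction-strength selection of k on derivation -> final K-means
fit on derivation -> assignment of validation patients -> cluster quality,
one-year outcome curves and prevalence characterisation on validation.

Every stage persists its artifact as a delimited file under the output
directory and the run report echoes the configuration, so each reported
number is recomputable from the persisted intermediates.  Nothing from the
validation cohort influences any fitted parameter; the report carries an id
audit asserting this.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cluster as cl
from . import outcomes as oc
from .ehr_data import (
    PatientRecord,
    apply_cohort_filters,
    build_vocabulary,
    read_cohort,
    split_by_practice,
    tokenise_patient,
    write_cohort,
)
from .encoder import EncoderConfig, train_encoder
from .synth_cohort import (
    HF_HOSPITALISATION_CODE,
    SynthConfig,
    simulate,
    strong_signal_config,
    write_truth,
)
from .tfidf import fit_tfidf, vectorise_cohort
from .vectors import stack

log = logging.getLogger("ehrsubtype")


@dataclass
class RunConfig:
    patients_file: str
    events_file: str
    output_dir: str
    vectoriser: str = "tfidf"  # or "transformer"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    k_max: int = 8
    ps_threshold: float = 0.8
    ps_folds: int = 5
    n_restarts: int = 10
    derivation_fraction: float = 0.8
    min_age: int = 35
    min_registration_months: int = 12
    min_code_count: int = 5
    horizon_days: float = 365.0
    alpha: float = 0.05
    min_spread: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vectoriser not in ("tfidf", "transformer"):
            raise ValueError("vectoriser must be 'tfidf' or 'transformer'")
        if isinstance(self.encoder, dict):
            self.encoder = EncoderConfig(**self.encoder)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    config: dict
    attrition: dict
    n_derivation: int
    n_validation: int
    chosen_k: int
    silhouette: float
    calinski_harabasz: float
    cluster_sizes: dict[int, int]
    one_year_incidence: dict  # outcome -> cluster -> {incidence, lo, hi}
    incidence_range: dict  # outcome -> float
    discriminative_codes: list
    id_audit: dict

    def to_json(self, path: str) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
                return int(obj)
            if isinstance(obj, (np.floating, float)):
                f = float(obj)
                return f if np.isfinite(f) else None  # strict-JSON safe
            return obj

        Path(path).write_text(
            json.dumps(_clean(dataclasses.asdict(self)), indent=2, sort_keys=True)
        )


def _vectorise(
    config: RunConfig,
    derivation: list[PatientRecord],
    validation: list[PatientRecord],
):
    """Fit the chosen vectoriser on derivation, apply to both cohorts."""
    if config.vectoriser == "tfidf":
        idf = fit_tfidf(derivation)
        der_vecs = [v for v in vectorise_cohort(derivation, idf) if not v.flagged]
        val_vecs = [v for v in vectorise_cohort(validation, idf) if not v.flagged]
        der_mat, der_ids = stack(der_vecs)
        val_mat, val_ids = stack(val_vecs)
        artifact = idf
    else:
        vocab = build_vocabulary(derivation, config.min_code_count)
        # patients with no pre-index history have no representation in either
        # arm; exclude them so both vectorisers see the same cohort
        der_seqs = [
            s
            for r in derivation
            if not (s := tokenise_patient(r, vocab, config.encoder.max_len)).empty_history
        ]
        val_seqs = [
            s
            for r in validation
            if not (s := tokenise_patient(r, vocab, config.encoder.max_len)).empty_history
        ]
        model, _ = train_encoder(
            der_seqs,
            config.encoder,
            vocab,
            allowed_ids={r.patient_id for r in derivation},
        )
        der_mat = model.encode_patients(der_seqs)
        der_ids = [s.patient_id for s in der_seqs]
        val_mat = model.encode_patients(val_seqs)
        val_ids = [s.patient_id for s in val_seqs]
        artifact = model
    return der_mat, der_ids, val_mat, val_ids, artifact


def run_subtyping(
    config: RunConfig,
    records: list[PatientRecord] | None = None,
) -> RunReport:
    """Execute the full workflow and persist artifacts under the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "ingest"
    try:
        if records is None:
            records, ingest_report = read_cohort(
                config.patients_file, config.events_file
            )
            if ingest_report.orphan_patient_ids:
                log.warning(
                    "orphan event patient ids: %s",
                    ingest_report.orphan_patient_ids[:10],
                )
        stage = "filters"
        records, attrition = apply_cohort_filters(
            records, config.min_age, config.min_registration_months
        )
        (out / "attrition.txt").write_text(attrition.as_text())

        stage = "split"
        split = split_by_practice(records, config.derivation_fraction, config.seed)
        der_ids_set, val_ids_set = set(split.derivation), set(split.validation)
        derivation = [r for r in records if r.patient_id in der_ids_set]
        validation = [r for r in records if r.patient_id in val_ids_set]

        stage = "vectorise"
        der_mat, der_ids, val_mat, val_ids, _ = _vectorise(
            config, derivation, validation
        )

        stage = "select_k"
        curve = cl.ps_curve(
            der_mat,
            config.k_max,
            n_folds=config.ps_folds,
            seed=config.seed,
            threshold=config.ps_threshold,
            n_restarts=config.n_restarts,
        )
        curve.to_frame().to_csv(out / "prediction_strength.csv", index=False)
        chosen_k = cl.select_optimal_k(curve)

        stage = "cluster"
        model = cl.fit_kmeans(
            der_mat, chosen_k, seed=config.seed, n_restarts=config.n_restarts
        )
        val_labels_arr = cl.assign(model, val_mat)
        labels = dict(zip(val_ids, (int(x) for x in val_labels_arr)))
        import pandas as pd

        pd.DataFrame(
            {"patient_id": val_ids, "cluster": val_labels_arr}
        ).to_csv(out / "assignments.csv", index=False)

        stage = "evaluate"
        if chosen_k >= 2:
            quality = cl.cluster_quality(val_mat, val_labels_arr)
        else:
            quality = cl.ClusterQuality(float("nan"), float("nan"))
        one_year = {}
        ranges = {}
        for outcome in ("death", "hf_hospitalisation"):
            curves, spread = oc.per_cluster_curves(
                validation,
                labels,
                outcome,
                horizon=config.horizon_days,
                alpha=config.alpha,
            )
            per_cluster = {}
            frames = []
            for c, cv in curves.items():
                lo, hi = cv.ci_at(config.horizon_days)
                per_cluster[c] = {
                    "incidence": cv.incidence_at(config.horizon_days),
                    "ci_lower": lo,
                    "ci_upper": hi,
                }
                f = cv.to_frame()
                f.insert(0, "cluster", c)
                frames.append(f)
            pd.concat(frames).to_csv(out / f"curves_{outcome}.csv", index=False)
            one_year[outcome] = per_cluster
            ranges[outcome] = spread

        universe = sorted(
            {
                e.code
                for r in validation
                for e in r.pre_index_events()
                if e.code != HF_HOSPITALISATION_CODE
            }
        )
        pm = oc.prevalence_matrix(validation, labels, universe)
        pm.to_frame().to_csv(out / "prevalence_matrix.csv")
        disc = oc.select_discriminative_codes(pm, config.min_spread)
        pd.DataFrame(disc, columns=["code", "spread"]).to_csv(
            out / "discriminative_codes.csv", index=False
        )

        sizes: dict[int, int] = {}
        for c in val_labels_arr:
            sizes[int(c)] = sizes.get(int(c), 0) + 1

        audit = {
            "derivation_ids_used_for_fitting": sorted(der_ids) == sorted(
                set(der_ids) & der_ids_set
            ),
            "validation_overlap_with_fitting": len(set(der_ids) & val_ids_set),
            "n_derivation_vectors": len(der_ids),
            "n_validation_vectors": len(val_ids),
        }
        report = RunReport(
            config=config.echo(),
            attrition=dataclasses.asdict(attrition),
            n_derivation=len(derivation),
            n_validation=len(validation),
            chosen_k=chosen_k,
            silhouette=quality.silhouette,
            calinski_harabasz=quality.calinski_harabasz,
            cluster_sizes=sizes,
            one_year_incidence=one_year,
            incidence_range=ranges,
            discriminative_codes=disc,
            id_audit=audit,
        )
        report.to_json(str(out / "report.json"))
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def make_demo(
    output_dir: str,
    config: SynthConfig | None = None,
    run_quick_check: bool = True,
) -> dict:
    """Write the canonical preset cohort (patients/events/truth files) plus a
    digest of the headline outputs expected from it."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or strong_signal_config()
    records, truth = simulate(config)
    write_cohort(records, str(out / "patients.csv"), str(out / "events.csv"))
    write_truth(truth, str(out / "truth.csv"))
    digest = {
        "n_patients": len(records),
        "n_events": int(sum(len(r.events) for r in records)),
        "n_subtypes": len(config.subtypes),
        "seed": config.seed,
    }
    if run_quick_check:
        run_cfg = RunConfig(
            patients_file=str(out / "patients.csv"),
            events_file=str(out / "events.csv"),
            output_dir=str(out / "run"),
            vectoriser="tfidf",
            seed=config.seed,
        )
        report = run_subtyping(run_cfg, records=records)
        digest["chosen_k"] = report.chosen_k
    (out / "digest.json").write_text(json.dumps(digest, indent=2, sort_keys=True))
    return digest
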