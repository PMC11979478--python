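# ehrsubtype

Data-driven disease subtyping from longitudinal coded electronic health
records.  The package is built for the incident-heart-failure setting —
heterogeneous patients, a well-defined index date (first HF record), and
routinely coded diagnoses, procedures and medications before it — but nothing
in it is HF-specific.

It is aimed at epidemiologists and clinical-ML researchers who want to go from
two flat tables (patients, events) to validated patient clusters with
prognostic characterisation, with every stage seeded and reproducible.

## What it does

1. **Patient vectors.**  Two vectorisers over the pre-index history:
   * a **Transformer encoder** whose token embeddings sum a code, age,
     calendar-year and visit-position channel, trained with an unsupervised
     contrastive (InfoNCE) objective — two corrupted views of the same patient
     are pulled together against in-batch negatives at temperature τ; the
     patient vector is the token-mean of the averaged first and final layer
     outputs.  Implemented in NumPy with exact hand-written backpropagation.
   * a **TF-IDF baseline**: `tf(c) · (ln((1+N)/(1+df(c))) + 1)`, L2-normalised
     — a cross-sectional comparator that ignores all temporal structure.
2. **Clustering.**  K-means, with the number of clusters chosen by
   **prediction strength** under 5-fold cross-validation on the derivation
   cohort: k* is the largest k whose fold-mean ps(k) ≥ 0.8, where ps(k) is the
   minimum over test-side clusters of the fraction of within-cluster pairs
   that the training-side centroids co-assign.
3. **Evaluation** on a practice-level held-out validation cohort: silhouette
   and Calinski-Harabasz scores; one-year Kaplan-Meier cumulative incidence of
   all-cause mortality and HF hospitalisation per cluster with Greenwood
   exponential (log(−log)) 95% bands; pre-index prevalence matrices with a
   ≥ 30-percentage-point spread rule for discriminative characteristics; and
   post-index comorbidity incidence excluding prevalent cases.
4. **Synthetic cohorts.**  A generator with planted latent subtypes
   (signature codes at 0.9 per visit vs 0.05 background), Poisson visit
   histories and exponential subtype-specific outcome hazards, so the whole
   pipeline is testable without access to any real EHR.

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

```bash
ehrsubtype simulate --out demo --n-patients 1000 --seed 13
ehrsubtype run-all --patients demo/patients.csv --events demo/events.csv \
    --out demo/run --vectoriser tfidf --seed 13
```

prints (abbreviated):

```json
{
  "calinski_harabasz": 646.150286379609,
  "chosen_k": 3,
  "incidence_range": {
    "death": 0.24761904761904763,
    "hf_hospitalisation": 0.3936859553092811
  },
  "silhouette": 0.709940759356653
}
```

Reading: prediction strength recovered the three planted subtypes
(`chosen_k: 3`); on the held-out validation practices the clusters are
internally coherent (silhouette 0.71, Calinski-Harabasz 646); and the highest-
and lowest-risk clusters differ by ~25 percentage points in one-year mortality
and ~39 in one-year HF hospitalisation — the prognostic separation the planted
hazards (death 0.45/0.25/0.10 per person-year) imply.  `demo/run/` holds the full
artifact set: prediction-strength curve, assignments, per-cluster incidence
curves with confidence bands, the prevalence matrix and the
discriminative-code table, plus `report.json` echoing the configuration.

The same workflow with `--vectoriser transformer` trains the encoder on the
derivation cohort first (a few minutes on one CPU core at the default
desk-scale architecture).  Stage-by-stage verbs (`fit`, `select-k`, `cluster`,
`evaluate`, `attrition`, `split`) expose the intermediate artifacts; the
Python API (`ehrsubtype.run_subtyping`, or the individual modules) gives the
same results programmatically.

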