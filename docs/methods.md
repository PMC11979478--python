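# Methods

`ehrsubtype` stratifies an incident-disease cohort (the motivating use case is
incident heart failure) into data-driven subtypes from longitudinal coded EHR.
This note documents the models, the synthetic study conditions, the numerical
choices, and the limits of what the bundled tests demonstrate.

## Cohort model and eligibility

Input is two flat tables: a patient table (id, sex, birth year, practice,
registration start, index date, optional death date) and an event table (id,
date, code, code type ∈ {diagnosis, procedure, medication}, source).  The
*index date* is the first recorded event of the disease of interest; all
modelling inputs are events strictly before it and all outcomes are measured
from it.  Eligibility filters retain patients aged ≥ 35 years at index (age is
computed from birth year, so in whole calendar years) with ≥ 12 months of
registration before index.  The derivation/validation split is at **practice**
level (default 80/20): whole practices are randomly assigned to one side, so
no practice contributes to both model fitting and evaluation.

## Tokenisation

A patient's pre-index history becomes four aligned integer streams: code ids,
age in whole years at the event, calendar year, and visit position.  A *visit*
is a distinct calendar date — same-day events in GP data are one encounter.
Visit ids start at 1 and increment per distinct date; a leading `[CLS]` token
carries the age/year at index with visit 0.  Codes seen fewer than
`min_code_count` (default 5) times in the fitting corpus collapse to `[UNK]`.
Sequences longer than `max_len` (default 128) keep the **most recent** tokens,
on the view that history closest to onset is the most informative.  Patients
with no pre-index events cannot be represented and are excluded from both
vectoriser arms (they are flagged, never silently dropped).

## Transformer encoder with contrastive training

Each token embeds as the **sum** of four learned channels (code + age + year +
visit position, width `d_model`); the sequence passes through a pre-LayerNorm
self-attention encoder stack.  The patient vector is the token-mean over
non-padding positions of the element-wise average of the *first* encoder
layer's output and the *final* layer's output: the first layer stays close to
the lexical content of the record while the final layer is fully
contextualised, and averaging the two retains both.  (A configuration switch
pools the embedding output instead of the first encoder layer.)

Training is unsupervised InfoNCE: two stochastic views of the same patient
form a positive pair, every other patient in the batch is a negative, and the
loss is

    L = -(1/N) Σ_i log [ exp(cos(a_i, p_i)/τ) / Σ_j exp(cos(a_i, p_j)/τ) ]

with temperature τ = 0.1.  Two view constructions are implemented:

* **span-mask** (default): each view independently replaces
  `round(rate · T)` event tokens with `[UNK]`, default rate 0.5.  The
  objective then rewards representations that are invariant to which subset
  of a patient's codes happened to be recorded — a direct proxy for "similar
  medical history".  The heavy default rate is deliberate: coded histories
  are highly redundant (a subtype's signature codes recur at visit after
  visit), so even half-masked views preserve the patient's profile while
  making the discrimination task hard enough that the encoder must rely on
  the profile rather than instance-specific detail.  At light masking the
  pairs are too easy and the learned space separates subtypes only weakly.
* **dropout-twin**: the same tokens encoded twice under independent dropout
  masks (the SimCSE recipe).  At the desk-scale dropout rate (0.1) the two
  views are nearly identical, the loss starts near zero, and training barely
  moves the representation; on some seeds it *reduced* ground-truth subtype
  separation.  It remains available but is not the default for that reason.

The encoder is implemented in NumPy with hand-written backpropagation
(verified against central-difference numerical gradients to ~1e-6 relative
error in float64) and Adam.  Weights are float32; all randomness flows from a
single seeded generator, so training is bit-reproducible on one CPU.  The
desk-scale default architecture is d_model = 64, 2 layers, 4 heads,
feed-forward width 256, batch 64, learning rate 3e-3, 6 epochs — it trains on
a 2000-patient cohort in under half a minute per epoch on a single core.
Training refuses sequences from outside an explicitly permitted id set, which
the pipeline sets to the derivation cohort.

## TF-IDF baseline

The comparator treats each patient's pre-index code multiset as a document:
`tf` is the raw within-patient count and `idf(c) = ln((1+N)/(1+df(c))) + 1`
(the smoothed variant, so idf is finite and ≥ 1), with vectors L2-normalised.
Codes unseen at fit time are dropped; all-out-of-vocabulary patients yield a
flagged zero vector and are excluded downstream.  By construction the
representation ignores dates and ordering — the cross-sectional limitation the
sequence encoder is designed to overcome — and the test suite asserts this
invariance explicitly.

## Clustering and selection of k

K-means (k-means++ seeding, best of 10 restarts) runs in Euclidean space: on
unit-normalised TF-IDF vectors Euclidean distance is monotone in cosine
distance, and encoder vectors are pooled raw.  The number of clusters is
chosen by **prediction strength** under 5-fold cross-validation on the
derivation vectors only: per fold, cluster the training and test parts
independently, classify test points with the training-side centroids, and take
the minimum over test-side clusters of the fraction of within-cluster pairs
that the training centroids co-assign.  Singleton test clusters contribute a
vacuous 1; ps(1) = 1 by definition.  The selected k* is the **largest** k
whose fold-mean clears 0.8 (the lower end of the 0.8–0.9 range recommended for
the method), falling back to k = 1 with a warning.  Ties in nearest-centroid
assignment go to the lowest cluster index.

Internal quality is reported as the mean silhouette and the Calinski-Harabasz
variance ratio; both are undefined for a single cluster and CH additionally
errors on zero within-cluster scatter (an infinite ratio is reported as a
degenerate-clustering error, not a sentinel value).

## Outcome evaluation

Each cluster's prognosis is summarised by one-year Kaplan-Meier cumulative
incidence, 1 − Ŝ(t) with Ŝ(t) = Π_{t_j ≤ t}(1 − d_j/n_j), with administrative
censoring at the horizon (default 365 days) and events-first resolution of
event/censoring ties.  Confidence bands use **Greenwood's exponential
(log(−log)) formula**: with V(t) = Σ d_j/(n_j(n_j−d_j)) and
se(t) = √V(t)/|ln Ŝ(t)|, the survival bounds are Ŝ(t)^{exp(±z·se(t))}, which
cannot leave [0, 1]; plain linear Greenwood bands are available behind a flag.
Mortality and HF hospitalisation are separate single-event analyses; death
before hospitalisation censors the hospitalisation time (no competing-risks
estimator — a known limitation; with high mortality the hospitalisation
incidence is biased upward relative to an Aalen-Johansen estimate).  The
between-cluster range of incidence at the horizon is the separation summary.

Cluster characterisation uses the pre-index prevalence matrix p_{c,j}
(fraction of cluster j carrying code c before index) and flags codes whose
spread Δ_c = max_j p_{c,j} − min_j p_{c,j} is at least 0.30, ordered by spread.
Post-index comorbidity incidence excludes prevalent cases: any patient with a
pre-index record of the condition leaves that condition's risk set entirely.

## Synthetic study conditions

The generator plants the structure the pipeline is meant to recover.  Each
patient draws a latent subtype from a mixture; visits arrive as a homogeneous
Poisson process over the pre-index history window; at each visit the
subtype's signature codes fire with probability 0.9 and background codes with
0.05 (per visit).  Planted pre-index comorbidities are recorded *at clinical
encounters* — at an existing visit, or at one new encounter that also runs the
ordinary per-visit recording process — so no patient ever consists of a
single planted code.  Post-index event times (death, HF hospitalisation,
comorbidity onsets) are exponential with subtype-specific per-person-year
hazards, censored at the horizon; hospitalisations and onsets are only
recorded if they precede death.  Exponential times and Poisson visits are
deliberately minimal: every downstream estimate then has a closed-form truth
(e.g. one-year incidence 1 − e^{−λ}) for 3-standard-error tests.

The canonical **strong-signal preset** is 3 equally weighted subtypes, 8
signature codes each from a 60-code vocabulary, ~6 visits over 5 years of
history, n = 2000 patients in 10 practices, death hazards 0.45/0.25/0.10 and
hospitalisation hazards 0.55/0.30/0.12 per person-year.  What the preset does
*not* emulate: realistic code frequency distributions, care-seeking dynamics,
informative censoring, measurement noise in dates, or overlapping subtype
signatures.  Passing tests therefore demonstrate correctness of the machinery
and recoverability of strong planted structure — not performance on real EHR.

## Numerical and procedural choices

* Problem sizes in tests and the acceptance script (n = 2000 cohorts, 20
  selection runs, 10 paired training runs, 500 coverage simulations, 2
  training epochs) are chosen so the whole battery runs on a single CPU core
  in minutes while keeping Monte-Carlo tolerances (3 SE) meaningful.
* All stochastic components take explicit seeds; reruns with the same
  configuration are byte-identical.
* k-means restarts default to 10; prediction-strength folds re-seed per fold.
* Dates are whole days; hazards are per person-year with 365.25-day years.
* Empty clusters in evaluation are skipped with a warning; empty histories
  are flagged; orphan event rows are reported, never dropped silently.

## Known limitations

Single-event survival analyses (no competing risks), calendar-year age rather
than exact age, no imputation of missing baseline measurements, no code-list
curation or terminology mapping, and a synthetic-data generator that is a
testing instrument rather than a realistic EHR simulator.
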