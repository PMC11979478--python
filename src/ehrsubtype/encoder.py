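"""Contrastively trained Transformer encoder for pre-index patient histories.

The encoder embeds each event as the sum of four learned channels — code, age
(whole years), calendar year and visit position — and passes the sequence
through a self-attention stack.  A patient's representation is the token-mean
of the averaged first and final layer outputs, which mixes the near-lexical
embedding-level view of the history with the fully contextualised one.

Training is unsupervised: two stochastic views of the same patient form a
positive pair (by default two forward passes under independent dropout masks,
"dropout-twin"; alternatively "span-mask" replaces a random fraction of event
tokens with ``[UNK]`` in each view) and the InfoNCE objective with in-batch
negatives pulls the pair together at temperature ``tau`` under cosine
similarity.  Patients with similar histories end up close in the embedding
space, which is what the downstream K-means subtyping consumes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import nn
from .ehr_data import CLS, PAD, SEP, UNK, TokenSequence, Vocabulary
from .vectors import PatientVector


@dataclass
class EncoderConfig:
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    max_len: int = 128
    dropout: float = 0.1
    temperature: float = 0.1
    batch_size: int = 64
    learning_rate: float = 3e-3
    n_epochs: int = 6
    seed: int = 0
    d_ff: int | None = None  # default 4 * d_model
    pool_first: str = "encoder"  # "encoder": H^(1); "embedding": H^(0)
    positive_mode: str = "span_mask"  # or "dropout_twin"
    span_mask_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_layers < 1:
            raise ValueError("need at least one encoder layer")
        if self.pool_first not in ("encoder", "embedding"):
            raise ValueError("pool_first must be 'encoder' or 'embedding'")
        if self.positive_mode not in ("dropout_twin", "span_mask"):
            raise ValueError("positive_mode must be 'dropout_twin' or 'span_mask'")

    @property
    def ff_width(self) -> int:
        return self.d_ff if self.d_ff is not None else 4 * self.d_model


@dataclass
class LayerOutputs:
    """Per-layer token vectors for one sequence: ``layers[0]`` is the embedding
    output, ``layers[L]`` the final encoder layer; each is ``(T, d_model)``.
    ``mask`` marks real (non-padding) positions."""

    layers: list[np.ndarray]
    mask: np.ndarray
    patient_id: str

    @property
    def n_layers(self) -> int:
        return len(self.layers) - 1


class TransformerEncoder:
    """A self-attention encoder over tokenised pre-index histories."""

    def __init__(
        self,
        config: EncoderConfig,
        vocab: Vocabulary,
        params: dict[str, np.ndarray] | None = None,
    ):
        self.config = config
        self.vocab_sizes = dict(
            n_codes=vocab.size,
            n_ages=vocab.n_age_buckets,
            n_years=vocab.n_year_buckets,
            n_visits=vocab.n_visit_buckets,
        )
        if params is None:
            rng = np.random.default_rng(config.seed)
            params = nn.init_params(
                rng,
                **self.vocab_sizes,
                d_model=config.d_model,
                n_layers=config.n_layers,
                d_ff=config.ff_width,
            )
        self.params = params

    # -- batching -----------------------------------------------------------

    def _validate_ids(self, seq: TokenSequence) -> None:
        limits = (
            ("token", seq.token_ids, self.vocab_sizes["n_codes"]),
            ("age", seq.age_ids, self.vocab_sizes["n_ages"]),
            ("year", seq.year_ids, self.vocab_sizes["n_years"]),
            ("visit", seq.visit_ids, self.vocab_sizes["n_visits"]),
        )
        for name, ids, limit in limits:
            if ids.min(initial=0) < 0 or ids.max(initial=0) >= limit:
                raise ValueError(
                    f"{name} id out of range [0, {limit}) for patient "
                    f"{seq.patient_id}"
                )

    def _pack(self, seqs: list[TokenSequence]):
        for s in seqs:
            self._validate_ids(s)
        t_max = max(len(s) for s in seqs)
        padded = [s.padded(t_max) for s in seqs]
        tok = np.stack([s.token_ids for s in padded])
        age = np.stack([s.age_ids for s in padded])
        yr = np.stack([s.year_ids for s in padded])
        vis = np.stack([s.visit_ids for s in padded])
        mask = (tok != PAD).astype(np.float64)
        return tok, age, yr, vis, mask

    def _forward_batch(self, seqs, rng=None):
        tok, age, yr, vis, mask = self._pack(seqs)
        layers, cache = nn.forward(
            self.params,
            tok,
            age,
            yr,
            vis,
            mask,
            n_layers=self.config.n_layers,
            n_heads=self.config.n_heads,
            dropout=self.config.dropout if rng is not None else 0.0,
            rng=rng,
        )
        return layers, cache, mask

    # -- public API ---------------------------------------------------------

    def embed_sequence(
        self, seq: TokenSequence, rng: np.random.Generator | None = None
    ) -> LayerOutputs:
        """Encode one sequence, returning every layer's token vectors.

        Without ``rng`` the pass is deterministic (inference mode); with an
        ``rng`` dropout is active (training-mode stochastic view)."""
        layers, _, mask = self._forward_batch([seq], rng=rng)
        return LayerOutputs(
            layers=[h[0] for h in layers], mask=mask[0], patient_id=seq.patient_id
        )

    def encode_patients(
        self, seqs: list[TokenSequence], batch_size: int = 128
    ) -> np.ndarray:
        """Pooled patient vectors for a list of sequences (inference mode).

        Sequences are batched by length to minimise padding; the output rows
        follow the input order."""
        out = np.empty((len(seqs), self.config.d_model))
        first = self._pool_first_index()
        order = sorted(range(len(seqs)), key=lambda i: len(seqs[i]))
        for lo in range(0, len(seqs), batch_size):
            idx = order[lo : lo + batch_size]
            chunk = [seqs[i] for i in idx]
            layers, _, mask = self._forward_batch(chunk)
            out[idx] = _pool_batch(layers, mask, first, self.config.n_layers)
        return out

    def _pool_first_index(self) -> int:
        return 0 if self.config.pool_first == "embedding" else min(
            1, self.config.n_layers
        )

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        meta = dict(config=asdict(self.config), vocab_sizes=self.vocab_sizes)
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        ), **self.params)

    @classmethod
    def load(cls, path: str) -> "TransformerEncoder":
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = EncoderConfig(**meta["config"])
        params = {k: data[k] for k in data.files if k != "__meta__"}
        obj = cls.__new__(cls)
        obj.config = config
        obj.vocab_sizes = meta["vocab_sizes"]
        obj.params = params
        return obj


def _pool_batch(layers, mask, first: int, n_layers: int) -> np.ndarray:
    h = 0.5 * (layers[first] + layers[n_layers])
    denom = mask.sum(1, keepdims=True)
    return (h * mask[:, :, None]).sum(1) / denom


def pool_patient_vector(
    outputs: LayerOutputs, first: str = "encoder"
) -> PatientVector:
    """Mean over non-padding tokens of the averaged first and final layers.

    ``first='encoder'`` uses the first encoder layer's output H^(1);
    ``first='embedding'`` uses the embedding output H^(0).
    """
    if outputs.mask.sum() == 0:
        raise ValueError("all-padding sequence: nothing to pool")
    f = 0 if first == "embedding" else min(1, outputs.n_layers)
    h = 0.5 * (outputs.layers[f] + outputs.layers[-1])
    m = outputs.mask[:, None]
    values = (h * m).sum(0) / outputs.mask.sum()
    return PatientVector(values, outputs.patient_id, "transformer")


# ---------------------------------------------------------------------------
# Contrastive objective
# ---------------------------------------------------------------------------

def _normalise_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm vector: cosine similarity undefined")
    return x / norms, norms


def contrastive_loss(
    anchors: np.ndarray, positives: np.ndarray, temperature: float
) -> float:
    """InfoNCE with in-batch negatives under cosine similarity.

    ``loss = -(1/N) sum_i log softmax_j(cos(a_i, p_j)/tau)_i`` — row ``i`` of
    ``positives`` is the positive for row ``i`` of ``anchors``; every other row
    in the batch is a negative.
    """
    loss, _, _ = _contrastive_loss_grad(anchors, positives, temperature)
    return loss


def _contrastive_loss_grad(anchors, positives, temperature):
    a = np.atleast_2d(np.asarray(anchors, dtype=np.float64))
    p = np.atleast_2d(np.asarray(positives, dtype=np.float64))
    if a.shape != p.shape or a.shape[0] < 2:
        raise ValueError("need aligned anchor/positive batches with N >= 2")
    n = a.shape[0]
    a_hat, a_norm = _normalise_rows(a)
    p_hat, p_norm = _normalise_rows(p)
    s = a_hat @ p_hat.T / temperature
    s_shift = s - s.max(1, keepdims=True)
    log_z = np.log(np.exp(s_shift).sum(1)) + s.max(1)
    loss = float(np.mean(log_z - np.diag(s)))
    soft = np.exp(s - log_z[:, None])
    ds = (soft - np.eye(n)) / n
    da_hat = ds @ p_hat / temperature
    dp_hat = ds.T @ a_hat / temperature
    da = (da_hat - (da_hat * a_hat).sum(1, keepdims=True) * a_hat) / a_norm
    dp = (dp_hat - (dp_hat * p_hat).sum(1, keepdims=True) * p_hat) / p_norm
    return loss, da, dp


# ---------------------------------------------------------------------------
# Positive-pair construction
# ---------------------------------------------------------------------------

def span_mask_sequence(
    seq: TokenSequence, rate: float, rng: np.random.Generator
) -> TokenSequence:
    """Replace ``round(rate * n_event_tokens)`` event tokens with ``[UNK]``.

    ``[CLS]``/``[SEP]`` positions are never masked.  Rounding is to nearest.
    """
    maskable = np.where(
        (seq.token_ids != CLS) & (seq.token_ids != PAD) & (seq.token_ids != SEP)
    )[0]
    n_mask = int(round(rate * len(maskable)))
    toks = seq.token_ids.copy()
    if n_mask > 0:
        chosen = rng.choice(maskable, size=n_mask, replace=False)
        toks[chosen] = UNK
    return replace(seq, token_ids=toks)


def make_positive_pair(
    seq: TokenSequence,
    model: TransformerEncoder,
    mode: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PatientVector, PatientVector]:
    """Two stochastic views of one patient, pooled to vectors.

    ``dropout_twin`` encodes the same tokens twice under independent dropout
    masks; ``span_mask`` additionally corrupts each view's tokens.
    """
    mode = mode or model.config.positive_mode
    rng = rng or np.random.default_rng(model.config.seed)
    if mode == "dropout_twin" and model.config.dropout <= 0:
        raise ValueError(
            "dropout-twin positives need dropout > 0 (views would be identical)"
        )
    first = model.config.pool_first
    use_dropout = model.config.dropout > 0
    views = []
    for _ in range(2):
        s = seq
        if mode == "span_mask":
            s = span_mask_sequence(seq, model.config.span_mask_rate, rng)
        out = model.embed_sequence(s, rng=rng if use_dropout else None)
        views.append(pool_patient_vector(out, first=first))
    return views[0], views[1]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingLog:
    epochs: list[int]
    mean_loss: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epochs, "mean_loss": self.mean_loss})

    @property
    def final_loss(self) -> float:
        return self.mean_loss[-1]


def train_encoder(
    seqs: list[TokenSequence],
    config: EncoderConfig,
    vocab: Vocabulary,
    allowed_ids: set[str] | None = None,
) -> tuple[TransformerEncoder, TrainingLog]:
    """Train the encoder with the contrastive objective.

    ``allowed_ids`` (when given, normally the derivation-cohort ids) is a
    hygiene guard: training refuses sequences from outside it, so validation
    patients can never influence the fitted weights.  Fully seeded and
    single-threaded, hence reproducible.
    """
    if config.batch_size < 2:
        raise ValueError("batch_size must be >= 2 for in-batch negatives")
    if config.positive_mode == "dropout_twin" and config.dropout <= 0:
        raise ValueError("dropout-twin positives need dropout > 0")
    if allowed_ids is not None:
        outside = {s.patient_id for s in seqs} - set(allowed_ids)
        if outside:
            raise ValueError(
                f"training sequences outside the permitted cohort: "
                f"{sorted(outside)[:5]}"
            )
    model = TransformerEncoder(config, vocab)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params, lr=config.learning_rate)
    first = model._pool_first_index()
    log = TrainingLog([], [])
    for epoch in range(config.n_epochs):
        # length-bucketed batches (less padding), visited in random order
        order = list(rng.permutation(len(seqs)))
        order.sort(key=lambda i: len(seqs[i]))  # stable on the permuted order
        batches = [
            order[lo : lo + config.batch_size]
            for lo in range(0, len(seqs), config.batch_size)
        ]
        rng.shuffle(batches)
        losses = []
        for batch_idx in batches:
            batch = [seqs[i] for i in batch_idx]
            if len(batch) < 2:
                continue
            views = []
            for _ in range(2):
                b = batch
                if config.positive_mode == "span_mask":
                    b = [
                        span_mask_sequence(s, config.span_mask_rate, rng)
                        for s in batch
                    ]
                layers, cache, mask = model._forward_batch(b, rng=rng)
                pooled = _pool_batch(layers, mask, first, config.n_layers)
                views.append((layers, cache, mask, pooled))
            loss, da, dp = _contrastive_loss_grad(
                views[0][3], views[1][3], config.temperature
            )
            losses.append(loss)
            grads = nn.zeros_like_params(model.params)
            dtype = model.params["emb_code"].dtype
            for (layers, cache, mask, _), dv in zip(views, (da, dp)):
                d_layers = _pool_backward(dv, mask, first, config.n_layers, dtype)
                nn.backward(model.params, cache, d_layers, grads)
            opt.step(model.params, grads)
        log.epochs.append(epoch)
        log.mean_loss.append(float(np.mean(losses)))
    return model, log


def _pool_backward(
    dv, mask, first: int, n_layers: int, dtype=np.float32
) -> dict[int, np.ndarray]:
    denom = mask.sum(1)[:, None]
    per_tok = (0.5 * dv[:, None, :] * mask[:, :, None] / denom[:, None]).astype(dtype)
    d_layers = {n_layers: per_tok.copy()}
    if first == n_layers:
        d_layers[n_layers] = d_layers[n_layers] + per_tok
    else:
        d_layers[first] = per_tok.copy()
    return d_layers
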