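import datetime as dt
import math

import numpy as np
import pytest

from ehrsubtype import nn
from ehrsubtype.ehr_data import (
    CodedEvent,
    PatientRecord,
    TokenSequence,
    UNK,
    build_vocabulary,
    tokenise_patient,
)
from ehrsubtype.encoder import (
    EncoderConfig,
    LayerOutputs,
    TransformerEncoder,
    contrastive_loss,
    make_positive_pair,
    pool_patient_vector,
    span_mask_sequence,
    train_encoder,
)


def _cohort(n=12, seed=0, n_codes=8, n_visits=4):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        index = dt.date(2010, 1, 1)
        events = []
        for v in range(n_visits):
            date = index - dt.timedelta(days=30 * (v + 1))
            for _ in range(rng.integers(1, 4)):
                events.append(
                    CodedEvent(date, f"C{rng.integers(n_codes)}", "diagnosis",
                               "primary_care")
                )
        records.append(PatientRecord(
            patient_id=f"P{i}", sex="female", birth_year=1950,
            practice_id=f"G{i % 3}", registration_start=dt.date(2000, 1, 1),
            index_date=index, events=events,
        ))
    return records


@pytest.fixture()
def small_model():
    records = _cohort()
    vocab = build_vocabulary(records, 1)
    seqs = [tokenise_patient(r, vocab, 32) for r in records]
    config = EncoderConfig(d_model=16, n_layers=2, n_heads=2, max_len=32,
                           dropout=0.1, seed=0)
    return TransformerEncoder(config, vocab), vocab, seqs


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """The hand-written backward pass agrees with central differences on
        sampled coordinates of every parameter (float64)."""
        rng = np.random.default_rng(0)
        V, A, Y, P, d, L, dff, H = 11, 7, 5, 6, 8, 2, 16, 2
        params = nn.init_params(rng, V, A, Y, P, d, L, dff, dtype=np.float64)
        for k in params:  # inflate so gradients are non-trivial
            if params[k].ndim > 1:
                params[k] = params[k] * 5
        B, T = 3, 5
        tok = rng.integers(1, V, (B, T))
        age = rng.integers(0, A, (B, T))
        yr = rng.integers(0, Y, (B, T))
        vis = rng.integers(0, P, (B, T))
        mask = np.ones((B, T))
        mask[0, 3:] = 0
        tok[0, 3:] = 0

        def loss_fn(params):
            layers, cache = nn.forward(params, tok, age, yr, vis, mask, L, H)
            h = 0.5 * (layers[1] + layers[L])
            pooled = (h * mask[:, :, None]).sum(1) / mask.sum(1)[:, None]
            w = np.arange(pooled.size).reshape(pooled.shape)
            return float((np.sin(pooled) * w).sum()), layers, cache, pooled, w

        loss, layers, cache, pooled, w = loss_fn(params)
        dpooled = np.cos(pooled) * w
        per_tok = (
            0.5 * dpooled[:, None, :] * mask[:, :, None]
            / mask.sum(1)[:, None, None]
        )
        grads = nn.backward(params, cache, {L: per_tok.copy(), 1: per_tok.copy()})
        for key in params:
            for _ in range(4):
                idx = tuple(rng.integers(0, s) for s in params[key].shape)
                eps, orig = 1e-6, params[key][idx]
                params[key][idx] = orig + eps
                lp = loss_fn(params)[0]
                params[key][idx] = orig - eps
                lm = loss_fn(params)[0]
                params[key][idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key][idx]
                assert abs(num - ana) <= 1e-5 * (abs(num) + abs(ana) + 1e-3), key


class TestEmbed:
    def test_inference_is_deterministic(self, small_model):
        model, _, seqs = small_model
        o1 = model.embed_sequence(seqs[0])
        o2 = model.embed_sequence(seqs[0])
        for a, b in zip(o1.layers, o2.layers):
            np.testing.assert_array_equal(a, b)

    def test_visit_position_channel_is_live(self, small_model):
        model, _, seqs = small_model
        seq = next(s for s in seqs if len(np.unique(s.visit_ids)) > 2)
        i, j = 1, len(seq) - 1
        assert seq.visit_ids[i] != seq.visit_ids[j]
        swapped = TokenSequence(
            token_ids=seq.token_ids.copy(), age_ids=seq.age_ids.copy(),
            year_ids=seq.year_ids.copy(),
            visit_ids=seq.visit_ids.copy(), patient_id=seq.patient_id,
        )
        swapped.visit_ids[[i, j]] = swapped.visit_ids[[j, i]]
        a = model.embed_sequence(seq).layers[-1]
        b = model.embed_sequence(swapped).layers[-1]
        assert not np.allclose(a, b)

    def test_padding_does_not_move_pooled_vector(self, small_model):
        model, _, seqs = small_model
        seq = seqs[0]
        padded = seq.padded(len(seq) + 7)
        v1 = pool_patient_vector(model.embed_sequence(seq))
        v2 = pool_patient_vector(model.embed_sequence(padded))
        np.testing.assert_allclose(v1.values, v2.values, atol=1e-5)

    def test_out_of_range_id_names_stream(self, small_model):
        model, _, seqs = small_model
        bad = seqs[0].padded(len(seqs[0]))
        bad.age_ids[0] = 10_000
        with pytest.raises(ValueError, match="age id"):
            model.embed_sequence(bad)


class TestPooling:
    def _outputs(self, layers, mask=None):
        layers = [np.asarray(h, dtype=float) for h in layers]
        T = layers[0].shape[0]
        return LayerOutputs(
            layers=layers,
            mask=np.ones(T) if mask is None else np.asarray(mask, float),
            patient_id="P",
        )

    def test_identical_layers_reduce_to_token_mean(self, rng):
        h = rng.normal(size=(5, 3))
        out = self._outputs([h, h, h])
        np.testing.assert_allclose(
            pool_patient_vector(out).values, h.mean(0)
        )

    def test_single_token_hand_case(self):
        out = self._outputs([[[9.0, 9.0]], [[1.0, 0.0]], [[0.0, 1.0]]])
        np.testing.assert_allclose(
            pool_patient_vector(out).values, [0.5, 0.5]
        )

    def test_matches_elementwise_oracle(self, rng):
        h0, h1, h2 = rng.normal(size=(3, 6, 4))
        mask = np.array([1, 1, 1, 1, 0, 0], dtype=float)
        out = self._outputs([h0, h1, h2], mask)
        got = pool_patient_vector(out).values
        # brute force: loop over real positions
        acc = np.zeros(4)
        for t in range(4):
            acc += (h1[t] + h2[t]) / 2
        np.testing.assert_allclose(got, acc / 4)

    def test_pooling_linearity(self, rng):
        h0, h1, h2 = rng.normal(size=(3, 5, 4))
        c = rng.normal(size=4)
        base = pool_patient_vector(self._outputs([h0, h1, h2])).values
        shifted = pool_patient_vector(
            self._outputs([h0, h1 + c, h2 + c])
        ).values
        np.testing.assert_allclose(shifted, base + c, atol=1e-12)

    def test_all_padding_errors(self):
        out = self._outputs([np.ones((2, 3))] * 3, mask=[0, 0])
        with pytest.raises(ValueError, match="pool"):
            pool_patient_vector(out)


class TestContrastiveLoss:
    def test_uniform_similarity_gives_log_n(self):
        v = np.tile([1.0, 2.0, 3.0], (4, 1))
        assert contrastive_loss(v, v.copy(), 0.5) == pytest.approx(math.log(4))

    def test_perfect_separation_small_tau_gives_zero(self):
        a = np.eye(3)
        assert contrastive_loss(a, a.copy(), 0.01) == pytest.approx(0.0, abs=1e-9)

    def test_hand_similarity_matrix(self):
        # cosine similarities [[0.9, 0.1], [0.2, 0.8]] built in 4-D
        a = np.eye(2, 4)
        p = np.array([
            [0.9, 0.2, math.sqrt(1 - 0.81 - 0.04), 0.0],
            [0.1, 0.8, 0.0, math.sqrt(1 - 0.01 - 0.64)],
        ])
        s = np.array([[0.9, 0.1], [0.2, 0.8]])
        expected = -0.5 * sum(
            math.log(math.exp(s[i, i]) / sum(math.exp(s[i, j]) for j in range(2)))
            for i in range(2)
        )
        assert contrastive_loss(a, p, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_loss_bounds_on_random_batches(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 9))
            a = rng.normal(size=(n, 5))
            p = rng.normal(size=(n, 5))
            loss = contrastive_loss(a, p, 0.3)
            assert 0.0 < loss <= math.log(n) + 2 / 0.3

    def test_zero_norm_vector_errors(self):
        a = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="zero-norm"):
            contrastive_loss(a, a.copy(), 1.0)

    def test_batch_of_one_errors(self):
        with pytest.raises(ValueError, match="N >= 2"):
            contrastive_loss(np.ones((1, 3)), np.ones((1, 3)), 1.0)


class TestPositivePairs:
    def test_dropout_twin_views_differ(self, small_model):
        model, _, seqs = small_model
        rng = np.random.default_rng(3)
        v1, v2 = make_positive_pair(seqs[0], model, mode="dropout_twin", rng=rng)
        assert not np.allclose(v1.values, v2.values)

    def test_dropout_twin_requires_dropout(self, small_model):
        _, vocab, seqs = small_model
        cfg = EncoderConfig(d_model=16, n_layers=2, n_heads=2, dropout=0.0)
        model = TransformerEncoder(cfg, vocab)
        with pytest.raises(ValueError, match="dropout"):
            make_positive_pair(seqs[0], model, mode="dropout_twin")

    def test_span_mask_rate_zero_equals_clean_encoding(self, small_model):
        _, vocab, seqs = small_model
        cfg = EncoderConfig(d_model=16, n_layers=2, n_heads=2, dropout=0.0,
                            positive_mode="span_mask", span_mask_rate=0.0)
        model = TransformerEncoder(cfg, vocab)
        clean = pool_patient_vector(model.embed_sequence(seqs[0]))
        v1, v2 = make_positive_pair(seqs[0], model, rng=np.random.default_rng(0))
        np.testing.assert_allclose(v1.values, clean.values)
        np.testing.assert_allclose(v2.values, clean.values)

    def test_span_mask_counts_positions(self):
        seq = TokenSequence(
            token_ids=np.full(20, 5, dtype=np.int64),
            age_ids=np.zeros(20, dtype=np.int64),
            year_ids=np.zeros(20, dtype=np.int64),
            visit_ids=np.arange(20, dtype=np.int64),
            patient_id="P",
        )
        masked = span_mask_sequence(seq, 0.15, np.random.default_rng(0))
        assert int((masked.token_ids == UNK).sum()) == 3  # round(0.15 * 20)


class TestTraining:
    def test_loss_decreases_on_structured_cohort(self):
        records = _cohort(n=60, seed=1, n_codes=10)
        vocab = build_vocabulary(records, 1)
        seqs = [tokenise_patient(r, vocab, 32) for r in records]
        cfg = EncoderConfig(d_model=16, n_layers=2, n_heads=2, batch_size=16,
                            n_epochs=3, seed=0)
        _, log = train_encoder(seqs, cfg, vocab)
        assert log.mean_loss[-1] < log.mean_loss[0]

    def test_training_is_reproducible(self):
        records = _cohort(n=24, seed=2)
        vocab = build_vocabulary(records, 1)
        seqs = [tokenise_patient(r, vocab, 32) for r in records]
        cfg = EncoderConfig(d_model=16, n_layers=2, n_heads=2, batch_size=8,
                            n_epochs=2, seed=7)
        _, log1 = train_encoder(seqs, cfg, vocab)
        _, log2 = train_encoder(seqs, cfg, vocab)
        assert log1.mean_loss == log2.mean_loss

    def test_batch_size_below_two_errors(self, small_model):
        _, vocab, seqs = small_model
        cfg = EncoderConfig(d_model=16, n_layers=2, n_heads=2, batch_size=1)
        with pytest.raises(ValueError, match="batch_size"):
            train_encoder(seqs, cfg, vocab)

    def test_training_refuses_out_of_cohort_sequences(self, small_model):
        _, vocab, seqs = small_model
        cfg = EncoderConfig(d_model=16, n_layers=2, n_heads=2, n_epochs=1)
        with pytest.raises(ValueError, match="outside"):
            train_encoder(seqs, cfg, vocab, allowed_ids={"P0", "P1"})

    def test_checkpoint_roundtrip(self, small_model, tmp_path):
        model, _, seqs = small_model
        path = str(tmp_path / "model.npz")
        model.save(path)
        back = TransformerEncoder.load(path)
        np.testing.assert_allclose(
            model.encode_patients(seqs), back.encode_patients(seqs)
        )
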