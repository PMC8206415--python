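"""Sequence models: attention structure, reductions, masking, training."""

import numpy as np
import pytest

from rcmstrata._nn import load_state_dict, state_dict
from rcmstrata.sequence_models import (RCN, RCNConfig, apply_attention,
                                       build_toeplitz_attention_map, decode,
                                       encode_sequence,
                                       global_attention_scores,
                                       make_partial_sequences, toeplitz_kernel,
                                       train_rcn)
from rcmstrata.slice_encoder import FeatureSequence
from rcmstrata.stack_io import StrataLabelSequence


def tiny_config(**kw):
    base = dict(variant="toeplitz", D=1, feature_dim=12, gru_hidden=6,
                seed=2, epochs=3, recurrent_dropout=0.0, l1_recurrent=0.0)
    base.update(kw)
    return RCNConfig(**base)


def share_weights(src: RCN, dst: RCN):
    """Copy every parameter the two models have in common."""
    sd = state_dict(src.params())
    dst_params = dst.params()
    merged = state_dict(dst_params)
    merged.update({k: v for k, v in sd.items() if k in merged})
    load_state_dict(dst_params, merged)


class TestToeplitzKernel:
    def test_zero_weights_give_uniform_kernel(self):
        assert np.allclose(toeplitz_kernel(np.zeros(3)), 1 / 3)

    def test_large_logit_concentrates_mass(self):
        a = toeplitz_kernel(np.array([50.0, 0.0, 0.0]))
        assert np.allclose(a, [1.0, 0.0, 0.0], atol=1e-20)

    def test_matches_closed_form_normalized_exponentials(self):
        raw = np.array([1.0, 2.0, 3.0])
        expected = np.exp(raw) / np.exp(raw).sum()
        assert np.allclose(toeplitz_kernel(raw), expected, atol=1e-12)

    def test_even_length_rejected(self):
        with pytest.raises(ValueError):
            toeplitz_kernel(np.zeros(4))


class TestToeplitzAttentionMap:
    def test_d0_is_identity(self):
        for n in (1, 5, 20):
            assert np.allclose(build_toeplitz_attention_map(
                np.array([1.0]), n, 0).A, np.eye(n))

    def test_edge_rows_renormalized_by_hand_oracle(self):
        A = build_toeplitz_attention_map(np.array([0.25, 0.5, 0.25]), 4, 1).A
        assert np.allclose(A[0], [2 / 3, 1 / 3, 0, 0])
        assert np.allclose(A[1], [0.25, 0.5, 0.25, 0])
        assert np.allclose(A[3], [0, 0, 1 / 3, 2 / 3])

    @pytest.mark.parametrize("D", range(6))
    def test_rows_sum_to_one_for_random_kernels(self, D):
        rng = np.random.default_rng(D)
        for n in (1, 2, 7, 20):
            a = toeplitz_kernel(rng.standard_normal(2 * D + 1))
            A = build_toeplitz_attention_map(a, n, D).A
            assert np.allclose(A.sum(axis=1), 1.0, atol=1e-6)
            assert (A >= 0).all()

    def test_interior_constant_diagonals_and_banded_support(self):
        rng = np.random.default_rng(1)
        for D in range(8):
            a = toeplitz_kernel(rng.standard_normal(2 * D + 1))
            A = build_toeplitz_attention_map(a, 71, D).A
            interior = range(D, 71 - D)
            for n in interior:
                assert np.allclose(A[n, n - D:n + D + 1], a, atol=1e-12)
            m, n = np.meshgrid(np.arange(71), np.arange(71), indexing="xy")
            assert np.all(A[np.abs(m - n) > D] == 0)

    def test_masked_columns_excluded_and_renormalized(self):
        mask = np.array([True, True, False, True])
        A = build_toeplitz_attention_map(np.array([0.25, 0.5, 0.25]), 4, 1,
                                         mask).A
        assert np.all(A[:, 2] == 0)
        assert np.allclose(A[1], [0.25 / 0.75, 0.5 / 0.75, 0, 0])


class TestApplyAttention:
    def test_identity_map_returns_input_bitwise(self):
        rng = np.random.default_rng(0)
        h = rng.standard_normal((6, 4))
        out = apply_attention(np.eye(6), h)
        assert np.array_equal(out.h_tilde, h)

    def test_constant_encodings_are_fixed_point_of_any_stochastic_map(self):
        rng = np.random.default_rng(1)
        A = rng.dirichlet(np.ones(5), size=5)
        h = np.tile(rng.standard_normal(3), (5, 1))
        assert np.allclose(apply_attention(A, h).h_tilde, h)

    def test_matches_dense_matrix_product_oracle(self):
        rng = np.random.default_rng(2)
        A = rng.dirichlet(np.ones(8), size=8)
        h = rng.standard_normal((8, 5))
        assert np.allclose(apply_attention(A, h).h_tilde, A @ h, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_attention(np.eye(3), np.zeros((4, 2)))


class TestGlobalAttention:
    def test_single_slice_gives_unit_map(self):
        m = RCN(tiny_config(variant="global_attention"))
        enc = encode_sequence(m, np.random.default_rng(0).standard_normal((1, 12)))
        assert np.allclose(global_attention_scores(m, enc).A, [[1.0]])

    def test_masked_position_has_zero_column(self):
        m = RCN(tiny_config(variant="global_attention"))
        feats = np.random.default_rng(0).standard_normal((6, 12))
        mask = np.array([True] * 4 + [False] * 2)
        enc = encode_sequence(m, feats, mask)
        A = global_attention_scores(m, enc).A
        assert np.all(A[:, 4:] == 0)
        assert np.allclose(A[:4].sum(axis=1), 1.0, atol=1e-6)

    def test_zero_scoring_vector_gives_uniform_rows(self):
        m = RCN(tiny_config(variant="global_attention"))
        m.v.data[:] = 0.0
        feats = np.random.default_rng(1).standard_normal((5, 12))
        A = global_attention_scores(m, encode_sequence(m, feats)).A
        assert np.allclose(A, 1 / 5)


class TestEncodeDecode:
    def test_bidirectional_encoding_dimension(self):
        m = RCN(tiny_config(gru_hidden=64, feature_dim=256))
        feats = np.random.default_rng(0).standard_normal((10, 256))
        enc = encode_sequence(m, feats)
        assert enc.h.shape == (10, 128)

    def test_unidirectional_encoding_dimension(self):
        m = RCN(tiny_config(bidirectional=False))
        feats = np.random.default_rng(0).standard_normal((10, 12))
        assert encode_sequence(m, feats).h.shape == (10, 6)

    def test_encoding_deterministic_in_eval_mode(self):
        m = RCN(tiny_config())
        feats = np.random.default_rng(0).standard_normal((7, 12))
        a, b = encode_sequence(m, feats), encode_sequence(m, feats)
        assert np.array_equal(a.h, b.h)

    def test_decode_rows_are_probability_distributions(self):
        m = RCN(tiny_config())
        ctx = np.random.default_rng(0).standard_normal((9, 12)) @ \
            np.random.default_rng(1).standard_normal((12, m.config.h_dim))
        res = decode(m, ctx)
        assert np.allclose(res.probs.sum(axis=1), 1.0, atol=1e-6)
        assert (res.probs >= 0).all()

    def test_first_step_uses_zero_previous_probabilities(self):
        m = RCN(tiny_config())
        ctx = np.random.default_rng(3).standard_normal((1, m.config.h_dim))
        res = decode(m, ctx)
        inp = np.concatenate([ctx[0], np.zeros(3)])
        logits = inp @ m.dec_out.W.data + m.dec_out.b.data
        expect = np.exp(logits - logits.max())
        assert np.allclose(res.probs[0], expect / expect.sum(), atol=1e-12)

    def test_d0_toeplitz_equals_full_sequence_with_shared_weights(self):
        rng = np.random.default_rng(4)
        m0 = RCN(tiny_config(D=0))
        mf = RCN(tiny_config(variant="full_seq"))
        share_weights(m0, mf)
        for _ in range(20):
            n = int(rng.integers(3, 15))
            feats = FeatureSequence(rng.standard_normal((n, 12)))
            p0 = m0.predict_stack(feats).probs
            pf = mf.predict_stack(feats).probs
            assert np.abs(p0 - pf).max() <= 1e-5

    def test_reversed_sequence_changes_full_sequence_predictions(self):
        m = RCN(tiny_config(variant="full_seq"))
        rng = np.random.default_rng(5)
        feats = rng.standard_normal((10, 12))
        p_fwd = m.predict_stack(FeatureSequence(feats)).probs
        p_rev = m.predict_stack(FeatureSequence(feats[::-1])).probs
        assert np.abs(p_fwd - p_rev[::-1]).max() > 1e-6

    def test_appending_padding_never_changes_unmasked_predictions(self):
        m = RCN(tiny_config())
        rng = np.random.default_rng(6)
        feats = rng.standard_normal((8, 12))
        mask = np.ones((1, 8), dtype=bool)
        _, p_short = m.forward(feats[None], mask)
        padded = np.concatenate([feats, np.zeros((5, 12))])[None]
        pad_mask = np.concatenate([mask, np.zeros((1, 5), dtype=bool)], axis=1)
        _, p_padded = m.forward(padded, pad_mask)
        assert np.abs(p_short.data[0] - p_padded.data[0, :8]).max() <= 1e-6


class TestPartialSequences:
    def test_edge_windows_replicate_terminal_slices(self):
        feats = np.arange(5)[:, None] * np.ones((1, 2))
        windows = make_partial_sequences(feats, neighborhood=3)
        assert windows.shape == (5, 3, 2)
        assert np.allclose(windows[0, :, 0], [0, 0, 1])
        assert np.allclose(windows[4, :, 0], [3, 4, 4])

    def test_neighborhood_one_degenerates_to_single_slices(self):
        feats = np.random.default_rng(0).standard_normal((6, 3))
        windows = make_partial_sequences(feats, neighborhood=1)
        assert np.allclose(windows[:, 0, :], feats)

    def test_window_count_equals_stack_length(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(1, 40))
            assert len(make_partial_sequences(
                rng.standard_normal((n, 4)), neighborhood=3)) == n

    def test_even_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            make_partial_sequences(np.zeros((4, 2)), neighborhood=2)


def _toy_pairs(rng, n_stacks, feature_dim=12, length=12):
    """Feature sequences whose class signal is a shifted mean level."""
    pairs = []
    for _ in range(n_stacks):
        b1 = int(rng.integers(2, max(3, length // 3)))
        b2 = int(rng.integers(length // 2, length - 1))
        labels = np.concatenate([np.zeros(b1), np.ones(b2 - b1),
                                 2 * np.ones(length - b2)]).astype(int)
        feats = rng.standard_normal((length, feature_dim)) * 0.25
        feats += 1.5 * labels[:, None] * np.linspace(1.0, -1.0, feature_dim)
        pairs.append((FeatureSequence(feats),
                      StrataLabelSequence(labels)))
    return pairs


class TestTrainRCN:
    def test_training_reduces_loss_and_fits_toy_signal(self):
        rng = np.random.default_rng(0)
        pairs = _toy_pairs(rng, 12)
        cfg = tiny_config(epochs=60, lr=3e-3, batch_stacks=4, seed=0)
        model, hist = train_rcn(RCN(cfg), pairs[:9], pairs[9:], cfg)
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]
        assert max(h["val_accuracy"] for h in hist) > 0.8

    def test_best_validation_snapshot_is_returned(self):
        rng = np.random.default_rng(1)
        pairs = _toy_pairs(rng, 6)
        cfg = tiny_config(epochs=8, seed=1)
        model, hist = train_rcn(RCN(cfg), pairs[:4], pairs[4:], cfg)
        best = max(h["val_accuracy"] for h in hist)
        from rcmstrata.sequence_models import _validate
        _, acc = _validate(model, pairs[4:], cfg)
        assert acc == pytest.approx(best)

    def test_large_l1_shrinks_recurrent_weights(self):
        rng = np.random.default_rng(2)
        pairs = _toy_pairs(rng, 6)
        norms = {}
        for l1 in (0.0, 10.0):
            cfg = tiny_config(epochs=5, l1_recurrent=l1, seed=3)
            model, _ = train_rcn(RCN(cfg), pairs[:4], pairs[4:], cfg)
            norms[l1] = sum(np.abs(u.data).sum()
                            for u in model.recurrent_weights())
        assert norms[10.0] < norms[0.0]

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        rng = np.random.default_rng(3)
        pairs = _toy_pairs(rng, 4)
        cfg = tiny_config(epochs=2, lr=0.0, seed=4)
        model = RCN(cfg)
        before = state_dict(model.params())
        # snapshot selection restores the epoch-0 state, which equals init
        model, _ = train_rcn(model, pairs[:3], pairs[3:], cfg)
        after = state_dict(model.params())
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_missing_validation_set_rejected(self):
        rng = np.random.default_rng(4)
        pairs = _toy_pairs(rng, 2)
        cfg = tiny_config()
        with pytest.raises(ValueError, match="validation"):
            train_rcn(RCN(cfg), pairs, [], cfg)

    def test_partial_sequence_variant_trains(self):
        rng = np.random.default_rng(5)
        pairs = _toy_pairs(rng, 6)
        cfg = tiny_config(variant="partial_seq", epochs=6, seed=5)
        model, hist = train_rcn(RCN(cfg), pairs[:4], pairs[4:], cfg)
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]
        res = model.predict_stack(pairs[0][0])
        assert res.probs.shape == (12, 3)
        assert np.allclose(res.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_global_attention_variant_trains(self):
        rng = np.random.default_rng(6)
        pairs = _toy_pairs(rng, 6, length=8)
        cfg = tiny_config(variant="global_attention", epochs=10, seed=6)
        model, hist = train_rcn(RCN(cfg), pairs[:4], pairs[4:], cfg)
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]


class TestCheckpointRoundtrip:
    def test_save_load_preserves_predictions(self, tmp_path):
        from rcmstrata.sequence_models import load_rcn, save_rcn
        m = RCN(tiny_config(seed=7))
        feats = FeatureSequence(
            np.random.default_rng(0).standard_normal((9, 12)))
        p1 = m.predict_stack(feats).probs
        save_rcn(m, tmp_path / "m.npz")
        p2 = load_rcn(tmp_path / "m.npz").predict_stack(feats).probs
        assert np.array_equal(p1, p2)
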