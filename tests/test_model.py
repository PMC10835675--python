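"""Positional encoding, embedding, forward-pass contracts and MSE loss."""

import numpy as np
import pytest

import probedepth as pp
from probedepth import autodiff as ad


class TestPositionalEncoding:
    def test_position_zero_rows(self):
        pe = pp.positional_encoding(4, 8, base=1000.0)
        np.testing.assert_array_equal(pe[0, 0::2], 0.0)  # sin(0)
        np.testing.assert_array_equal(pe[0, 1::2], 1.0)  # cos(0)

    def test_unit_circle_identity_everywhere(self):
        pe = pp.positional_encoding(128, 64, base=1000.0)
        np.testing.assert_allclose(pe[:, 0::2] ** 2 + pe[:, 1::2] ** 2, 1.0, atol=1e-12)

    def test_matches_direct_formula_base_1000(self):
        d_model, base = 32, 1000.0
        pe = pp.positional_encoding(50, d_model, base)
        for pos in (0, 1, 7, 49):
            for i in range(d_model // 2):
                angle = pos / base ** (2 * i / d_model)
                assert pe[pos, 2 * i] == pytest.approx(np.sin(angle), abs=1e-12)
                assert pe[pos, 2 * i + 1] == pytest.approx(np.cos(angle), abs=1e-12)

    def test_sin_of_one_at_position_one(self):
        # first sin column at pos=1 has argument exactly 1 for any base
        for base in (1000.0, 10000.0):
            pe = pp.positional_encoding(2, 16, base)
            assert pe[1, 0] == pytest.approx(np.sin(1.0), abs=1e-12)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            pp.positional_encoding(8, 7)


class TestEmbedding:
    def test_zero_table_reduces_to_positional_rows(self, small_model_cfg):
        model = pp.DepthModel(small_model_cfg)
        model.params["tok_emb"].data[:] = 0.0
        ids = np.array([[3, 4, 5]])
        emb = model.embed_ids(ids)
        np.testing.assert_allclose(emb.data[0], model.pe[:3], atol=1e-6)

    def test_same_token_differs_by_positional_offset(self, small_model_cfg):
        model = pp.DepthModel(small_model_cfg)
        ids = np.array([[7, 7]])
        emb = model.embed_ids(ids).data[0]
        np.testing.assert_allclose(emb[0] - emb[1], model.pe[0] - model.pe[1], atol=1e-6)

    def test_output_shape_follows_token_count(self):
        model = pp.DepthModel(pp.ModelConfig(max_len=256))
        seq = "ACGT" * 15  # 60 nt -> 58 trimers + CLS
        ids_f, ids_r, mask = pp.encode_batch([seq], model.vocab)
        emb = model.embed_ids(ids_f)
        assert emb.shape == (1, 59, 256)

    def test_out_of_range_id_rejected(self, small_model_cfg):
        model = pp.DepthModel(small_model_cfg)
        with pytest.raises(ValueError, match="out of vocabulary"):
            model.embed_ids(np.array([[9999]]))


class TestForward:
    def test_batch_of_probes_gives_finite_scalars(self, small_model_cfg):
        model = pp.DepthModel(small_model_cfg)
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(50)]
        ids_f, ids_r, mask = pp.encode_batch(seqs, model.vocab)
        out = model.forward_ids(ids_f, ids_r, mask)
        assert out.shape == (50,)
        assert np.all(np.isfinite(out.data))

    def test_padding_invariance(self, small_model_cfg):
        """A probe's prediction must not depend on how much padding batching adds."""
        model = pp.DepthModel(small_model_cfg)
        short, long = "ACGTACGTAC", "ACGT" * 10
        ids_f, ids_r, mask = pp.encode_batch([short, long], model.vocab)
        batched = model.forward_ids(ids_f, ids_r, mask).data[0]
        ids_f1, ids_r1, mask1 = pp.encode_batch([short], model.vocab)
        alone = model.forward_ids(ids_f1, ids_r1, mask1).data[0]
        assert batched == pytest.approx(alone, abs=1e-5)

    def test_eval_mode_deterministic(self, small_model_cfg):
        model = pp.DepthModel(small_model_cfg)
        ids_f, ids_r, mask = pp.encode_batch(["ACGTACGTAC"], model.vocab)
        a = model.forward_ids(ids_f, ids_r, mask).data
        b = model.forward_ids(ids_f, ids_r, mask).data
        np.testing.assert_array_equal(a, b)

    def test_single_branch_ablation_runs(self):
        cfg = pp.ModelConfig(k=3, d_model=32, n_layers=1, n_heads=2, ffn_dim=64,
                             max_len=32, dropout=0.0, head_hidden=32, use_pam=False)
        model = pp.DepthModel(cfg)
        assert model.params["head.W1"].shape == (32, 32)  # d_model-wide head
        ids_f, ids_r, mask = pp.encode_batch(["ACGTACGTAC"], model.vocab)
        assert np.isfinite(model.forward_ids(ids_f, ids_r, mask).data).all()

    def test_tied_encoders_with_symmetric_head_strand_invariant(self):
        """With shared encoder weights and a swap-symmetric head, a probe and
        its reverse complement get identical predictions."""
        cfg = pp.ModelConfig(k=3, d_model=32, n_layers=2, n_heads=2, ffn_dim=64,
                             max_len=32, dropout=0.0, head_hidden=16, tie_encoders=True)
        model = pp.DepthModel(cfg)
        w1 = model.params["head.W1"].data
        w1[32:] = w1[:32]  # make the head symmetric under branch swap
        seq = "ACGTTACGGA"
        ids = [pp.encode_batch([s], model.vocab) for s in (seq, pp.reverse_complement(seq))]
        outs = [model.forward_ids(f, r, m).data[0] for f, r, m in ids]
        assert outs[0] == pytest.approx(outs[1], abs=1e-5)

    def test_untied_encoders_have_independent_weights(self, small_model_cfg):
        model = pp.DepthModel(small_model_cfg)
        assert not np.array_equal(model.params["fwd.l0.Wq"].data,
                                  model.params["rev.l0.Wq"].data)


class TestMseLoss:
    def test_zero_iff_equal(self):
        v = np.array([0.1, -0.5, 2.0])
        assert pp.mse_loss(v, v) == 0.0
        assert pp.mse_loss(v, v + 0.1) > 0.0

    def test_mean_of_squares(self):
        assert pp.mse_loss(np.array([1.0, -1.0]), np.zeros(2)) == pytest.approx(1.0)

    def test_single_residual(self):
        assert pp.mse_loss(np.array([3.0]), np.array([1.0])) == pytest.approx(4.0)

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            pp.mse_loss(np.zeros(2), np.zeros(3))
        with pytest.raises(ValueError):
            pp.mse_loss(np.zeros(0), np.zeros(0))


class TestCheckpoint:
    def test_save_load_round_trip(self, small_model_cfg, tmp_path):
        model = pp.DepthModel(small_model_cfg)
        norm = pp.NormalizationParams(pseudocount=1.0, mean_log10=2.0, sd_log10=0.5)
        model.save(tmp_path / "m.ckpt", norm)
        loaded, norm2 = pp.DepthModel.load(tmp_path / "m.ckpt")
        assert norm2 == norm
        ids_f, ids_r, mask = pp.encode_batch(["ACGTACGTAC"], model.vocab)
        np.testing.assert_array_equal(
            model.forward_ids(ids_f, ids_r, mask).data,
            loaded.forward_ids(ids_f, ids_r, mask).data,
        )


class TestAutodiffPrimitives:
    def test_matmul_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(0)
        a = ad.parameter(rng.normal(size=(3, 4)).astype(np.float32))
        b = ad.parameter(rng.normal(size=(4, 2)).astype(np.float32))
        out = ad.ssum(ad.matmul(a, b))
        out.backward()
        eps = 1e-2
        a.data[1, 2] += eps
        up = float(ad.matmul(a, b).data.sum())
        a.data[1, 2] -= 2 * eps
        down = float(ad.matmul(a, b).data.sum())
        a.data[1, 2] += eps
        assert a.grad[1, 2] == pytest.approx((up - down) / (2 * eps), rel=1e-3)

    def test_masked_softmax_rows_sum_to_one_on_valid_keys(self):
        rng = np.random.default_rng(1)
        scores = ad.constant(rng.normal(size=(2, 2, 5, 5)).astype(np.float32))
        mask = np.array([[True] * 5, [True, True, True, False, False]])
        p = ad.masked_softmax(scores, mask).data
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)
        assert p[1, :, :, 3:].max() < 1e-12  # masked keys get no mass

    def test_layer_norm_standardizes_last_axis(self):
        rng = np.random.default_rng(2)
        x = ad.constant(rng.normal(2.0, 3.0, size=(4, 16)).astype(np.float32))
        g = ad.constant(np.ones(16, dtype=np.float32))
        b = ad.constant(np.zeros(16, dtype=np.float32))
        out = ad.layer_norm(x, g, b).data
        np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.std(axis=-1), 1.0, atol=1e-3)
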