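"""Encoder shapes, attention algebra, fusion wiring and training behavior."""

import numpy as np
import pytest

from mirlink import autograd as ag
from mirlink.autograd import Tensor
from mirlink.model import (
    ModelConfig,
    _fusion_input_dim,
    build_pair_dataset,
    complement_permutation,
    encode_sequence,
    forward_batch,
    init_parameters,
    load_checkpoint,
    mutual_attention,
    pool_features,
    save_checkpoint,
    score_pairs,
    tokens_to_ids,
    train_model,
)
from mirlink.sequences import build_vocabulary
from mirlink.synthetic import SyntheticSpec, make_dataset

# small encoder for fast unit tests
SMALL_CFG = dict(
    mirna_len=20,
    mrna_len=64,
    cnn_filters=16,
    lstm_hidden=8,
    heads=2,
    pool=2,
    node_dim=8,
    fusion_hidden=16,
)


def small_cfg(**kw):
    return ModelConfig(**{**SMALL_CFG, **kw})


class TestConfig:
    def test_bad_enum_values_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(ablation="bogus")
        with pytest.raises(ValueError):
            ModelConfig(fusion="bogus")
        with pytest.raises(ValueError):
            ModelConfig(seq_pool="bogus")

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(lstm_hidden=3, heads=4)  # width 6 not divisible by 4

    def test_fusion_width_arithmetic(self):
        cfg = ModelConfig(duplex_path=False)
        # attended miRNA (64) + pooled mRNA (64) + two node vectors (64 each)
        assert _fusion_input_dim(cfg) == 256
        assert _fusion_input_dim(ModelConfig()) == 258  # + 2 duplex channels


class TestComplementPermutation:
    def test_involution_and_example(self):
        vocab = build_vocabulary(3)
        perm = complement_permutation(vocab)
        assert perm[vocab.index["AAA"]] == vocab.index["UUU"]
        assert perm[vocab.index["ACG"]] == vocab.index["UGC"]
        assert np.array_equal(perm[perm], np.arange(len(perm)))  # involution
        assert perm[-1] == len(vocab)  # pad maps to pad


class TestEncode:
    def test_output_length_is_floor_t_over_pool(self):
        cfg = small_cfg()
        params = init_parameters(cfg)
        ids = np.full((3, cfg.mrna_len), 5, dtype=np.int64)
        H, mask, E = encode_sequence(ids, "m", params, cfg)
        assert H.shape == (3, 32, 2 * cfg.lstm_hidden)
        assert E.shape == (3, 32, cfg.embed_dim)
        assert mask.shape == (3, 32)

    def test_nolstm_keeps_cnn_width(self):
        cfg = small_cfg(ablation="nolstm")
        params = init_parameters(cfg)
        ids = np.full((2, cfg.mrna_len), 5, dtype=np.int64)
        H, _, _ = encode_sequence(ids, "m", params, cfg)
        assert H.shape[-1] == cfg.cnn_filters

    def test_unidirectional_lstm_width(self):
        cfg = small_cfg(ablation="lstm")
        params = init_parameters(cfg)
        ids = np.full((2, cfg.mrna_len), 5, dtype=np.int64)
        H, _, _ = encode_sequence(ids, "m", params, cfg)
        assert H.shape[-1] == 2 * cfg.lstm_hidden  # same width as the BiLSTM

    def test_determinism(self):
        cfg = small_cfg()
        ids = np.arange(2 * cfg.mrna_len).reshape(2, -1) % 4096
        a = encode_sequence(ids, "m", init_parameters(cfg), cfg)[0].data
        b = encode_sequence(ids, "m", init_parameters(cfg), cfg)[0].data
        assert np.array_equal(a, b)

    def test_out_of_vocabulary_rejected(self):
        cfg = small_cfg()
        params = init_parameters(cfg)
        ids = np.full((1, cfg.mrna_len), 5000, dtype=np.int64)
        with pytest.raises(ValueError):
            encode_sequence(ids, "m", params, cfg)


class TestMutualAttention:
    def test_rows_sum_to_one_on_random_inputs(self):
        cfg = small_cfg(duplex_path=False, attn_residual_embed=False)
        params = init_parameters(cfg)
        rng = np.random.default_rng(0)
        for _ in range(20):
            H_mi = Tensor(rng.standard_normal((2, 5, cfg.att_dim)))
            H_m = Tensor(rng.standard_normal((2, 9, cfg.att_dim)))
            mask = np.ones((2, 9), dtype=np.float32)
            mask[:, 7:] = 0  # padded keys must get zero weight
            _, alpha = mutual_attention(H_mi, H_m, mask, params, cfg)
            assert np.allclose(alpha.data.sum(axis=-1), 1.0, atol=1e-6)
            assert np.all(alpha.data[:, :, :, 7:] < 1e-8)

    def test_uniform_weights_average_identical_values(self):
        # zero query row + identical key rows -> alpha = [0.5, 0.5], out = v
        cfg = ModelConfig(
            mirna_len=8,
            mrna_len=8,
            lstm_hidden=2,
            heads=1,
            duplex_path=False,
            attn_residual_embed=False,
        )
        params = init_parameters(cfg)
        eye = np.eye(cfg.att_dim, dtype=np.float32)
        for name in ("att_WQ", "att_WK", "att_WV"):
            params[name] = ag.parameter(eye.copy())
        v = np.array([1.0, -2.0, 0.5, 3.0], dtype=np.float32)
        H_mi = Tensor(np.zeros((1, 1, 4), dtype=np.float32))
        H_m = Tensor(np.stack([v, v])[None])
        out, alpha = mutual_attention(H_mi, H_m, np.ones((1, 2), np.float32), params, cfg)
        assert np.allclose(alpha.data, 0.5, atol=1e-7)
        assert np.allclose(out.data[0, 0], v, atol=1e-6)

    def test_inverse_sqrt_dk_scaling(self):
        """Tiling the feature dimension 4x quadruples raw QK^T but d_k also
        quadruples, so the pre-softmax scores only double: the 1/sqrt(d_k)
        factor halves the scale relative to unscaled QK^T."""
        rng = np.random.default_rng(1)
        q = rng.standard_normal((1, 2, 4)).astype(np.float32)
        k = rng.standard_normal((1, 3, 4)).astype(np.float32)

        def scores(qx, kx, dk):
            return (qx @ np.swapaxes(kx, -1, -2)) / np.sqrt(dk)

        s_small = scores(q, k, 4)
        s_big = scores(np.tile(q, 4), np.tile(k, 4), 16)
        assert np.allclose(s_big, 2 * s_small, atol=1e-5)


class TestPooling:
    def test_mean_example(self):
        H = Tensor(np.array([[[1.0, 3.0], [3.0, 1.0]]]))
        assert np.allclose(pool_features(H).data, [[2.0, 2.0]])

    def test_single_row(self):
        H = Tensor(np.array([[[4.0, 5.0]]]))
        assert np.allclose(pool_features(H).data, [[4.0, 5.0]])

    def test_masked_positions_excluded(self):
        H = Tensor(np.array([[[2.0, 2.0], [100.0, 100.0]]]))
        mask = np.array([[1.0, 0.0]], dtype=np.float32)
        assert np.allclose(pool_features(H, mask).data, [[2.0, 2.0]])

    def test_all_masked_gives_zeros(self):
        H = Tensor(np.ones((1, 3, 2)))
        mask = np.zeros((1, 3), dtype=np.float32)
        assert np.allclose(pool_features(H, mask).data, 0.0)

    def test_max_mode_keeps_channel_peaks(self):
        H = Tensor(np.array([[[1.0, 9.0], [5.0, 2.0]]]))
        mask = np.ones((1, 2), dtype=np.float32)
        assert np.allclose(pool_features(H, mask, "max").data, [[5.0, 9.0]])


class TestFusion:
    def _vectors(self, cfg, rng):
        d = cfg.att_dim + (2 if cfg.duplex_path and cfg.ablation != "noatt" else 0)
        return (
            Tensor(rng.standard_normal((4, d)).astype(np.float32)),
            Tensor(rng.standard_normal((4, cfg.enc_width())).astype(np.float32)),
            Tensor(rng.standard_normal((4, cfg.node_dim)).astype(np.float32)),
            Tensor(rng.standard_normal((4, cfg.node_dim)).astype(np.float32)),
        )

    @pytest.mark.parametrize("fusion", ["concat_bp", "dnn", "no_bp"])
    def test_scores_in_unit_interval(self, fusion):
        cfg = small_cfg(fusion=fusion, duplex_path=False)
        params = init_parameters(cfg)
        rng = np.random.default_rng(0)
        seq_mi = Tensor(rng.standard_normal((4, cfg.att_dim)).astype(np.float32))
        seq_m = Tensor(rng.standard_normal((4, cfg.enc_width())).astype(np.float32))
        node = Tensor(rng.standard_normal((4, cfg.node_dim)).astype(np.float32))
        from mirlink.model import fuse_and_classify

        logits = fuse_and_classify(seq_mi, seq_m, node, node, params, cfg)
        probs = 1 / (1 + np.exp(-logits.data))
        assert np.all((probs >= 0) & (probs <= 1))

    def test_no_bp_has_no_hidden_layer(self):
        with_bp = init_parameters(small_cfg(fusion="concat_bp"))
        without = init_parameters(small_cfg(fusion="no_bp"))
        assert "fc1_w" in with_bp and "fc1_w" not in without
        assert "out_w" in without

    def test_add_fusion_requires_equal_widths(self):
        with pytest.raises(ValueError):
            init_parameters(small_cfg(fusion="add"))  # node_dim 8 != att_dim 16

    def test_add_fusion_with_matching_widths(self):
        cfg = small_cfg(fusion="add", node_dim=16)
        params = init_parameters(cfg)
        assert params["fc1_w"].shape == (16, cfg.fusion_hidden)


def tiny_fixture():
    spec = SyntheticSpec(
        n_mirna=6, n_mrna=12, mrna_len_range=(60, 90), n_positive=25, seed=4
    )
    records, pairs = make_dataset(spec)
    return spec, records, pairs


def tiny_train_cfg(**kw):
    base = dict(
        mirna_len=17,
        mrna_len=90,
        cnn_filters=16,
        lstm_hidden=8,
        heads=2,
        pool=2,
        node_dim=8,
        fusion_hidden=16,
        epochs=25,
        patience=25,
        batch=16,
        dropout=0.0,
        node_dropout=0.0,
        seed=5,
    )
    return ModelConfig(**{**base, **kw})


class TestTraining:
    def test_overfits_separable_synthetic_data(self):
        from mirlink.sequences import Role, build_vocabulary, reverse_orientation

        _, records, pairs = tiny_fixture()
        by_id = {
            r.id: (reverse_orientation(r) if r.role is Role.MRNA else r)
            for r in records
        }
        cfg = tiny_train_cfg()
        ds = build_pair_dataset(
            list(pairs.pairs), pairs.label_array(), by_id, cfg, None
        )
        params, history = train_model(ds, cfg)
        scores = score_pairs(params, cfg, ds)
        acc = np.mean((scores >= 0.5) == (ds.labels == 1))
        assert acc == 1.0
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_fixed_seed_reproducible(self):
        from mirlink.sequences import Role, reverse_orientation

        _, records, pairs = tiny_fixture()
        by_id = {
            r.id: (reverse_orientation(r) if r.role is Role.MRNA else r)
            for r in records
        }
        cfg = tiny_train_cfg(epochs=4)
        ds = build_pair_dataset(list(pairs.pairs), pairs.label_array(), by_id, cfg, None)
        _, h1 = train_model(ds, cfg)
        _, h2 = train_model(ds, cfg)
        assert h1 == h2

    def test_single_class_rejected(self):
        from mirlink.sequences import Role, reverse_orientation

        _, records, pairs = tiny_fixture()
        by_id = {
            r.id: (reverse_orientation(r) if r.role is Role.MRNA else r)
            for r in records
        }
        cfg = tiny_train_cfg()
        ds = build_pair_dataset(
            list(pairs.pairs), np.ones(len(pairs), dtype=int), by_id, cfg, None
        )
        with pytest.raises(ValueError):
            train_model(ds, cfg)

    def test_checkpoint_round_trip(self, tmp_path):
        from mirlink.sequences import Role, reverse_orientation

        _, records, pairs = tiny_fixture()
        by_id = {
            r.id: (reverse_orientation(r) if r.role is Role.MRNA else r)
            for r in records
        }
        cfg = tiny_train_cfg(epochs=2)
        ds = build_pair_dataset(list(pairs.pairs), pairs.label_array(), by_id, cfg, None)
        params, _ = train_model(ds, cfg)
        save_checkpoint(tmp_path / "ck.npz", params, cfg)
        params2, cfg2 = load_checkpoint(tmp_path / "ck.npz")
        assert cfg2 == cfg
        assert np.array_equal(score_pairs(params, cfg, ds), score_pairs(params2, cfg2, ds))


def test_tokens_to_ids_pads_and_truncates():
    vocab = build_vocabulary(2)
    ids = tokens_to_ids("ACGU", vocab, capacity=5, pad_id=16)
    assert list(ids) == [vocab.index["AC"], vocab.index["CG"], vocab.index["GU"], 16, 16]
    ids = tokens_to_ids("ACGUACGU", vocab, capacity=3, pad_id=16)
    assert len(ids) == 3 and 16 not in ids
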