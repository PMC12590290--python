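"""Detector architecture: encodings, backbones, decoder contracts, grouping."""

import dataclasses

import numpy as np
import pytest

from gtpick import nn
from gtpick.model import (
    DecoderLayer,
    EncoderLayer,
    ModelConfig,
    ParticleDetector,
    build_backbone,
    load_checkpoint,
    positional_encoding,
    reference_encoding,
    save_checkpoint,
)
from gtpick.nn import Tensor, no_grad

from conftest import TINY, make_model


class TestPositionalEncoding:
    def test_origin_is_sin_zero_cos_one(self):
        pe = positional_encoding(4, 4, 16)
        np.testing.assert_allclose(pe[0, 0, 0::2], 0.0, atol=1e-12)
        np.testing.assert_allclose(pe[0, 0, 1::2], 1.0, atol=1e-12)

    def test_bounded(self):
        pe = positional_encoding(20, 20, 64)
        assert np.all(np.abs(pe) <= 1.0)

    @pytest.mark.parametrize("h,w", [(20, 20), (50, 50)])
    def test_injective_on_grid(self, h, w):
        pe = positional_encoding(h, w, 64)
        codes = {tuple(np.round(row, 10)) for row in pe.reshape(h * w, 64)}
        assert len(codes) == h * w

    def test_rejects_bad_channel_count(self):
        with pytest.raises(ValueError):
            positional_encoding(4, 4, 6)

    def test_reference_encoding_matches_family(self):
        # a reference point exactly on a grid node shares that node's code
        pe = positional_encoding(8, 8, 32)
        pts = Tensor(np.array([[2 / 8, 5 / 8]]))
        enc = reference_encoding(pts, 32).data[0]
        np.testing.assert_allclose(enc, pe[5, 2], atol=1e-10)


class TestBackbones:
    def test_tiny_stride_arithmetic(self):
        nn.manual_seed(0)
        bb = build_backbone("tiny")
        out = bb(Tensor(np.zeros((1, 1, 128, 128))))
        assert out.shape == (1, bb.out_channels, 8, 8)

    def test_resnet18_stride32_at_640(self):
        nn.manual_seed(0)
        bb = build_backbone("resnet18")
        out = bb(Tensor(np.zeros((1, 1, 640, 640))))
        assert out.shape[2:] == (20, 20)

    def test_resnet101_block_structure_and_stride(self):
        nn.manual_seed(0)
        bb = build_backbone("resnet101")
        # bottleneck [3, 4, 23, 3] -> 2048 output channels
        assert bb.out_channels == 2048
        assert [len(s.layers) for s in bb.stages] == [3, 4, 23, 3]
        out = bb(Tensor(np.zeros((1, 1, 64, 64))))
        assert out.shape == (1, 2048, 2, 2)

    def test_image_smaller_than_stride_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.backbone_forward(Tensor(np.zeros((1, 1, 8, 8))))

    def test_frozen_norm_statistics_never_change(self, tiny_model):
        from gtpick.losses import detection_loss

        before = {k: v.copy() for k, v in tiny_model.named_buffers()}
        opt = nn.AdamW(tiny_model.parameters(), lr=1e-2)
        rng = np.random.default_rng(0)
        for _ in range(3):
            tiny_model.train()
            out = tiny_model(Tensor(rng.normal(size=(1, 1, 64, 64))))
            loss, _ = detection_loss(*out[-1], [np.array([[0.5, 0.5, 0.2, 0.2]])],
                                     tiny_model.group_of)
            opt.zero_grad()
            loss.backward()
            opt.step()
        for k, v in tiny_model.named_buffers():
            np.testing.assert_array_equal(v, before[k])


class TestEncoder:
    def test_zero_layer_encoder_is_identity_after_pos(self):
        nn.manual_seed(0)
        cfg = dataclasses.replace(TINY, n_encoder_layers=0)
        model = ParticleDetector(cfg)
        fm = Tensor(np.random.default_rng(0).normal(size=(1, cfg.hidden_dim, 4, 4)))
        tokens = model.encode(fm)
        pe = positional_encoding(4, 4, cfg.hidden_dim)
        expected = fm.data.reshape(1, cfg.hidden_dim, 16).transpose(2, 0, 1) \
            + pe.reshape(16, 1, cfg.hidden_dim)
        np.testing.assert_allclose(tokens.data, expected, atol=1e-12)

    def test_batch_independence(self):
        nn.manual_seed(0)
        layer = EncoderLayer(TINY)
        layer.eval()
        x = np.random.default_rng(1).normal(size=(6, 3, TINY.hidden_dim))
        out = layer(Tensor(x)).data
        perm = [2, 0, 1]
        out_perm = layer(Tensor(x[:, perm, :])).data
        np.testing.assert_allclose(out_perm, out[:, perm, :], atol=1e-12)

    def test_self_only_mask_equals_per_token_mlp(self):
        """With attention masked to the diagonal, the layer acts per token."""
        nn.manual_seed(0)
        layer = EncoderLayer(TINY)
        layer.eval()
        x = np.random.default_rng(2).normal(size=(5, 1, TINY.hidden_dim))
        mask = np.where(np.eye(5, dtype=bool), 0.0, -np.inf)
        full = layer(Tensor(x), attn_mask=mask).data
        for i in range(5):
            single = layer(Tensor(x[i:i + 1])).data
            np.testing.assert_allclose(full[i:i + 1], single, atol=1e-10)


def _set_identity(linear):
    linear.weight.data = np.eye(linear.weight.data.shape[0])
    linear.bias.data[:] = 0.0


class TestDecoderLayer:
    def test_shape_preserved(self, tiny_model):
        tiny_model.eval()
        q = tiny_model.initial_queries(2)
        mem = Tensor(np.random.default_rng(0).normal(size=(16, 2, TINY.hidden_dim)))
        out = tiny_model.decoder_layers[0](q, mem)
        assert out.content.shape == q.content.shape

    def test_uniform_cross_attention_oracle(self):
        """Forced-uniform attention + zero FFN reduce to LayerNorm(q1 + mean M)."""
        nn.manual_seed(0)
        layer = DecoderLayer(TINY)
        layer.eval()
        layer.cross_attn.q_proj.weight.data[:] = 0.0
        layer.cross_attn.q_proj.bias.data[:] = 0.0
        layer.cross_attn.k_proj.weight.data[:] = 0.0
        layer.cross_attn.k_proj.bias.data[:] = 0.0
        _set_identity(layer.cross_attn.v_proj)
        _set_identity(layer.cross_attn.out_proj)
        layer.linear2.weight.data[:] = 0.0
        layer.linear2.bias.data[:] = 0.0

        nn.manual_seed(1)
        model = ParticleDetector(TINY)
        q = model.initial_queries(1)
        rng = np.random.default_rng(3)
        mem = Tensor(rng.normal(size=(9, 1, TINY.hidden_dim)))
        out = layer(q, mem)  # no token positions -> no locality bias

        sa = layer.self_attn(q.content, q.content, q.content)
        q1 = layer.norm1(q.content + sa)
        mean_m = mem.data.mean(axis=0, keepdims=True)
        expected = layer.norm3(layer.norm2(q1 + mean_m)).data
        np.testing.assert_allclose(out.content.data, expected, atol=1e-10)

    def test_single_query_self_attention_oracle(self):
        """One query attends only to itself: out = W_out (W_v q + b_v) + b_out."""
        nn.manual_seed(0)
        mha = nn.MultiheadAttention(16, 4)
        x = np.random.default_rng(4).normal(size=(1, 1, 16))
        out = mha(Tensor(x), Tensor(x), Tensor(x)).data
        v = x[0, 0] @ mha.v_proj.weight.data.T + mha.v_proj.bias.data
        expected = v @ mha.out_proj.weight.data.T + mha.out_proj.bias.data
        np.testing.assert_allclose(out[0, 0], expected, atol=1e-10)


class TestGrouping:
    def test_query_count_is_groups_times_queries_per_group(self):
        for g, qg in [(1, 5), (2, 10), (3, 7)]:
            cfg = dataclasses.replace(TINY, groups=g, queries_per_group=qg)
            model = make_model(cfg)
            assert model.cfg.num_queries == g * qg
            assert len(model.group_of) == g * qg
            assert all(np.sum(model.group_of == i) == qg for i in range(g))

    def test_group_isolation(self, tiny_model, rng):
        """Zeroing group 2's query content does not change group 1's output."""
        tiny_model.eval()
        mem = Tensor(rng.normal(size=(16, 1, TINY.hidden_dim)))
        q = tiny_model.initial_queries(1)
        layer = tiny_model.decoder_layers[0]
        mask = tiny_model._group_mask
        out_a = layer(q, mem, self_attn_mask=mask).content.data
        g2 = tiny_model.group_of == 1
        content = q.content.data.copy()
        content[g2] = 0.0
        q2 = dataclasses.replace(q, content=Tensor(content))
        out_b = layer(q2, mem, self_attn_mask=mask).content.data
        g1 = tiny_model.group_of == 0
        np.testing.assert_allclose(out_a[g1], out_b[g1], atol=1e-12)

    def test_grouped_equals_independent_single_group_runs(self, rng):
        """G groups with a block-diagonal mask == G shared-weight G=1 models."""
        cfg = ModelConfig(hidden_dim=16, n_heads=2, n_encoder_layers=1,
                          n_decoder_layers=2, groups=2, queries_per_group=4,
                          dropout=0.0, dim_feedforward=32, backbone="tiny")
        full = make_model(cfg, seed=11)
        full.eval()
        image = Tensor(rng.normal(size=(1, 1, 64, 64)))
        out_full = full(image)

        state = full.state_dict()
        single_cfg = dataclasses.replace(cfg, groups=1)
        for g in range(cfg.groups):
            sub = make_model(single_cfg, seed=99)
            sub.eval()
            sl = slice(g * cfg.queries_per_group, (g + 1) * cfg.queries_per_group)
            sub_state = dict(state)
            sub_state["query_embed.weight"] = state["query_embed.weight"][sl]
            sub_state["reference_logits"] = state["reference_logits"][sl]
            sub.load_state_dict(sub_state)
            out_sub = sub(image)
            for (s_full, b_full), (s_sub, b_sub) in zip(out_full, out_sub):
                np.testing.assert_allclose(s_sub.data, s_full.data[sl], atol=1e-9)
                np.testing.assert_allclose(b_sub.data, b_full.data[sl], atol=1e-9)


class TestPredictionHeads:
    def test_zero_head_anchors_at_reference_point(self):
        model = make_model(TINY)
        for layer in model.box_head.layers:
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        q = model.initial_queries(1)
        ref = np.full((TINY.num_queries, 2), 0.5)
        q = dataclasses.replace(q, reference_points=Tensor(ref))
        _, boxes = model.prediction_heads(q)
        np.testing.assert_allclose(boxes.data[:, 0, :2], 0.5, atol=1e-12)

    def test_output_ranges(self, tiny_model, rng):
        tiny_model.eval()
        with no_grad():
            out = tiny_model(Tensor(rng.normal(size=(1, 1, 64, 64))))
        for scores, boxes in out:
            assert np.all((scores.data > 0) & (scores.data < 1))
            assert np.all((boxes.data > 0) & (boxes.data < 1))

    def test_score_monotone_in_head_logit(self, tiny_model, rng):
        q = tiny_model.initial_queries(1)
        s1, _ = tiny_model.prediction_heads(q)
        tiny_model.class_head.bias.data[:] += 1.0
        s2, _ = tiny_model.prediction_heads(q)
        assert np.all(s2.data > s1.data)


class TestModelForward:
    def test_eval_determinism_and_layer_count(self, tiny_model, rng):
        tiny_model.eval()
        x = Tensor(rng.normal(size=(1, 1, 64, 64)))
        with no_grad():
            a = tiny_model(x)
            b = tiny_model(x)
        assert len(a) == TINY.n_decoder_layers
        for (sa, ba), (sb, bb) in zip(a, b):
            np.testing.assert_array_equal(sa.data, sb.data)
            np.testing.assert_array_equal(ba.data, bb.data)

    def test_checkpoint_round_trip_bitwise(self, tiny_model, rng, tmp_path):
        tiny_model.eval()
        x = Tensor(rng.normal(size=(1, 1, 64, 64)))
        with no_grad():
            before = tiny_model(x)
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path, extra={"mean_box_side": 0.1})
        loaded, extra = load_checkpoint(path)
        assert extra["mean_box_side"] == 0.1
        loaded.eval()
        with no_grad():
            after = loaded(x)
        for (sa, ba), (sb, bb) in zip(before, after):
            np.testing.assert_array_equal(sa.data, sb.data)
            np.testing.assert_array_equal(ba.data, bb.data)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_dim=30, n_heads=4)
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.5)
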