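"""Architecture wiring, masking, merge algebra, and attention export."""

from dataclasses import replace

import numpy as np
import pytest

from mippi import nn
from mippi.features import assemble_features
from mippi.network import (
    ConfigurationError,
    MIPPIModel,
    ModelConfig,
    PredictionResult,
    UnsupportedOperationError,
    build_model,
    export_attention,
    merge_branches,
    stack_examples,
)
from mippi.records import CLASS_ORDER, Origin

from conftest import make_event

TINY = dict(d_model=32, d_embed=8, n_heads=4, ffn_width=32,
            n_encoder_blocks_per_branch=1, resblock_filters=32,
            partner_len=128, dropout=0.1)


def tiny_config(**overrides):
    return ModelConfig(**{**TINY, **overrides})


def encode(event, model):
    return assemble_features(event, partner_len=model.config.partner_len)


class TestBuild:
    def test_default_config_builds_and_reports_parameter_count(self):
        model = build_model()
        n = model.count_parameters()
        assert isinstance(n, int) and n > 0

    def test_default_parameter_count_in_expected_band(self):
        # sanity band around the architecture's intended size (~1.3M)
        assert 800_000 <= build_model().count_parameters() <= 2_000_000

    def test_parameter_count_independent_of_inputs(self, tiny_model):
        n0 = tiny_model.count_parameters()
        ev = make_event()
        tiny_model.predict([encode(ev, tiny_model)])
        assert tiny_model.count_parameters() == n0

    def test_invalid_head_split_rejected(self):
        with pytest.raises(ConfigurationError):
            MIPPIModel(tiny_config(n_heads=5))

    def test_mismatched_resblock_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            MIPPIModel(tiny_config(resblock_filters=64))

    def test_no_partner_removes_branch_and_shrinks_merge(self):
        full = MIPPIModel(tiny_config(seed=3))
        ablated = MIPPIModel(tiny_config(no_partner=True, seed=3))
        assert ablated.partner_branch is None
        assert ablated.count_parameters() < full.count_parameters()
        # channel-mode merge: one segment fewer in the head's input
        assert ablated.final_conv.W.v.shape[1] == 4 * ablated.config.d_model
        assert full.final_conv.W.v.shape[1] == 5 * full.config.d_model

    def test_lstm_substitute_replaces_transformer_blocks(self):
        model = MIPPIModel(tiny_config(encoder_substitute="lstm", seed=3))
        assert len(model.mut_branch.encoders) == 1
        assert isinstance(model.mut_branch.encoders[0], nn.LSTMLayer)
        ev = make_event()
        res = model.predict([encode(ev, model)])[0]
        assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("substitute", ["dense", "conv"])
    def test_dense_and_conv_substitutes_forward(self, substitute):
        model = MIPPIModel(tiny_config(encoder_substitute=substitute, seed=3))
        res = model.predict([encode(make_event(), model)])[0]
        assert np.isfinite(res.probabilities).all()

    def test_encoder_block_structure(self, tiny_model):
        """One encoder block = 4-head self-attention + 2-layer feedforward,
        each with layer norm, dropout and a residual connection."""
        block = tiny_model.mut_branch.encoders[0]
        assert isinstance(block, nn.TransformerEncoderBlock)
        assert block.attn.h == 4
        assert isinstance(block.ln1, nn.LayerNorm)
        assert isinstance(block.ln2, nn.LayerNorm)
        assert isinstance(block.ffn.fc1, nn.Dense)
        assert isinstance(block.ffn.fc2, nn.Dense)
        assert isinstance(block.drop1, nn.Dropout)

    def test_residual_block_structure(self, tiny_model):
        """Residual block = 2 subblocks of (conv, ReLU, conv) + skip,
        ReLU, max pooling."""
        rb = tiny_model.mut_branch.resblocks[0]
        assert len(rb.subblocks) == 2
        conv1, relu1, conv2, relu2, pool = rb.subblocks[0]
        assert isinstance(conv1, nn.Conv1D) and isinstance(conv2, nn.Conv1D)
        assert isinstance(pool, nn.MaxPool1D)


class TestForward:
    def test_probabilities_sum_to_one_on_random_inputs(self, rng):
        model = MIPPIModel(tiny_config(seed=5))
        events = [make_event(event_id=f"e{i}",
                             position=int(rng.integers(1, 60)),
                             alt_aa="W")
                  for i in range(20)]
        events = [e for e in events if e.ref_aa != "W"]
        probs = model.predict_proba(stack_examples(
            [encode(e, model) for e in events]))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_forward_is_reproducible_with_dropout_disabled(self, tiny_model):
        batch = stack_examples([encode(make_event(), tiny_model)])
        a, _ = tiny_model.forward_batch(batch, train=False)
        b, _ = tiny_model.forward_batch(batch, train=False)
        np.testing.assert_array_equal(a, b)

    def test_padding_perturbation_does_not_leak_through_encoder(self):
        """Perturbing profile rows at padded positions must leave encoder
        outputs at real positions essentially unchanged."""
        model = MIPPIModel(tiny_config(seed=5))
        ev = make_event()  # partner length 47 << 128
        ex = encode(ev, model)
        batch = stack_examples([ex])

        def encoder_output(b):
            pb = model.partner_branch
            x, _ = pb.embed_input(b["partner_tokens"], b["partner_pssm"],
                                  b["partner_mask"], model.pe_partner)
            h, _ = pb.encode(x, b["partner_mask"], train=False)
            return h

        base = encoder_output(batch)
        perturbed = {k: v.copy() for k, v in batch.items()}
        pad = ~batch["partner_mask"][0]
        perturbed["partner_pssm"][0, pad] = 7.5
        out = encoder_output(perturbed)
        real = batch["partner_mask"][0]
        assert np.abs(out[0, real] - base[0, real]).max() <= 1e-5

    def test_nonmutated_input_gives_zero_sub_and_unit_div(self, tiny_model):
        ev = make_event()
        nm = replace(ev, alt_aa=ev.ref_aa, origin=Origin.NONMUTATED)
        batch = stack_examples([encode(nm, tiny_model)])
        _, cache = tiny_model.forward_batch(batch, train=False)
        r_ref, r_mut, denom, quot = cache[7][:4]
        np.testing.assert_array_equal(r_mut - r_ref, 0.0)
        # identical channels: quotient is ref/(ref+eps) ~ 1 wherever ref > 0
        positive = r_ref > 1e-3
        np.testing.assert_allclose(quot[positive], 1.0, atol=1e-3)


class TestMergeBranches:
    def test_identical_inputs_zero_subtraction(self, rng):
        x = rng.normal(size=(2, 5, 8)).astype(np.float32)
        p = rng.normal(size=(2, 7, 8)).astype(np.float32)
        merged = merge_branches(x, x, p, mode="length")
        np.testing.assert_array_equal(merged[:, 10:15], 0.0)
        merged_c = merge_branches(x, x, p, mode="channel")
        np.testing.assert_array_equal(merged_c[:, :, 16:24], 0.0)

    def test_near_zero_reference_is_clipped_finite(self):
        ref = np.full((1, 3, 4), 1e-12, dtype=np.float32)
        mut = np.ones((1, 3, 4), dtype=np.float32)
        merged = merge_branches(ref, mut, None)
        assert np.isfinite(merged).all()
        assert np.abs(merged).max() <= 100.0

    def test_merged_length_arithmetic(self, rng):
        """Length-axis mode concatenates the five segments end to end."""
        for lm, lp in [(3, 11), (12, 64), (1, 1)]:
            ref = rng.normal(size=(2, lm, 8)).astype(np.float32)
            mut = rng.normal(size=(2, lm, 8)).astype(np.float32)
            p = rng.normal(size=(2, lp, 8)).astype(np.float32)
            assert merge_branches(ref, mut, p, mode="length").shape == (
                2, 4 * lm + lp, 8)

    def test_channel_mode_gives_each_segment_its_own_channels(self, rng):
        ref = rng.normal(size=(2, 12, 8)).astype(np.float32)
        mut = rng.normal(size=(2, 12, 8)).astype(np.float32)
        p = rng.normal(size=(2, 64, 8)).astype(np.float32)
        merged = merge_branches(ref, mut, p, mode="channel")
        assert merged.shape == (2, 12, 40)
        np.testing.assert_array_equal(merged[:, :, :8], ref)
        np.testing.assert_allclose(merged[:, :, 8:16], mut, atol=0)

    def test_adaptive_pool_preserves_global_mean(self, rng):
        from mippi.network import adaptive_average_pool

        p = rng.normal(size=(3, 60, 8)).astype(np.float32)
        pooled = adaptive_average_pool(p, 12)
        # equal bins here, so pooled mean equals the original mean
        np.testing.assert_allclose(pooled.mean(axis=1), p.mean(axis=1),
                                   atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            merge_branches(np.zeros((1, 3, 4), dtype=np.float32),
                           np.zeros((1, 4, 4), dtype=np.float32), None)


class TestAttentionExport:
    def test_one_map_per_head_with_rows_summing_to_one(self, tiny_model):
        ev = make_event()
        maps = export_attention(tiny_model, encode(ev, tiny_model), "partner")
        assert len(maps) == 4
        n_real = len(ev.partner_seq)
        for amap in maps:
            assert amap.matrix.shape == (n_real, n_real)
            np.testing.assert_allclose(amap.matrix.sum(axis=1), 1.0, atol=1e-5)

    def test_padded_keys_are_excluded(self, tiny_model):
        ev = make_event()
        maps = export_attention(tiny_model, encode(ev, tiny_model), "partner")
        assert maps[0].positions.max() == len(ev.partner_seq)
        assert maps[0].positions.min() == 1

    def test_padded_keys_receive_negligible_weight_before_cropping(self, tiny_model):
        ev = make_event()
        batch = stack_examples([encode(ev, tiny_model)])
        tiny_model.forward_batch(batch, train=False)
        attn = tiny_model._attn_partner  # (1, heads, L, L)
        pad = ~batch["partner_mask"][0]
        real = batch["partner_mask"][0]
        assert attn[0][:, real][:, :, pad].max() <= 1e-6

    def test_export_without_transformer_is_unsupported(self):
        model = MIPPIModel(tiny_config(encoder_substitute="dense", seed=3))
        with pytest.raises(UnsupportedOperationError):
            export_attention(model, encode(make_event(), model), "partner")


class TestPredictionResult:
    def test_argmax_ties_break_to_lowest_canonical_index(self):
        res = PredictionResult.from_probabilities(np.array([0.3, 0.3, 0.3, 0.1]))
        assert res.predicted is CLASS_ORDER[0]

    def test_effective_grouping_preserves_normalization(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            effective = p[0] + p[1] + p[3]
            assert effective + p[2] == pytest.approx(1.0, abs=1e-12)


class TestCheckpoint:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path, tiny_model):
        from mippi.network import load_checkpoint, save_checkpoint

        ev = make_event()
        before = tiny_model.predict([encode(ev, tiny_model)])[0]
        save_checkpoint(tiny_model, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        after = loaded.predict([encode(ev, loaded)])[0]
        np.testing.assert_allclose(before.probabilities, after.probabilities,
                                   atol=1e-7)
        assert loaded.config.d_model == tiny_model.config.d_model
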