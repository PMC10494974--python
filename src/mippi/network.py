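"""The interaction-impact classifier.

Two parallel branches process the encoded inputs.  The mutation branch
embeds the reference and mutant 51-residue windows with *shared*
weights, passes each through a stack of masked transformer encoder
blocks and a residual convolution block; the partner branch has its own
embedding, encoder stack and two residual blocks.  The two mutation-
branch outputs are subtracted and divided elementwise to form two
auxiliary difference representations; the five representations
(reference, mutant, difference, ratio, partner) are concatenated along
the length axis, passed through a 1D convolution with one filter per
class, globally average-pooled, and normalized with softmax into four
class probabilities.

Each input position is a d_model-dimensional vector: 20 profile values,
a learned token embedding, and a sinusoidal positional encoding,
concatenated (default 20 + 44 + 64 = 128).

Ablation switches reproduce the published architecture studies: remove
the partner branch, remove the profile features, replace global average
pooling with a dense layer, or substitute the transformer blocks with
dense / convolutional / LSTM layers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .features import EncodedExample, PositionalEncodingSpec, positional_encoding
from .records import CLASS_ORDER, ImpactLabel

F32 = nn.F32


class ConfigurationError(ValueError):
    pass


class UnsupportedOperationError(RuntimeError):
    pass


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier; defaults are the full model."""

    d_model: int = 128
    n_heads: int = 4
    n_encoder_blocks_per_branch: int = 3
    ffn_width: int = 256
    dropout: float = 0.1
    n_resblocks_mut: int = 1
    n_resblocks_partner: int = 2
    conv_kernel: int = 3
    resblock_filters: int = 128
    pool_size: int = 2
    final_conv_filters: int = 4
    merge_mode: str = "channel"  # channel | length
    init: str = "he_uniform"
    # ablation switches
    no_partner: bool = False
    no_pssm: bool = False
    gap_to_dense: bool = False
    encoder_substitute: str = "transformer"  # transformer | dense | conv | lstm
    epsilon_div: float = 1e-6
    seed: int = 0
    # input geometry
    d_embed: int = 44
    mut_window: int = 51
    partner_len: int = 1024

    @property
    def pe_dim(self) -> int:
        return self.d_model - 20 - self.d_embed

    def validate(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ConfigurationError(
                f"d_model {self.d_model} not divisible by n_heads {self.n_heads}"
            )
        if self.pe_dim <= 0 or self.pe_dim % 2 != 0:
            raise ConfigurationError(
                f"positional-encoding width d_model - 20 - d_embed = {self.pe_dim} "
                f"must be positive and even"
            )
        if self.resblock_filters != self.d_model:
            raise ConfigurationError(
                "resblock_filters must equal d_model (identity skips preserve channels)"
            )
        if self.encoder_substitute not in ("transformer", "dense", "conv", "lstm"):
            raise ConfigurationError(
                f"unknown encoder substitute: {self.encoder_substitute!r}"
            )
        if self.final_conv_filters != len(CLASS_ORDER):
            raise ConfigurationError("final conv needs one filter per class")
        if self.merge_mode not in ("channel", "length"):
            raise ConfigurationError(f"unknown merge mode: {self.merge_mode!r}")


@dataclass(frozen=True)
class PredictionResult:
    """Four class probabilities (canonical order) and the argmax call."""

    probabilities: np.ndarray
    predicted: ImpactLabel
    confidence: float

    @classmethod
    def from_probabilities(cls, probs: np.ndarray) -> "PredictionResult":
        probs = np.asarray(probs, dtype=float)
        idx = int(np.argmax(probs))  # ties: lowest canonical index wins
        return cls(probabilities=probs, predicted=CLASS_ORDER[idx],
                   confidence=float(probs[idx]))


@dataclass(frozen=True)
class AttentionMap:
    """One head's attention weights for one input, padding removed."""

    layer: int
    head: int
    matrix: np.ndarray  # (Lq, Lk) over non-padded positions
    positions: np.ndarray  # 1-based residue positions of the retained rows/cols


def _pooled_length(length: int, n_resblocks: int, pool: int) -> int:
    for _ in range(2 * n_resblocks):  # two pooling stages per residual block
        length //= pool
    return length


def _pool_bins(in_len: int, out_len: int) -> list[tuple[int, int]]:
    bins = []
    for i in range(out_len):
        lo = (i * in_len) // out_len
        hi = max(lo + 1, ((i + 1) * in_len) // out_len)
        bins.append((lo, hi))
    return bins


def adaptive_average_pool(x: np.ndarray, out_len: int) -> np.ndarray:
    """Resample the length axis of (B, L, C) to ``out_len`` bins by
    averaging (repeating entries when upsampling)."""
    bins = _pool_bins(x.shape[1], out_len)
    return np.stack([x[:, lo:hi].mean(axis=1) for lo, hi in bins], axis=1)


def merge_branches(
    ref_repr: np.ndarray,
    mut_repr: np.ndarray,
    partner_repr: np.ndarray | None,
    epsilon: float = 1e-6,
    clip: float = 100.0,
    mode: str = "channel",
) -> np.ndarray:
    """Merge (ref, mut, mut-ref, mut/(ref+eps), partner) into one tensor.

    ``mode="channel"`` (default) aligns the partner to the mutation-branch
    length by adaptive average pooling and concatenates the five
    representations along the channel axis, so the classifier can weight
    each of them independently.  ``mode="length"`` concatenates along the
    length axis instead (all segments then share channels and the
    average-pooled classifier sees only their pooled sum, which buries
    the auxiliary difference vectors; kept for comparison).

    The elementwise quotient is clipped to ``[-clip, clip]`` so near-zero
    reference activations cannot produce non-finite values.
    """
    if ref_repr.shape != mut_repr.shape:
        raise ValueError(
            f"shape mismatch: ref {ref_repr.shape} vs mut {mut_repr.shape}"
        )
    aux_sub = mut_repr - ref_repr
    aux_div = np.clip(mut_repr / (ref_repr + F32(epsilon)), -clip, clip)
    parts = [ref_repr, mut_repr, aux_sub, aux_div]
    if partner_repr is not None:
        if partner_repr.shape[-1] != ref_repr.shape[-1]:
            raise ValueError("partner channel width differs from mutation branch")
        if mode == "channel":
            parts.append(adaptive_average_pool(partner_repr, ref_repr.shape[1]))
        else:
            parts.append(partner_repr)
    axis = 2 if mode == "channel" else 1
    if mode not in ("channel", "length"):
        raise ValueError(f"unknown merge mode: {mode!r}")
    return np.concatenate(parts, axis=axis)


class _Branch:
    """Embedding + encoder stack + residual blocks for one input family."""

    def __init__(self, cfg: ModelConfig, rng, drop_rng, n_resblocks: int, name: str):
        self.cfg = cfg
        self.embed = nn.Embedding(rng, 21, cfg.d_embed, f"{name}.embed")
        self.encoders: list = []
        sub = cfg.encoder_substitute
        if sub == "transformer":
            for i in range(cfg.n_encoder_blocks_per_branch):
                self.encoders.append(nn.TransformerEncoderBlock(
                    rng, cfg.d_model, cfg.n_heads, cfg.ffn_width, cfg.dropout,
                    drop_rng, f"{name}.enc{i}", cfg.init))
        elif sub == "dense":
            for i in range(cfg.n_encoder_blocks_per_branch):
                self.encoders.append(
                    (nn.Dense(rng, cfg.d_model, cfg.d_model, f"{name}.dense{i}",
                              cfg.init), nn.ReLU()))
        elif sub == "conv":
            for i in range(cfg.n_encoder_blocks_per_branch):
                self.encoders.append(
                    (nn.Conv1D(rng, cfg.d_model, cfg.d_model, cfg.conv_kernel,
                               f"{name}.conv{i}", cfg.init), nn.ReLU()))
        elif sub == "lstm":
            self.encoders.append(nn.LSTMLayer(rng, cfg.d_model, cfg.d_model,
                                              f"{name}.lstm"))
        self.resblocks = [
            nn.ResidualConvBlock(rng, cfg.d_model, cfg.conv_kernel, cfg.pool_size,
                                 f"{name}.res{i}", cfg.init)
            for i in range(n_resblocks)
        ]

    def params(self):
        out = self.embed.params()
        for enc in self.encoders:
            if isinstance(enc, tuple):
                out += enc[0].params()
            else:
                out += enc.params()
        for rb in self.resblocks:
            out += rb.params()
        return out

    def embed_input(self, tokens, pssm, mask, pe):
        emb, ce = self.embed.forward(tokens)
        pssm_part = np.zeros_like(pssm) if self.cfg.no_pssm else pssm
        B = tokens.shape[0]
        pe_part = np.broadcast_to(pe, (B,) + pe.shape)
        x = np.concatenate(
            [pssm_part.astype(F32), emb, pe_part.astype(F32)], axis=-1
        ) * mask[..., None].astype(F32)
        return x, (ce, mask)

    def embed_backward(self, cache, grad):
        ce, mask = cache
        grad = grad * mask[..., None].astype(F32)
        de = self.cfg.d_embed
        self.embed.backward(ce, grad[:, :, 20:20 + de])

    def encode(self, x, mask, train):
        caches = []
        for enc in self.encoders:
            if isinstance(enc, nn.TransformerEncoderBlock):
                x, c = enc.forward(x, mask, train)
            elif isinstance(enc, nn.LSTMLayer):
                x, c = enc.forward(x)
            else:
                layer, relu = enc
                x, c1 = layer.forward(x)
                x, c2 = relu.forward(x)
                c = (c1, c2)
            caches.append(c)
        return x, caches

    def encode_backward(self, caches, grad):
        for enc, c in zip(reversed(self.encoders), reversed(caches)):
            if isinstance(enc, nn.TransformerEncoderBlock):
                grad = enc.backward(c, grad)
            elif isinstance(enc, nn.LSTMLayer):
                grad = enc.backward(c, grad)
            else:
                layer, relu = enc
                grad = relu.backward(c[1], grad)
                grad = layer.backward(c[0], grad)
        return grad

    def reduce(self, x):
        caches = []
        for rb in self.resblocks:
            x, c = rb.forward(x)
            caches.append(c)
        return x, caches

    def reduce_backward(self, caches, grad):
        for rb, c in zip(reversed(self.resblocks), reversed(caches)):
            grad = rb.backward(c, grad)
        return grad

    def last_attention(self):
        for enc in reversed(self.encoders):
            if isinstance(enc, nn.TransformerEncoderBlock):
                return enc.attn.last_attention
        raise UnsupportedOperationError(
            "attention export requires transformer encoder blocks"
        )


class MIPPIModel:
    """The full classifier; see the module docstring for the wiring."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        init_seed, drop_seed = ss.spawn(2)
        rng = np.random.default_rng(init_seed)
        self.drop_rng = np.random.default_rng(drop_seed)

        self.mut_branch = _Branch(config, rng, self.drop_rng,
                                  config.n_resblocks_mut, "mut")
        self.partner_branch = None
        if not config.no_partner:
            self.partner_branch = _Branch(config, rng, self.drop_rng,
                                          config.n_resblocks_partner, "partner")

        pe_spec = PositionalEncodingSpec(d_model=config.pe_dim)
        self.pe_mut = positional_encoding(config.mut_window, pe_spec).astype(F32)
        self.pe_partner = positional_encoding(config.partner_len, pe_spec).astype(F32)

        self.l_mut = _pooled_length(config.mut_window, config.n_resblocks_mut,
                                    config.pool_size)
        self.l_partner = 0
        if not config.no_partner:
            self.l_partner = _pooled_length(config.partner_len,
                                            config.n_resblocks_partner,
                                            config.pool_size)
        n_segments = 4 if config.no_partner else 5
        if config.merge_mode == "channel":
            self.l_merged = self.l_mut
            head_channels = n_segments * config.d_model
        else:
            self.l_merged = 4 * self.l_mut + self.l_partner
            head_channels = config.d_model

        self.final_conv = nn.Conv1D(rng, head_channels, config.final_conv_filters,
                                    config.conv_kernel, "head.conv", config.init)
        self.gap = nn.GlobalAveragePool()
        self.final_dense = None
        if config.gap_to_dense:
            self.final_dense = nn.Dense(
                rng, self.l_merged * config.final_conv_filters,
                len(CLASS_ORDER), "head.dense", config.init)

        names = [p.name for p in self.params()]
        assert len(names) == len(set(names)), "duplicate parameter names"

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[nn.Param]:
        out = self.mut_branch.params()
        if self.partner_branch is not None:
            out += self.partner_branch.params()
        out += self.final_conv.params()
        if self.final_dense is not None:
            out += self.final_dense.params()
        return out

    def count_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    # -- forward / backward -------------------------------------------------

    def forward_batch(self, batch: dict, train: bool = False):
        """Compute logits for a stacked batch; returns (logits, cache)."""
        cfg = self.config
        mb = self.mut_branch
        x_ref, ce_ref = mb.embed_input(batch["ref_tokens"], batch["ref_pssm"],
                                       batch["ref_mask"], self.pe_mut)
        x_mut, ce_mut = mb.embed_input(batch["mut_tokens"], batch["mut_pssm"],
                                       batch["mut_mask"], self.pe_mut)
        h_ref, cenc_ref = mb.encode(x_ref, batch["ref_mask"], train)
        self._attn_ref = self._grab_attention(mb)
        h_mut, cenc_mut = mb.encode(x_mut, batch["mut_mask"], train)
        self._attn_mut = self._grab_attention(mb)
        r_ref, cres_ref = mb.reduce(h_ref)
        r_mut, cres_mut = mb.reduce(h_mut)

        r_partner = None
        partner_caches = None
        if self.partner_branch is not None:
            pb = self.partner_branch
            x_p, ce_p = pb.embed_input(batch["partner_tokens"], batch["partner_pssm"],
                                       batch["partner_mask"], self.pe_partner)
            h_p, cenc_p = pb.encode(x_p, batch["partner_mask"], train)
            self._attn_partner = self._grab_attention(pb)
            r_partner, cres_p = pb.reduce(h_p)
            partner_caches = (ce_p, cenc_p, cres_p)

        eps, clip = F32(cfg.epsilon_div), F32(100.0)
        denom = r_ref + eps
        quot_raw = r_mut / denom
        clip_mask = np.abs(quot_raw) <= clip
        merged = merge_branches(r_ref, r_mut, r_partner, cfg.epsilon_div, 100.0,
                                cfg.merge_mode)
        self._last_merged = merged

        conv_out, c_conv = self.final_conv.forward(merged)
        if self.final_dense is not None:
            B = conv_out.shape[0]
            flat = conv_out.reshape(B, -1)
            logits, c_dense = self.final_dense.forward(flat)
            head_cache = (c_conv, ("dense", c_dense, conv_out.shape))
        else:
            logits, c_gap = self.gap.forward(conv_out)
            head_cache = (c_conv, ("gap", c_gap, None))

        l_p = r_partner.shape[1] if r_partner is not None else 0
        cache = (ce_ref, ce_mut, cenc_ref, cenc_mut, cres_ref, cres_mut,
                 partner_caches, (r_ref, r_mut, denom, quot_raw, clip_mask, l_p),
                 head_cache)
        return logits, cache

    def _split_merge_grad(self, dmerged, merge_cache):
        """Gradients of the five merged segments back to (ref, mut, partner)."""
        r_ref, r_mut, denom, quot_raw, clip_mask, l_p = merge_cache
        Lm = r_ref.shape[1]
        d = r_ref.shape[2]
        if self.config.merge_mode == "channel":
            g_ref = dmerged[:, :, 0 * d:1 * d].copy()
            g_mut = dmerged[:, :, 1 * d:2 * d].copy()
            g_sub = dmerged[:, :, 2 * d:3 * d]
            g_div = dmerged[:, :, 3 * d:4 * d] * clip_mask
            g_partner = None
            if not self.config.no_partner and dmerged.shape[2] > 4 * d:
                g_pool = dmerged[:, :, 4 * d:5 * d]
                # un-pool: distribute each bin's gradient over its members
                g_partner = np.zeros((dmerged.shape[0], l_p, d), dtype=nn.F32)
                for i, (lo, hi) in enumerate(_pool_bins(l_p, Lm)):
                    g_partner[:, lo:hi] += (g_pool[:, i][:, None, :]
                                            / nn.F32(hi - lo))
        else:
            g_ref = dmerged[:, 0 * Lm:1 * Lm].copy()
            g_mut = dmerged[:, 1 * Lm:2 * Lm].copy()
            g_sub = dmerged[:, 2 * Lm:3 * Lm]
            g_div = dmerged[:, 3 * Lm:4 * Lm] * clip_mask
            g_partner = None
            if not self.config.no_partner and dmerged.shape[1] > 4 * Lm:
                g_partner = dmerged[:, 4 * Lm:]
        g_mut += g_sub + g_div / denom
        g_ref += -g_sub - g_div * quot_raw / denom
        return g_ref, g_mut, g_partner

    def backward_batch(self, cache, dlogits) -> None:
        (ce_ref, ce_mut, cenc_ref, cenc_mut, cres_ref, cres_mut,
         partner_caches, merge_cache, head_cache) = cache
        c_conv, (head_kind, c_head, conv_shape) = head_cache
        if head_kind == "dense":
            dflat = self.final_dense.backward(c_head, dlogits)
            dconv = dflat.reshape(conv_shape)
        else:
            dconv = self.gap.backward(c_head, dlogits)
        dmerged = self.final_conv.backward(c_conv, dconv)
        g_ref, g_mut, g_partner = self._split_merge_grad(dmerged, merge_cache)

        mb = self.mut_branch
        g = mb.reduce_backward(cres_ref, g_ref)
        g = mb.encode_backward(cenc_ref, g)
        mb.embed_backward(ce_ref, g)
        g = mb.reduce_backward(cres_mut, g_mut)
        g = mb.encode_backward(cenc_mut, g)
        mb.embed_backward(ce_mut, g)

        if self.partner_branch is not None and g_partner is not None:
            ce_p, cenc_p, cres_p = partner_caches
            pb = self.partner_branch
            g = pb.reduce_backward(cres_p, g_partner)
            g = pb.encode_backward(cenc_p, g)
            pb.embed_backward(ce_p, g)

    def merged_representation(self, batch: dict, chunk: int = 256) -> np.ndarray:
        """Trunk output: the merged five-segment representation, computed
        with dropout disabled (used to refit the classifier head on a
        frozen trunk)."""
        parts = []
        n = batch["ref_tokens"].shape[0]
        for s in range(0, n, chunk):
            sub = {k: v[s:s + chunk] for k, v in batch.items()}
            self.forward_batch(sub, train=False)
            parts.append(self._last_merged)
        return np.concatenate(parts)

    def encoder_outputs(self, batch: dict, chunk: int = 256):
        """Frozen-trunk encoder outputs for the three streams (dropout off)."""
        cfg = self.config
        mb = self.mut_branch
        refs, muts, partners = [], [], []
        n = batch["ref_tokens"].shape[0]
        for s in range(0, n, chunk):
            sub = {k: v[s:s + chunk] for k, v in batch.items()}
            x_ref, _ = mb.embed_input(sub["ref_tokens"], sub["ref_pssm"],
                                      sub["ref_mask"], self.pe_mut)
            x_mut, _ = mb.embed_input(sub["mut_tokens"], sub["mut_pssm"],
                                      sub["mut_mask"], self.pe_mut)
            h_ref, _ = mb.encode(x_ref, sub["ref_mask"], False)
            h_mut, _ = mb.encode(x_mut, sub["mut_mask"], False)
            refs.append(h_ref)
            muts.append(h_mut)
            if self.partner_branch is not None:
                pb = self.partner_branch
                x_p, _ = pb.embed_input(sub["partner_tokens"], sub["partner_pssm"],
                                        sub["partner_mask"], self.pe_partner)
                h_p, _ = pb.encode(x_p, sub["partner_mask"], False)
                partners.append(h_p)
        h_p_all = np.concatenate(partners) if partners else None
        return np.concatenate(refs), np.concatenate(muts), h_p_all

    def readout_forward(self, h_ref, h_mut, h_partner):
        """Residual blocks + merge + classifier head on encoder outputs."""
        mb = self.mut_branch
        r_ref, cres_ref = mb.reduce(h_ref)
        r_mut, cres_mut = mb.reduce(h_mut)
        r_p, cres_p = (None, None)
        if self.partner_branch is not None and h_partner is not None:
            r_p, cres_p = self.partner_branch.reduce(h_partner)
        eps = F32(self.config.epsilon_div)
        denom = r_ref + eps
        quot_raw = r_mut / denom
        clip_mask = np.abs(quot_raw) <= F32(100.0)
        merged = merge_branches(r_ref, r_mut, r_p, self.config.epsilon_div,
                                100.0, self.config.merge_mode)
        logits, c_head = self.head_forward(merged)
        l_p = r_p.shape[1] if r_p is not None else 0
        return logits, (cres_ref, cres_mut, cres_p,
                        (r_ref, r_mut, denom, quot_raw, clip_mask, l_p), c_head)

    def readout_backward(self, cache, dlogits) -> None:
        cres_ref, cres_mut, cres_p, merge_cache, c_head = cache
        c_conv, (kind, c_h, conv_shape) = c_head
        if kind == "dense":
            dconv = self.final_dense.backward(c_h, dlogits).reshape(conv_shape)
        else:
            dconv = self.gap.backward(c_h, dlogits)
        dmerged = self.final_conv.backward(c_conv, dconv)
        g_ref, g_mut, g_partner = self._split_merge_grad(dmerged, merge_cache)
        mb = self.mut_branch
        mb.reduce_backward(cres_ref, g_ref)
        mb.reduce_backward(cres_mut, g_mut)
        if self.partner_branch is not None and cres_p is not None and \
                g_partner is not None:
            self.partner_branch.reduce_backward(cres_p, g_partner)

    def readout_params(self) -> list[nn.Param]:
        out = []
        for rb in self.mut_branch.resblocks:
            out += rb.params()
        if self.partner_branch is not None:
            for rb in self.partner_branch.resblocks:
                out += rb.params()
        return out + self.head_params()

    def head_forward(self, merged: np.ndarray):
        """Classifier head only: conv (+ GAP or dense) producing logits."""
        conv_out, c_conv = self.final_conv.forward(merged)
        if self.final_dense is not None:
            B = conv_out.shape[0]
            logits, c_dense = self.final_dense.forward(conv_out.reshape(B, -1))
            return logits, (c_conv, ("dense", c_dense, conv_out.shape))
        logits, c_gap = self.gap.forward(conv_out)
        return logits, (c_conv, ("gap", c_gap, None))

    def head_backward(self, cache, dlogits) -> None:
        c_conv, (kind, c_head, conv_shape) = cache
        if kind == "dense":
            dconv = self.final_dense.backward(c_head, dlogits).reshape(conv_shape)
        else:
            dconv = self.gap.backward(c_head, dlogits)
        self.final_conv.backward(c_conv, dconv)

    def head_params(self) -> list[nn.Param]:
        out = self.final_conv.params()
        if self.final_dense is not None:
            out += self.final_dense.params()
        return out

    @staticmethod
    def _grab_attention(branch: _Branch):
        try:
            return branch.last_attention()
        except UnsupportedOperationError:
            return None

    # -- prediction ---------------------------------------------------------

    def predict_proba(self, batch: dict) -> np.ndarray:
        logits, _ = self.forward_batch(batch, train=False)
        return nn.softmax_lastaxis(logits.astype(np.float64))

    def predict(self, examples) -> list[PredictionResult]:
        batch = stack_examples(examples)
        probs = self.predict_proba(batch)
        return [PredictionResult.from_probabilities(p) for p in probs]


def build_model(config: ModelConfig | None = None) -> MIPPIModel:
    """Build a freshly initialized model from a configuration."""
    return MIPPIModel(config if config is not None else ModelConfig())


def count_parameters(model: MIPPIModel) -> int:
    return model.count_parameters()


def stack_examples(examples) -> dict:
    """Stack encoded examples into batch arrays for the model."""
    if isinstance(examples, EncodedExample):
        examples = [examples]
    return {
        "ref_tokens": np.stack([e.ref_tokens for e in examples]),
        "mut_tokens": np.stack([e.mut_tokens for e in examples]),
        "partner_tokens": np.stack([e.partner_tokens for e in examples]),
        "ref_pssm": np.stack([e.ref_pssm for e in examples]).astype(F32),
        "mut_pssm": np.stack([e.mut_pssm for e in examples]).astype(F32),
        "partner_pssm": np.stack([e.partner_pssm for e in examples]).astype(F32),
        "ref_mask": np.stack([e.ref_mask for e in examples]),
        "mut_mask": np.stack([e.mut_mask for e in examples]),
        "partner_mask": np.stack([e.partner_mask for e in examples]),
    }


def forward(model: MIPPIModel, example: EncodedExample) -> PredictionResult:
    """Predict a single encoded example (dropout disabled)."""
    return model.predict([example])[0]


def export_attention(model: MIPPIModel, example: EncodedExample,
                     sequence: str = "partner") -> list[AttentionMap]:
    """Export the last self-attention layer's weights for one input.

    One map per head; rows and columns at padded positions are
    discarded, and ``positions`` records the surviving 1-based residue
    indices.
    """
    if model.config.encoder_substitute != "transformer":
        raise UnsupportedOperationError(
            "attention export requires transformer encoder blocks"
        )
    batch = stack_examples([example])
    model.forward_batch(batch, train=False)
    if sequence == "partner":
        if model.partner_branch is None:
            raise UnsupportedOperationError("model was built without a partner branch")
        attn = model._attn_partner
        mask = example.partner_mask
    elif sequence == "ref":
        attn = model._attn_ref
        mask = example.ref_mask
    elif sequence == "mut":
        attn = model._attn_mut
        mask = example.mut_mask
    else:
        raise ValueError(f"unknown sequence channel: {sequence!r}")
    keep = np.flatnonzero(mask)
    positions = keep + 1
    layer = model.config.n_encoder_blocks_per_branch - 1
    maps = []
    for h in range(model.config.n_heads):
        sub = attn[0, h][np.ix_(keep, keep)]
        maps.append(AttentionMap(layer=layer, head=h + 1,
                                 matrix=np.asarray(sub, dtype=np.float64),
                                 positions=positions))
    return maps


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: MIPPIModel, path: str | Path) -> None:
    """Save weights (.npz) and the config snapshot (.json) side by side."""
    path = Path(path)
    arrays = {p.name: p.v for p in model.params()}
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(asdict(model.config), indent=2))


def load_checkpoint(path: str | Path) -> MIPPIModel:
    path = Path(path)
    config = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = MIPPIModel(config)
    with np.load(path.with_suffix(".npz")) as data:
        for p in model.params():
            p.v[...] = data[p.name]
    return model
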