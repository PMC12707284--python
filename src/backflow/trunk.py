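"""The three-track trunk: single, pair and rigid-frame representations.

One initial triangle block (triangle multiplicative updates + triangle
attention) runs on the backbone-derived pair features; because those features
never depend on the sequence state or flow time, its output is computed once
per backbone and cached across all sampling steps.  The main blocks then
update the single representation with gated attention under a pair-derived
bias, refine the pair representation with triangle multiplicative updates,
and update single + rigid frames with invariant point attention, ending in a
per-position 20-way logit head.

All residual branches end in zero-initialised output projections, so a fresh
model is an exact identity on its inputs and emits the uniform distribution.
Geometry enters only through distances, frame-local vectors and IPA, making
the logits invariant to global rigid motions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Parameter, Tensor, concatenate, softmax, stack
from .backbone_io import BackboneStructure, RigidFrames, build_frames
from .featurize import (FeatureBundle, FeaturizeConfig, featurize,
                        pair_features, single_features)
from .flow import FlowState
from .nn import LayerNorm, Linear, Module, Transition

__all__ = [
    "TrunkConfig",
    "TriangleMultiplicativeUpdate",
    "TriangleAttention",
    "TriangleBlock",
    "GatedAttentionPairBias",
    "InvariantPointAttention",
    "FrameTensors",
    "TrunkModel",
]


@dataclass(frozen=True)
class TrunkConfig:
    """Desk-scale hyperparameters (the published description fixes none)."""

    n_blocks: int = 4
    d_single: int = 128
    d_pair: int = 64
    n_heads: int = 4
    n_ipa_points: int = 4
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_blocks, self.d_single, self.d_pair, self.n_heads, self.n_ipa_points) < 1:
            raise ValueError("all trunk dimensions must be positive")
        if self.d_single % self.n_heads:
            raise ValueError("d_single must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def toy(cls, seed: int = 0) -> "TrunkConfig":
        """The configuration used for toy-world training and fast inference."""
        return cls(n_blocks=2, d_single=64, d_pair=32, n_heads=4, n_ipa_points=4, seed=seed)


def _check_square(pair: Tensor) -> int:
    if pair.ndim != 3 or pair.shape[0] != pair.shape[1]:
        raise ValueError(f"pair representation must be (L, L, d); got {pair.shape}")
    return pair.shape[0]


class TriangleMultiplicativeUpdate(Module):
    """Gated triangle multiplicative update (outgoing or incoming edges).

    outgoing: s_ij = sum_k a_ik * b_jk ; incoming: s_ij = sum_k a_ki * b_kj,
    channel-wise, with sigmoid gates on a, b and on the residual output.
    """

    def __init__(self, d_pair: int, direction: str, rng: np.random.Generator,
                 channels: int | None = None):
        if direction not in ("outgoing", "incoming"):
            raise ValueError("direction must be 'outgoing' or 'incoming'")
        self.direction = direction
        c = channels or max(d_pair // 2, 8)
        self.norm_in = LayerNorm(d_pair)
        self.lin_a = Linear(d_pair, c, rng)
        self.gate_a = Linear(d_pair, c, rng)
        self.lin_b = Linear(d_pair, c, rng)
        self.gate_b = Linear(d_pair, c, rng)
        self.norm_mid = LayerNorm(c)
        self.lin_out = Linear(c, d_pair, init="zero")
        self.gate_out = Linear(d_pair, d_pair, rng)

    def __call__(self, pair: Tensor) -> Tensor:
        _check_square(pair)
        z = self.norm_in(pair)
        a = self.gate_a(z).sigmoid() * self.lin_a(z)   # (L, L, c)
        b = self.gate_b(z).sigmoid() * self.lin_b(z)
        at = a.transpose(2, 0, 1)                       # (c, L, L)
        bt = b.transpose(2, 0, 1)
        if self.direction == "outgoing":
            s = at @ bt.swapaxes(-1, -2)                # sum_k a_ik b_jk
        else:
            s = at.swapaxes(-1, -2) @ bt                # sum_k a_ki b_kj
        s = s.transpose(1, 2, 0)                        # (L, L, c)
        delta = self.gate_out(z).sigmoid() * self.lin_out(self.norm_mid(s))
        return pair + delta


class TriangleAttention(Module):
    """Axial attention over pair rows (starting node) or columns (ending node)."""

    def __init__(self, d_pair: int, n_heads: int, node: str, rng: np.random.Generator):
        if node not in ("starting", "ending"):
            raise ValueError("node must be 'starting' or 'ending'")
        self.node = node
        self.n_heads = n_heads
        self.d_head = max(d_pair // n_heads, 8)
        hd = n_heads * self.d_head
        self.norm = LayerNorm(d_pair)
        self.to_q = Linear(d_pair, hd, rng, bias=False)
        self.to_k = Linear(d_pair, hd, rng, bias=False)
        self.to_v = Linear(d_pair, hd, rng, bias=False)
        self.to_bias = Linear(d_pair, n_heads, rng, bias=False)
        self.gate = Linear(d_pair, hd, rng)
        self.out = Linear(hd, d_pair, init="zero")
        self._chunk_elems = 4_000_000  # bound on the (chunk, h, L, L) logit tensor

    def __call__(self, pair: Tensor) -> Tensor:
        _check_square(pair)
        if self.node == "ending":
            delta = self._attend(pair.swapaxes(0, 1)).swapaxes(0, 1)
        else:
            delta = self._attend(pair)
        return pair + delta

    def _attend(self, pair: Tensor) -> Tensor:
        L = pair.shape[0]
        h, dh = self.n_heads, self.d_head
        z = self.norm(pair)
        q = self.to_q(z).reshape(L, L, h, dh) * (1.0 / np.sqrt(dh))
        k = self.to_k(z).reshape(L, L, h, dh)
        v = self.to_v(z).reshape(L, L, h, dh)
        bias = self.to_bias(z).transpose(2, 0, 1).expand_dims(0)  # (1, h, L, L)
        k2 = k.transpose(0, 2, 3, 1)                              # (L, h, dh, L)
        v2 = v.transpose(0, 2, 1, 3)                              # (L, h, L, dh)
        # attention over the third residue; rows processed in chunks to bound
        # the (chunk, h, L, L) logit tensor at long lengths
        chunk = max(1, int(self._chunk_elems // max(h * L * L, 1)))
        outs = []
        for s in range(0, L, chunk):
            e = min(s + chunk, L)
            qc = q[s:e].transpose(0, 2, 1, 3)                     # (c, h, L, dh)
            logits = qc @ k2[s:e] + bias                          # (c, h, L, L)
            att = softmax(logits, axis=-1)
            outs.append(att @ v2[s:e])                            # (c, h, L, dh)
        o = concatenate(outs, axis=0).transpose(0, 2, 1, 3).reshape(L, L, h * dh)
        return self.out(self.gate(z).sigmoid() * o)


class TriangleBlock(Module):
    """The initial pair-only block whose output is cached across sampling steps."""

    def __init__(self, d_pair: int, n_heads: int, rng: np.random.Generator):
        self.mult_out = TriangleMultiplicativeUpdate(d_pair, "outgoing", rng)
        self.mult_in = TriangleMultiplicativeUpdate(d_pair, "incoming", rng)
        self.att_start = TriangleAttention(d_pair, n_heads, "starting", rng)
        self.att_end = TriangleAttention(d_pair, n_heads, "ending", rng)
        self.transition = Transition(d_pair, 2, rng)

    def __call__(self, pair: Tensor) -> Tensor:
        pair = self.mult_out(pair)
        pair = self.mult_in(pair)
        pair = self.att_start(pair)
        pair = self.att_end(pair)
        return self.transition(pair)


class GatedAttentionPairBias(Module):
    """Multi-head attention on the single track with an additive pair bias."""

    def __init__(self, d_single: int, d_pair: int, n_heads: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.d_head = d_single // n_heads
        hd = n_heads * self.d_head
        self.norm_s = LayerNorm(d_single)
        self.norm_p = LayerNorm(d_pair)
        self.to_q = Linear(d_single, hd, rng, bias=False)
        self.to_k = Linear(d_single, hd, rng, bias=False)
        self.to_v = Linear(d_single, hd, rng, bias=False)
        self.to_bias = Linear(d_pair, n_heads, rng, bias=False)
        self.gate = Linear(d_single, hd, rng)
        self.out = Linear(hd, d_single, init="zero")

    def __call__(self, single: Tensor, pair: Tensor) -> Tensor:
        L = single.shape[0]
        h, dh = self.n_heads, self.d_head
        s = self.norm_s(single)
        q = self.to_q(s).reshape(L, h, dh).transpose(1, 0, 2) * (1.0 / np.sqrt(dh))
        k = self.to_k(s).reshape(L, h, dh).transpose(1, 2, 0)   # (h, dh, L)
        v = self.to_v(s).reshape(L, h, dh).transpose(1, 0, 2)   # (h, L, dh)
        bias = self.to_bias(self.norm_p(pair)).transpose(2, 0, 1)  # (h, L, L)
        att = softmax(q @ k + bias, axis=-1)                    # (h, L, L)
        o = (att @ v).transpose(1, 0, 2).reshape(L, h * dh)
        delta = self.out(self.gate(s).sigmoid() * o)
        return single + delta


@dataclass
class FrameTensors:
    """Differentiable rigid frames used inside the trunk."""

    rotations: Tensor   # (L, 3, 3)
    translations: Tensor  # (L, 3)

    @classmethod
    def from_frames(cls, frames: RigidFrames) -> "FrameTensors":
        return cls(Tensor(frames.rotations), Tensor(frames.translations))

    def to_frames(self) -> RigidFrames:
        return RigidFrames(rotations=self.rotations.data.copy(),
                           translations=self.translations.data.copy())

    def apply(self, points: Tensor) -> Tensor:
        """Map local points (L, n, 3) to global coordinates per residue."""
        return points @ self.rotations.swapaxes(-1, -2) + self.translations.expand_dims(1)

    def invert_apply(self, points: Tensor) -> Tensor:
        """Map global points (L, n, 3) into each residue's local frame."""
        return (points - self.translations.expand_dims(1)) @ self.rotations


def _small_rotation(omega: Tensor) -> Tensor:
    """Rotation matrices from the quaternion (1, wx, wy, wz), normalised.

    Exact identity at omega = 0, smooth and orthonormal everywhere.
    """
    a, b, c = omega[:, 0], omega[:, 1], omega[:, 2]
    n2 = 1.0 + a * a + b * b + c * c
    row0 = stack([1.0 + a * a - b * b - c * c, 2.0 * (a * b - c), 2.0 * (a * c + b)], axis=-1)
    row1 = stack([2.0 * (a * b + c), 1.0 - a * a + b * b - c * c, 2.0 * (b * c - a)], axis=-1)
    row2 = stack([2.0 * (a * c - b), 2.0 * (b * c + a), 1.0 - a * a - b * b + c * c], axis=-1)
    return stack([row0, row1, row2], axis=1) / n2.expand_dims(-1).expand_dims(-1)


class InvariantPointAttention(Module):
    """IPA: attention scored in global coordinates from frame-local points.

    Scalar query-key terms, a pair bias, and squared distances between
    frame-mapped query/key points combine into the attention logits; the
    output mixes scalar values, attention-weighted pair features and value
    points mapped back into the query residue's local frame (plus their
    norms), so the update is invariant to global rigid motions.  A small
    zero-initialised head then composes a per-residue rigid update onto the
    frames.
    """

    def __init__(self, d_single: int, d_pair: int, n_heads: int, n_points: int,
                 rng: np.random.Generator):
        self.n_heads = n_heads
        self.n_points = n_points
        self.d_head = d_single // n_heads
        h, dh, P = n_heads, self.d_head, n_points
        self.norm_s = LayerNorm(d_single)
        self.norm_p = LayerNorm(d_pair)
        self.to_q = Linear(d_single, h * dh, rng, bias=False)
        self.to_k = Linear(d_single, h * dh, rng, bias=False)
        self.to_v = Linear(d_single, h * dh, rng, bias=False)
        self.to_qpts = Linear(d_single, h * P * 3, rng, bias=False)
        self.to_kpts = Linear(d_single, h * P * 3, rng, bias=False)
        self.to_vpts = Linear(d_single, h * P * 3, rng, bias=False)
        self.to_bias = Linear(d_pair, n_heads, rng, bias=False)
        # softplus(gamma_raw) = per-head weight of the point term; init ~ 1
        self.gamma_raw = Parameter(np.full(n_heads, np.log(np.e - 1.0)))
        self.out = Linear(h * dh + h * d_pair + h * P * 4, d_single, init="zero")
        self.norm_upd = LayerNorm(d_single)
        self.frame_head = Linear(d_single, 6, init="zero")

    def __call__(self, single: Tensor, pair: Tensor, frames: FrameTensors
                 ) -> tuple[Tensor, FrameTensors]:
        L = single.shape[0]
        h, dh, P = self.n_heads, self.d_head, self.n_points
        d_pair = pair.shape[-1]
        s = self.norm_s(single)
        z = self.norm_p(pair)

        w_l = 1.0 / np.sqrt(3.0)
        w_c = np.sqrt(2.0 / (9.0 * P))
        q = self.to_q(s).reshape(L, h, dh).transpose(1, 0, 2) * (1.0 / np.sqrt(dh))
        k = self.to_k(s).reshape(L, h, dh).transpose(1, 2, 0)
        v = self.to_v(s).reshape(L, h, dh).transpose(1, 0, 2)
        scalar_logits = q @ k                                     # (h, L, L)
        bias = self.to_bias(z).transpose(2, 0, 1)                 # (h, L, L)

        gq = frames.apply(self.to_qpts(s).reshape(L, h * P, 3)).reshape(L, h, P, 3)
        gk = frames.apply(self.to_kpts(s).reshape(L, h * P, 3)).reshape(L, h, P, 3)
        gv = frames.apply(self.to_vpts(s).reshape(L, h * P, 3))   # (L, hP, 3)
        gqt = gq.transpose(1, 2, 0, 3)                            # (h, P, L, 3)
        gkt = gk.transpose(1, 2, 0, 3)
        cross = gqt @ gkt.swapaxes(-1, -2)                        # (h, P, L, L)
        qq = (gqt * gqt).sum(axis=-1)                             # (h, P, L)
        kk = (gkt * gkt).sum(axis=-1)
        d2 = (qq.expand_dims(3) + kk.expand_dims(2) - 2.0 * cross).sum(axis=1)  # (h, L, L)
        softplus = (1.0 + self.gamma_raw.exp()).log()
        gamma = softplus.reshape(h, 1, 1)
        logits = w_l * (scalar_logits + bias) - 0.5 * w_c * gamma * d2
        att = softmax(logits, axis=-1)                            # (h, L, L)

        o_scalar = (att @ v).transpose(1, 0, 2).reshape(L, h * dh)
        o_pair = (att.transpose(1, 0, 2) @ z).reshape(L, h * d_pair)
        gvh = gv.reshape(L, h, P * 3).transpose(1, 0, 2)          # (h, L, P3)
        o_pts_global = (att @ gvh).transpose(1, 0, 2).reshape(L, h * P, 3)
        o_pts_local = frames.invert_apply(o_pts_global)           # (L, hP, 3)
        o_norm = ((o_pts_local * o_pts_local).sum(axis=-1) + 1e-8).sqrt()
        o = concatenate(
            [o_scalar, o_pair, o_pts_local.reshape(L, h * P * 3), o_norm], axis=-1
        )
        single = single + self.out(o)

        upd = self.frame_head(self.norm_upd(single))              # (L, 6)
        delta_t, omega = upd[:, :3], upd[:, 3:]
        r_delta = _small_rotation(omega)
        new_rot = frames.rotations @ r_delta
        new_trans = frames.translations + (
            delta_t.expand_dims(1) @ frames.rotations.swapaxes(-1, -2)
        ).reshape(L, 3)
        return single, FrameTensors(new_rot, new_trans)


@dataclass
class PairCache:
    """Sequence-independent pair embeddings memoised per backbone.

    ``initial`` is the cached output of the initial triangle block; ``per_block``
    holds the (pre-update, post-update) pair tensors consumed by each main block.
    """

    initial: np.ndarray
    per_block: list = field(default_factory=list)


class MainBlock(Module):
    def __init__(self, cfg: TrunkConfig, rng: np.random.Generator):
        self.attn = GatedAttentionPairBias(cfg.d_single, cfg.d_pair, cfg.n_heads, rng)
        self.transition = Transition(cfg.d_single, 2, rng)
        self.mult_out = TriangleMultiplicativeUpdate(cfg.d_pair, "outgoing", rng)
        self.mult_in = TriangleMultiplicativeUpdate(cfg.d_pair, "incoming", rng)
        self.ipa = InvariantPointAttention(cfg.d_single, cfg.d_pair, cfg.n_heads,
                                           cfg.n_ipa_points, rng)

    def update_pair(self, pair: Tensor) -> Tensor:
        return self.mult_in(self.mult_out(pair))

    def __call__(self, single: Tensor, pair: Tensor, frames: FrameTensors,
                 pair_post: Tensor | None = None):
        single = self.attn(single, pair)
        single = self.transition(single)
        pair = self.update_pair(pair) if pair_post is None else pair_post
        single, frames = self.ipa(single, pair, frames)
        return single, pair, frames


class TrunkModel(Module):
    """Full trunk: feature embeddings, cached triangle block, main blocks, logit head."""

    def __init__(self, config: TrunkConfig | None = None,
                 feat_config: FeaturizeConfig | None = None):
        self.config = config or TrunkConfig()
        self.feat_config = feat_config or FeaturizeConfig()
        rng = np.random.default_rng(np.random.SeedSequence([self.config.seed, 0x7472756E]))
        self.embed_single = Linear(self.feat_config.d_single, self.config.d_single, rng)
        self.embed_pair = Linear(self.feat_config.d_pair, self.config.d_pair, rng)
        self.init_block = TriangleBlock(self.config.d_pair, self.config.n_heads, rng)
        self.blocks = [MainBlock(self.config, rng) for _ in range(self.config.n_blocks)]
        self.head_norm = LayerNorm(self.config.d_single)
        self.head = Linear(self.config.d_single, 20, init="zero")

    # -- caching ----------------------------------------------------------
    def pair_embedding(self, pair_feats: np.ndarray) -> Tensor:
        """Initial triangle block applied to embedded backbone pair features."""
        return self.init_block(self.embed_pair(Tensor(pair_feats)))

    def cache_pair(self, bb: BackboneStructure,
                   pair_feats: np.ndarray | None = None) -> "PairCache":
        """Backbone-only cached pair embeddings (sequence- and time-independent).

        The pair track never reads the single track, so beyond the initial
        triangle block the per-block pair updates are also a pure function of
        the backbone and are memoised here for sampling.
        """
        if pair_feats is None:
            pair_feats = pair_features(bb, self.feat_config)
        with ad.no_grad():
            initial = self.pair_embedding(pair_feats)
            pair = initial
            per_block = []
            for block in self.blocks:
                post = block.update_pair(pair)
                per_block.append((pair.data, post.data))
                pair = post
        return PairCache(initial=initial.data, per_block=per_block)

    # -- forward ----------------------------------------------------------
    def forward(self, feats: FeatureBundle, frames: RigidFrames,
                cached_pair: "PairCache | np.ndarray | None" = None) -> Tensor:
        """Per-position 20-way logits.

        ``cached_pair`` may be a full :class:`PairCache` (fast sampling path),
        the bare initial triangle-block embedding as an array (pair updates
        recomputed), or ``None`` (everything recomputed; the training path).
        All three produce bit-identical logits.
        """
        single = self.embed_single(Tensor(feats.single))
        track = None
        if isinstance(cached_pair, PairCache):
            track = cached_pair
            pair = Tensor(track.initial)
        elif cached_pair is not None:
            pair = Tensor(np.asarray(cached_pair))
        else:
            pair = self.pair_embedding(feats.pair)
        ft = FrameTensors.from_frames(frames)
        for i, block in enumerate(self.blocks):
            post = Tensor(track.per_block[i][1]) if track is not None else None
            single, pair, ft = block(single, pair, ft, pair_post=post)
            if not np.all(np.isfinite(single.data)):
                raise FloatingPointError(f"non-finite activations after block {i}")
        logits = self.head(self.head_norm(single))
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite logits")
        return logits

    def logits(self, bb: BackboneStructure, state: FlowState,
               cached: "PairCache | np.ndarray | None" = None,
               noise_level: str = "clean") -> np.ndarray:
        """Inference-mode per-position logits over the 20 amino acids."""
        if cached is not None:
            sf = single_features(bb, state, noise_level, self.feat_config)
            feats = FeatureBundle(single=sf, pair=np.zeros((len(bb), len(bb), 0)))
        else:
            feats = featurize(bb, state, noise_level, self.feat_config)
        frames = build_frames(bb)
        with ad.no_grad():
            return self.forward(feats, frames, cached_pair=cached).data

    # -- checkpointing ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **{k.replace(".", "/"): v for k, v in self.state_dict().items()})
        meta = {"trunk": self.config.__dict__, "features": self.feat_config.__dict__}
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, path: str | Path) -> "TrunkModel":
        path = Path(path)
        meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
        model = cls(TrunkConfig(**meta["trunk"]), FeaturizeConfig(**meta["features"]))
        with np.load(path) as data:
            model.load_state_dict({k.replace("/", "."): data[k] for k in data.files})
        return model
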