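"""Trunk network: residual identities, equivariances, caching, IPA geometry."""

import numpy as np
import pytest

from backflow import autodiff as ad
from backflow.autodiff import Tensor
from backflow.backbone_io import build_frames
from backflow.featurize import featurize
from backflow.flow import FlowState, corrupt
from backflow.synthetic_data import make_toy_backbone, make_toy_complex
from backflow.trunk import (FrameTensors, GatedAttentionPairBias,
                            InvariantPointAttention, TriangleAttention,
                            TriangleBlock, TriangleMultiplicativeUpdate,
                            TrunkConfig, TrunkModel)
from backflow.utils import MASK_TOKEN
from conftest import random_rigid, rigid_move

rng = np.random.default_rng(21)


def _mask_state(n):
    return FlowState(np.full(n, MASK_TOKEN), t=0.0)


class TestResidualIdentities:
    """Every residual branch ends in a zero-init projection: exact identity."""

    @pytest.mark.parametrize("make", [
        lambda: TriangleMultiplicativeUpdate(8, "outgoing", rng),
        lambda: TriangleMultiplicativeUpdate(8, "incoming", rng),
        lambda: TriangleAttention(8, 2, "starting", rng),
        lambda: TriangleAttention(8, 2, "ending", rng),
    ])
    def test_fresh_pair_ops_are_identities(self, make):
        op = make()
        pair = Tensor(rng.normal(size=(5, 5, 8)))
        out = op(pair)
        np.testing.assert_array_equal(out.data, pair.data)

    def test_fresh_attention_and_ipa_identity_on_single(self):
        attn = GatedAttentionPairBias(16, 8, 4, rng)
        single = Tensor(rng.normal(size=(6, 16)))
        pair = Tensor(rng.normal(size=(6, 6, 8)))
        np.testing.assert_array_equal(attn(single, pair).data, single.data)
        ipa = InvariantPointAttention(16, 8, 4, 2, rng)
        frames = FrameTensors(Tensor(np.tile(np.eye(3), (6, 1, 1))),
                              Tensor(rng.normal(size=(6, 3))))
        s_out, f_out = ipa(single, pair, frames)
        np.testing.assert_array_equal(s_out.data, single.data)
        np.testing.assert_allclose(f_out.rotations.data, frames.rotations.data, atol=1e-15)
        np.testing.assert_allclose(f_out.translations.data, frames.translations.data,
                                   atol=1e-15)

    def test_fresh_model_emits_uniform_distribution(self, hairpin36):
        model = TrunkModel(TrunkConfig.toy(seed=0))
        logits = model.logits(hairpin36, _mask_state(36))
        assert np.abs(logits).max() == 0.0


def _randomize(module, scale=0.1, seed=5):
    r = np.random.default_rng(seed)
    for _, p in module.named_parameters():
        p.data = p.data + r.normal(0, scale, p.data.shape)
    return module


class TestTriangleMultiplicative:
    def test_outgoing_matches_bruteforce_k_sum(self):
        op = _randomize(TriangleMultiplicativeUpdate(6, "outgoing", rng, channels=3))
        pair = Tensor(rng.normal(size=(4, 4, 6)))
        out = op(pair)
        # brute-force enumeration of s_ij = sum_k a_ik * b_jk from the module's
        # own gated projections, bypassing the vectorised matmul path
        with ad.no_grad():
            z = op.norm_in(pair)
            a = (op.gate_a(z).sigmoid() * op.lin_a(z)).data
            b = (op.gate_b(z).sigmoid() * op.lin_b(z)).data
            s = np.zeros((4, 4, 3))
            for i in range(4):
                for j in range(4):
                    for k in range(4):
                        s[i, j] += a[i, k] * b[j, k]
            delta = (op.gate_out(z).sigmoid() * op.lin_out(op.norm_mid(Tensor(s)))).data
        np.testing.assert_allclose(out.data, pair.data + delta, atol=1e-12)

    def test_incoming_matches_bruteforce_k_sum(self):
        op = _randomize(TriangleMultiplicativeUpdate(6, "incoming", rng, channels=3))
        pair = Tensor(rng.normal(size=(4, 4, 6)))
        out = op(pair)
        with ad.no_grad():
            z = op.norm_in(pair)
            a = (op.gate_a(z).sigmoid() * op.lin_a(z)).data
            b = (op.gate_b(z).sigmoid() * op.lin_b(z)).data
            s = np.einsum("kic,kjc->ijc", a, b)
            delta = (op.gate_out(z).sigmoid() * op.lin_out(op.norm_mid(Tensor(s)))).data
        np.testing.assert_allclose(out.data, pair.data + delta, atol=1e-12)

    @pytest.mark.parametrize("direction", ["outgoing", "incoming"])
    def test_row_col_permutation_equivariance(self, direction):
        op = _randomize(TriangleMultiplicativeUpdate(8, direction, rng))
        pair = Tensor(rng.normal(size=(5, 5, 8)))
        perm = np.random.default_rng(2).permutation(5)
        out = op(pair).data
        out_p = op(Tensor(pair.data[perm][:, perm])).data
        np.testing.assert_allclose(out_p, out[perm][:, perm], atol=1e-10)

    def test_degenerate_and_invalid_shapes(self):
        op = _randomize(TriangleMultiplicativeUpdate(8, "outgoing", rng))
        out = op(Tensor(rng.normal(size=(1, 1, 8))))
        assert np.all(np.isfinite(out.data))
        with pytest.raises(ValueError, match=r"\(L, L"):
            op(Tensor(rng.normal(size=(3, 4, 8))))


class TestTriangleAttention:
    @pytest.mark.parametrize("node", ["starting", "ending"])
    def test_permutation_equivariance(self, node):
        op = _randomize(TriangleAttention(8, 2, node, rng))
        pair = Tensor(rng.normal(size=(5, 5, 8)))
        perm = np.random.default_rng(3).permutation(5)
        out = op(pair).data
        out_p = op(Tensor(pair.data[perm][:, perm])).data
        np.testing.assert_allclose(out_p, out[perm][:, perm], atol=1e-10)

    def test_chunked_rows_match_unchunked(self):
        op = _randomize(TriangleAttention(8, 2, "starting", rng))
        pair = Tensor(rng.normal(size=(7, 7, 8)))
        full = op(pair).data
        op._chunk_elems = 2 * 2 * 7 * 7  # forces 2-row chunks
        chunked = op(pair).data
        np.testing.assert_allclose(chunked, full, atol=1e-12)


class TestGatedAttention:
    def test_uniform_inputs_give_uniform_attention(self):
        op = _randomize(GatedAttentionPairBias(16, 8, 4, rng))
        L = 6
        single = Tensor(np.tile(rng.normal(size=(1, 16)), (L, 1)))
        pair = Tensor(np.tile(rng.normal(size=(1, 1, 8)), (L, L, 1)))
        out = op(single, pair).data
        # identical rows + constant bias -> softmax weights 1/L everywhere ->
        # every output row identical
        np.testing.assert_allclose(out, np.tile(out[:1], (L, 1)), atol=1e-12)

    def test_permutation_equivariance(self):
        op = _randomize(GatedAttentionPairBias(16, 8, 4, rng))
        single = Tensor(rng.normal(size=(6, 16)))
        pair = Tensor(rng.normal(size=(6, 6, 8)))
        perm = np.random.default_rng(4).permutation(6)
        out = op(single, pair).data
        out_p = op(Tensor(single.data[perm]), Tensor(pair.data[perm][:, perm])).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


class TestIPA:
    def _setup(self, L=7):
        ipa = _randomize(InvariantPointAttention(16, 8, 4, 2, rng))
        single = Tensor(rng.normal(size=(L, 16)))
        pair = Tensor(rng.normal(size=(L, L, 8)))
        bb = make_toy_backbone(L + 3, "hairpin", seed=2)
        fr = build_frames(bb)
        frames = FrameTensors(Tensor(fr.rotations[:L]), Tensor(fr.translations[:L]))
        return ipa, single, pair, frames

    def test_rigid_motion_invariance_and_frame_equivariance(self):
        ipa, single, pair, frames = self._setup()
        s0, f0 = ipa(single, pair, frames)
        rot, trans = random_rigid(np.random.default_rng(8))
        moved = FrameTensors(
            Tensor(rot @ frames.rotations.data),
            Tensor(frames.translations.data @ rot.T + trans),
        )
        s1, f1 = ipa(single, pair, moved)
        np.testing.assert_allclose(s1.data, s0.data, atol=1e-9)
        np.testing.assert_allclose(f1.rotations.data, rot @ f0.rotations.data, atol=1e-9)
        np.testing.assert_allclose(f1.translations.data,
                                   f0.translations.data @ rot.T + trans, atol=1e-8)

    def test_zero_point_weight_and_bias_reduce_to_plain_attention(self):
        # gamma -> 0 kills the point-distance term, zero bias kills the pair
        # term, and ablating the point output slice removes the remaining
        # frame-dependent path: the update must then ignore the frames
        ipa, single, pair, frames = self._setup()
        ipa.gamma_raw.data[:] = -40.0              # softplus ~ 4e-18
        ipa.to_bias.weight.data[:] = 0.0
        h, dh, P = ipa.n_heads, ipa.d_head, ipa.n_points
        ipa.out.weight.data[h * dh + h * 8:, :] = 0.0  # point + norm slice
        s0, _ = ipa(single, pair, frames)
        other = FrameTensors(Tensor(np.tile(np.eye(3), (7, 1, 1))),
                             Tensor(np.arange(21, dtype=float).reshape(7, 3)))
        s1, _ = ipa(single, pair, other)
        np.testing.assert_allclose(s0.data, s1.data, atol=1e-10)

    def test_single_residue_is_finite(self):
        ipa, _, _, _ = self._setup()
        single = Tensor(rng.normal(size=(1, 16)))
        pair = Tensor(rng.normal(size=(1, 1, 8)))
        frames = FrameTensors(Tensor(np.eye(3)[None]), Tensor(np.zeros((1, 3))))
        s, f = ipa(single, pair, frames)
        assert np.all(np.isfinite(s.data))
        assert f.rotations.data.shape == (1, 3, 3)

    def test_updated_frames_remain_valid_rotations(self):
        ipa, single, pair, frames = self._setup()
        ipa.frame_head.weight.data[:] = rng.normal(0, 0.3, ipa.frame_head.weight.data.shape)
        _, f = ipa(single, pair, frames)
        f.to_frames()  # validates orthonormality + det via RigidFrames invariants


class TestTrunkModel:
    def test_cache_is_sequence_and_time_independent(self, toy_model, hairpin36):
        c1 = toy_model.cache_pair(hairpin36)
        import dataclasses
        other = dataclasses.replace(hairpin36, sequence="A" * 36)
        c2 = toy_model.cache_pair(other)
        np.testing.assert_array_equal(c1.initial, c2.initial)

    def test_cache_sensitive_to_coordinates(self, toy_model, hairpin36):
        import dataclasses
        ca = hairpin36.coords_CA.copy()
        ca[5] += 1.0
        moved = dataclasses.replace(hairpin36, coords_CA=ca)
        c1 = toy_model.cache_pair(hairpin36)
        c2 = toy_model.cache_pair(moved)
        assert np.abs(c1.initial - c2.initial).max() > 0

    def test_cached_and_recomputed_logits_bit_identical(self, toy_model, hairpin36):
        state = corrupt(hairpin36.sequence, 0.5, seed=3)
        cache = toy_model.cache_pair(hairpin36)
        fast = toy_model.logits(hairpin36, state, cached=cache)
        semi = toy_model.logits(hairpin36, state, cached=cache.initial)
        feats = featurize(hairpin36, state, "clean", toy_model.feat_config)
        with ad.no_grad():
            full = toy_model.forward(feats, build_frames(hairpin36)).data
        assert np.array_equal(fast, semi)
        assert np.array_equal(fast, full)

    def test_se3_invariance_of_logits(self, toy_model, hairpin36):
        state = _mask_state(36)
        base = toy_model.logits(hairpin36, state, cached=toy_model.cache_pair(hairpin36))
        r = np.random.default_rng(11)
        for _ in range(3):
            rot, trans = random_rigid(r)
            moved = rigid_move(hairpin36, rot, trans)
            out = toy_model.logits(moved, state, cached=toy_model.cache_pair(moved))
            assert np.abs(out - base).max() < 1e-4

    def test_residue_permutation_equivariance(self, toy_model, hairpin36):
        state = corrupt(hairpin36.sequence, 0.5, seed=9)
        feats = featurize(hairpin36, state, "clean", toy_model.feat_config)
        frames = build_frames(hairpin36)
        with ad.no_grad():
            base = toy_model.forward(feats, frames).data
        perm = np.random.default_rng(13).permutation(36)
        from backflow.featurize import FeatureBundle
        from backflow.backbone_io import RigidFrames
        pfeats = FeatureBundle(single=feats.single[perm],
                               pair=feats.pair[perm][:, perm])
        pframes = RigidFrames(rotations=frames.rotations[perm],
                              translations=frames.translations[perm])
        with ad.no_grad():
            out = toy_model.forward(pfeats, pframes).data
        np.testing.assert_allclose(out, base[perm], atol=1e-9)

    def test_nonfinite_activation_reports_block(self, toy_model, hairpin36):
        import copy
        broken = TrunkModel(toy_model.config, toy_model.feat_config)
        broken.load_state_dict(toy_model.state_dict())
        broken.blocks[1].attn.out.weight.data[:] = np.inf
        with pytest.raises(FloatingPointError, match="block 1"):
            broken.logits(hairpin36, _mask_state(36))

    def test_checkpoint_roundtrip(self, toy_model, hairpin36, tmp_path):
        p = tmp_path / "model.npz"
        toy_model.save(p)
        loaded = TrunkModel.load(p)
        state = _mask_state(36)
        np.testing.assert_array_equal(loaded.logits(hairpin36, state),
                                      toy_model.logits(hairpin36, state))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrunkConfig(d_single=30, n_heads=4)
        with pytest.raises(ValueError):
            TrunkConfig(n_blocks=0)
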