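"""Structure parsing, rigid frames, noise injection, interfaces and crops."""

import numpy as np
import pytest

from backflow.backbone_io import (BackboneStructure, add_backbone_noise,
                                  build_frames, crop_example, detect_interface,
                                  read_backbone, write_pdb)
from backflow.synthetic_data import make_toy_backbone, make_toy_complex
from conftest import random_rigid, rigid_move

PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.300   1.540   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       4.000   2.800   0.200  1.00  0.00           C
ATOM      7  C   GLY A   2       5.500   2.600   0.300  1.00  0.00           C
ATOM      8  O   GLY A   2       6.100   1.600   0.700  1.00  0.00           O
ATOM      9  N   VAL A   3       6.100   3.700   0.000  1.00  0.00           N
ATOM     10  CA  VAL A   3       7.500   3.900   0.300  1.00  0.00           C
ATOM     11  C   VAL A   3       8.300   4.700   1.300  1.00  0.00           C
ATOM     12  O   VAL A   3       7.800   5.700   1.800  1.00  0.00           O
END
"""


def _reference_parse(text):
    """Independent line-by-line PDB reader used as the oracle."""
    residues = {}
    for line in text.splitlines():
        if not line.startswith("ATOM"):
            continue
        name = line[12:16].strip()
        chain = line[21]
        resnum = int(line[22:26])
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        residues.setdefault((chain, resnum), {})[name] = xyz
    return residues


class TestReadBackbone:
    def test_three_residue_file(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(PDB_3RES)
        bb = read_backbone(p)
        assert len(bb) == 3
        assert bb.sequence == "AGV"
        assert list(bb.residue_ids) == [1, 2, 3]

    def test_missing_c_drops_residue_with_warning(self, tmp_path):
        text = "\n".join(l for l in PDB_3RES.splitlines() if not l.startswith("ATOM      7"))
        p = tmp_path / "gap.pdb"
        p.write_text(text)
        with pytest.warns(UserWarning, match="dropped 1 residue"):
            bb = read_backbone(p)
        assert len(bb) == 2
        assert bb.sequence == "AV"

    def test_two_chain_complex_matches_reference_parser(self, tmp_path):
        cx, _ = make_toy_complex(10, 12, gap=4.0, seed=3)
        p = tmp_path / "cx.pdb"
        write_pdb(cx, p)
        bb = read_backbone(p)
        ref = _reference_parse(p.read_text())
        assert bb.chains == ["A", "B"]
        assert len(bb) == len(ref) == 22
        for i in range(len(bb)):
            key = (str(bb.chain_ids[i]), int(bb.residue_ids[i]))
            np.testing.assert_allclose(bb.coords_CA[i], ref[key]["CA"], atol=1e-3)

    def test_unreadable_and_empty_inputs(self, tmp_path):
        missing_atoms = tmp_path / "nothing.pdb"
        missing_atoms.write_text("HEADER  EMPTY\nEND\n")
        with pytest.raises(ValueError, match="no residue"):
            read_backbone(missing_atoms)
        with pytest.raises(IndexError):
            p = tmp_path / "toy.pdb"
            p.write_text(PDB_3RES)
            read_backbone(p, model_index=5)


class TestBuildFrames:
    def test_canonical_placement_gives_identity(self):
        bb = BackboneStructure(
            chain_ids=np.array(["A"]), residue_ids=np.array([1]),
            coords_N=np.array([[0.5, 1.2, 0.0]]), coords_CA=np.array([[0.0, 0.0, 0.0]]),
            coords_C=np.array([[1.5, 0.0, 0.0]]), coords_O=np.array([[np.nan] * 3]),
        )
        fr = build_frames(bb)
        np.testing.assert_allclose(fr.rotations[0], np.eye(3), atol=1e-12)
        np.testing.assert_allclose(fr.translations[0], 0.0, atol=1e-12)

    def test_translation_moves_only_translation(self):
        shift = np.array([1.0, 2.0, 3.0])
        bb = BackboneStructure(
            chain_ids=np.array(["A"]), residue_ids=np.array([1]),
            coords_N=np.array([[0.5, 1.2, 0.0]]) + shift,
            coords_CA=np.array([[0.0, 0.0, 0.0]]) + shift,
            coords_C=np.array([[1.5, 0.0, 0.0]]) + shift,
            coords_O=np.array([[np.nan] * 3]),
        )
        fr = build_frames(bb)
        np.testing.assert_allclose(fr.rotations[0], np.eye(3), atol=1e-12)
        np.testing.assert_allclose(fr.translations[0], shift, atol=1e-12)

    def test_random_residues_give_orthonormal_right_handed_frames(self):
        rng = np.random.default_rng(4)
        n = 50
        ca = rng.normal(scale=10, size=(n, 3))
        bb = BackboneStructure(
            chain_ids=np.full(n, "A"), residue_ids=np.arange(n),
            coords_N=ca + rng.normal(scale=1, size=(n, 3)),
            coords_CA=ca,
            coords_C=ca + rng.normal(scale=1, size=(n, 3)),
            coords_O=np.full((n, 3), np.nan),
        )
        fr = build_frames(bb)
        for r in fr.rotations:  # brute-force per-frame check
            np.testing.assert_allclose(r.T @ r, np.eye(3), atol=1e-10)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)

    def test_equivariance_under_rigid_motion(self, hairpin36):
        rng = np.random.default_rng(9)
        rot, trans = random_rigid(rng)
        fr = build_frames(hairpin36)
        fr2 = build_frames(rigid_move(hairpin36, rot, trans))
        np.testing.assert_allclose(fr2.rotations, rot @ fr.rotations, atol=1e-5)
        np.testing.assert_allclose(fr2.translations, fr.translations @ rot.T + trans,
                                   atol=1e-5)

    def test_collinear_backbone_raises_with_residue_index(self):
        bb = BackboneStructure(
            chain_ids=np.array(["A"]), residue_ids=np.array([7]),
            coords_N=np.array([[2.0, 0.0, 0.0]]), coords_CA=np.array([[0.0, 0.0, 0.0]]),
            coords_C=np.array([[1.0, 0.0, 0.0]]), coords_O=np.array([[np.nan] * 3]),
        )
        with pytest.raises(ValueError, match="residue index 0"):
            build_frames(bb)


class TestBackboneNoise:
    def test_sigma_zero_is_identity(self, hairpin36):
        out = add_backbone_noise(hairpin36, 0.0, seed=1)
        np.testing.assert_array_equal(out.coords_CA, hairpin36.coords_CA)

    def test_displacement_sd_matches_sigma(self):
        bb = make_toy_backbone(2500, "helix", seed=0)  # 10,000 atoms
        noisy = add_backbone_noise(bb, 0.2, seed=2)
        disp = np.concatenate([
            (noisy.coords_N - bb.coords_N).ravel(),
            (noisy.coords_CA - bb.coords_CA).ravel(),
            (noisy.coords_C - bb.coords_C).ravel(),
            (noisy.coords_O - bb.coords_O).ravel(),
        ])
        assert disp.std() == pytest.approx(0.2, rel=0.05)

    def test_seed_determinism(self, hairpin36):
        a = add_backbone_noise(hairpin36, 0.2, seed=5)
        b = add_backbone_noise(hairpin36, 0.2, seed=5)
        c = add_backbone_noise(hairpin36, 0.2, seed=6)
        np.testing.assert_array_equal(a.coords_CA, b.coords_CA)
        assert not np.array_equal(a.coords_CA, c.coords_CA)

    def test_metadata_preserved_and_negative_sigma_rejected(self, hairpin36):
        noisy = add_backbone_noise(hairpin36, 0.2, seed=1)
        assert noisy.sequence == hairpin36.sequence
        np.testing.assert_array_equal(noisy.chain_ids, hairpin36.chain_ids)
        with pytest.raises(ValueError):
            add_backbone_noise(hairpin36, -0.1, seed=1)


def _parallel_strands(n=10, spacing=4.0):
    """Two CA-only parallel strands with known inter-chain spacing."""
    ca_a = np.stack([np.arange(n) * 3.8, np.zeros(n), np.zeros(n)], axis=1)
    ca_b = ca_a + np.array([0.0, spacing, 0.0])
    mk = lambda ca: (ca + [0.5, 0.9, 0.0], ca, ca + [-0.5, 0.9, 0.0])
    na, caa, cca = mk(ca_a)
    nb, cab, ccb = mk(ca_b)
    return BackboneStructure(
        chain_ids=np.array(["A"] * n + ["B"] * n),
        residue_ids=np.concatenate([np.arange(n), np.arange(n)]),
        coords_N=np.concatenate([na, nb]),
        coords_CA=np.concatenate([caa, cab]),
        coords_C=np.concatenate([cca, ccb]),
        coords_O=np.full((2 * n, 3), np.nan),
    )


class TestDetectInterface:
    def test_far_apart_chains_give_null(self):
        bb = _parallel_strands(spacing=100.0)
        assert detect_interface(bb, "A", "B", cutoff=5.0, min_residues=1) is None

    def test_close_strands_flag_everything(self):
        bb = _parallel_strands(spacing=4.0)
        ann = detect_interface(bb, "A", "B", cutoff=5.0, min_residues=5)
        assert ann is not None
        # brute-force all-pairs oracle over backbone atoms
        coords, owners = bb.backbone_coords()
        in_a = np.isin(owners, np.nonzero(bb.chain_ids == "A")[0])
        expected = np.zeros(len(bb), dtype=bool)
        for i in np.nonzero(in_a)[0]:
            for j in np.nonzero(~in_a)[0]:
                if np.linalg.norm(coords[i] - coords[j]) <= 5.0:
                    expected[owners[i]] = expected[owners[j]] = True
        np.testing.assert_array_equal(ann.interface_mask, expected)
        assert ann.interface_mask.all()

    def test_min_residue_qualification(self):
        bb = _parallel_strands(n=10, spacing=4.0)
        assert detect_interface(bb, "A", "B", cutoff=5.0, min_residues=11) is None

    def test_symmetry_in_chain_arguments(self):
        bb = _parallel_strands(spacing=4.5)
        a = detect_interface(bb, "A", "B", cutoff=5.0, min_residues=0)
        b = detect_interface(bb, "B", "A", cutoff=5.0, min_residues=0)
        np.testing.assert_array_equal(a.interface_mask, b.interface_mask)

    def test_unknown_chain_raises(self):
        bb = _parallel_strands()
        with pytest.raises(KeyError):
            detect_interface(bb, "A", "Z")


class TestCropExample:
    def test_crop_larger_than_structure_is_identity(self, hairpin36):
        out = crop_example(hairpin36, 100, seed=1)
        assert out.sequence == hairpin36.sequence
        np.testing.assert_array_equal(out.coords_CA, hairpin36.coords_CA)

    def test_contiguous_crop_is_a_window(self):
        bb = make_toy_backbone(10, "helix", seed=2)
        out = crop_example(bb, 4, mode="contiguous", seed=3)
        assert len(out) == 4
        ids = out.residue_ids
        assert np.all(np.diff(ids) == 1)

    def test_spatial_crop_is_nearest_neighbourhood(self):
        cx, ann = make_toy_complex(12, 12, gap=4.0, seed=5)
        out = crop_example(cx, 8, mode="spatial_interface", seed=7, interface=ann)
        assert len(out) == 8
        # the selected set must be the 8 CA-nearest residues of SOME residue
        sel = {(c, int(r)) for c, r in zip(out.chain_ids, out.residue_ids)}
        keys = [(c, int(r)) for c, r in zip(cx.chain_ids, cx.residue_ids)]
        found = False
        for center in range(len(cx)):
            d = np.linalg.norm(cx.coords_CA - cx.coords_CA[center], axis=1)
            nearest = {keys[i] for i in np.argsort(d, kind="stable")[:8]}
            if nearest == sel:
                found = True
                break
        assert found

    def test_crops_are_subsets_and_spatial_spans_chains(self):
        cx, ann = make_toy_complex(12, 12, gap=4.0, seed=6)
        keys = {(c, int(r)) for c, r in zip(cx.chain_ids, cx.residue_ids)}
        for seed in range(5):
            for mode in ("spatial_interface", "contiguous"):
                out = crop_example(cx, 10, mode=mode, seed=seed, interface=ann)
                sub = {(c, int(r)) for c, r in zip(out.chain_ids, out.residue_ids)}
                assert sub <= keys
            spatial = crop_example(cx, 10, mode="spatial_interface", seed=seed,
                                   interface=ann)
            assert set(spatial.chain_ids) == {"A", "B"}

    def test_invalid_inputs(self, hairpin36):
        with pytest.raises(ValueError):
            crop_example(hairpin36, 0)
        with pytest.raises(ValueError):
            crop_example(hairpin36, 5, mode="bogus")
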