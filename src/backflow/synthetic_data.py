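"""Toy-world generators for every input the package consumes.

The toy backbones carry a deterministic geometry->sequence rule: each residue's
amino acid is a fixed table lookup on binned CA(i)-CA(i-2) and CA(i)-CA(i+2)
distances (indices clamped at chain ends).  The rule is a pure function of the
clean geometry, so the Bayes-optimal sequence recovery on clean backbones is
1.0 and any measured recovery has a known ceiling.  Helices, strands and
hairpin turns occupy different descriptor bins, which is exactly the kind of
local distance pattern the trunk's pair features expose to the model.

Also generated here: two-chain complexes with a ground-truth interface mask,
natural/designed sequence profiles with planted functional sites, and
all-against-all ipAE tables with a planted on/off-target gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backbone_io import BackboneStructure, InterfaceAnnotation
from .profile_analysis import SequenceProfile
from .utils import AMINO_ACIDS, seed_stream

__all__ = [
    "ToyWorldConfig",
    "make_toy_backbone",
    "make_toy_complex",
    "make_toy_dataset",
    "toy_sequence_from_geometry",
    "make_synthetic_profiles",
    "make_synthetic_ipae",
]

HELIX_RISE = 1.5          # angstrom per residue
HELIX_TWIST = np.deg2rad(100.0)
HELIX_RADIUS = 2.3
STRAND_RISE = 3.3         # angstrom per residue along the strand axis
STRAND_ZIGZAG = 0.6       # alternating lateral offset
TURN_RADIUS = 2.4

# Geometry->token rule: bins of d(CA_i, CA_{i+/-2}); edges chosen so helix
# (~5.4 A), strand (~6.6 A), turns and chain ends fall in distinct bins.
DESCRIPTOR_BIN_EDGES = np.array([1.0, 4.2, 5.0, 5.9, 6.3, 7.5])
_N_BINS = len(DESCRIPTOR_BIN_EDGES) + 1
# Fixed many-to-one lookup (7x7 descriptor combinations -> 20 letters),
# frozen from a constant seed so the rule is part of the package definition.
TOKEN_TABLE = np.random.default_rng(20250925).integers(0, 20, size=(_N_BINS, _N_BINS))


@dataclass
class ToyWorldConfig:
    """Conditions of the toy training world."""

    alphabet_size: int = 20
    length_range: tuple[int, int] = (24, 48)
    noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (2 <= self.alphabet_size <= 20):
            raise ValueError("alphabet_size must be in [2, 20]")
        if self.length_range[0] < 8:
            raise ValueError("minimum length must be >= 8")


def _place_backbone(ca: np.ndarray, sides: np.ndarray, chain: str,
                    start_id: int = 1) -> BackboneStructure:
    """Attach N, C, O atoms to CA positions given per-residue side vectors."""
    L = len(ca)
    tang = np.zeros_like(ca)
    tang[1:-1] = ca[2:] - ca[:-2]
    tang[0] = ca[1] - ca[0]
    tang[-1] = ca[-1] - ca[-2]
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    side = sides - (sides * tang).sum(axis=1, keepdims=True) * tang
    side /= np.linalg.norm(side, axis=1, keepdims=True)
    # N-CA-C angle ~110 degrees, both atoms tilted to the side vector
    sin55, cos55 = np.sin(np.deg2rad(55.0)), np.cos(np.deg2rad(55.0))
    n = ca + 1.46 * (-sin55 * tang + cos55 * side)
    c = ca + 1.52 * (sin55 * tang + cos55 * side)
    o = c + 1.23 * side
    return BackboneStructure(
        chain_ids=np.full(L, chain, dtype="U4"),
        residue_ids=np.arange(start_id, start_id + L, dtype=np.int64),
        coords_N=n, coords_CA=ca, coords_C=c, coords_O=o,
    )


def _helix_ca(length: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(length)
    theta = i * HELIX_TWIST
    ca = np.stack([HELIX_RADIUS * np.cos(theta),
                   HELIX_RADIUS * np.sin(theta),
                   HELIX_RISE * i], axis=1)
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros(length)], axis=1)
    return ca, radial


def _strand_ca(length: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(length)
    ca = np.stack([STRAND_RISE * i,
                   STRAND_ZIGZAG * (-1.0) ** i,
                   np.zeros(length)], axis=1)
    sides = np.zeros((length, 3))
    sides[:, 2] = (-1.0) ** i
    return ca, sides


def _hairpin_ca(length: int) -> tuple[np.ndarray, np.ndarray]:
    n_turn = 4
    n1 = (length - n_turn + 1) // 2
    n2 = length - n_turn - n1
    if min(n1, n2) < 2:
        raise ValueError("hairpin needs length >= 8")
    i1 = np.arange(n1)
    s1 = np.stack([STRAND_RISE * i1, STRAND_ZIGZAG * (-1.0) ** i1,
                   np.zeros(n1)], axis=1)
    # semicircular turn in the xy-plane joining the two antiparallel strands
    cx = STRAND_RISE * (n1 - 1)
    cy = 2.4
    phi = np.linspace(-0.5 * np.pi, 0.5 * np.pi, n_turn + 2)[1:-1]
    turn = np.stack([cx + TURN_RADIUS * np.cos(phi) + 1.2,
                     cy + TURN_RADIUS * np.sin(phi),
                     np.zeros(n_turn)], axis=1)
    i2 = np.arange(n2)
    s2 = np.stack([STRAND_RISE * (n1 - 1) - STRAND_RISE * i2,
                   2 * cy + STRAND_ZIGZAG * (-1.0) ** i2,
                   np.zeros(n2)], axis=1)
    ca = np.concatenate([s1, turn, s2])
    sides = np.zeros((length, 3))
    sides[:n1, 2] = (-1.0) ** i1
    centre = np.array([cx + 1.2, cy, 0.0])
    turn_rad = turn - centre
    sides[n1:n1 + n_turn] = turn_rad / np.linalg.norm(turn_rad, axis=1, keepdims=True)
    sides[n1 + n_turn:, 2] = (-1.0) ** i2
    return ca, sides


_GEOMETRIES = {"helix": _helix_ca, "strand": _strand_ca, "hairpin": _hairpin_ca}


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random rotation (QR of a Gaussian matrix) + translation."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-20.0, 20.0, size=3)
    return q, t


def _transform(bb: BackboneStructure, rot: np.ndarray, trans: np.ndarray) -> BackboneStructure:
    from dataclasses import replace

    new = {}
    for name in ("coords_N", "coords_CA", "coords_C", "coords_O"):
        new[name] = getattr(bb, name) @ rot.T + trans
    return replace(bb, **new)


def toy_sequence_from_geometry(bb: BackboneStructure,
                               alphabet_size: int = 20) -> str:
    """Apply the deterministic descriptor-table rule to clean CA geometry."""
    letters = []
    ca = bb.coords_CA
    for chain in bb.chains:
        idx = np.nonzero(bb.chain_ids == chain)[0]
        pos = ca[idx]
        L = len(idx)
        for i in range(L):
            lo = max(i - 2, 0)
            hi = min(i + 2, L - 1)
            d_prev = np.linalg.norm(pos[i] - pos[lo])
            d_next = np.linalg.norm(pos[i] - pos[hi])
            b_prev = int(np.digitize(d_prev, DESCRIPTOR_BIN_EDGES))
            b_next = int(np.digitize(d_next, DESCRIPTOR_BIN_EDGES))
            tok = int(TOKEN_TABLE[b_prev, b_next]) % alphabet_size
            letters.append(AMINO_ACIDS[tok])
    return "".join(letters)


def make_toy_backbone(length: int, geometry: str = "helix", seed: int = 0,
                      alphabet_size: int = 20, chain: str = "A") -> BackboneStructure:
    """An ideal-geometry single-chain backbone with its rule-based sequence.

    The seed controls only the global rigid placement; geometry and sequence
    are deterministic functions of ``length`` and ``geometry``.
    """
    if geometry not in _GEOMETRIES:
        raise ValueError(f"unsupported geometry {geometry!r}; use one of {sorted(_GEOMETRIES)}")
    if length < 8:
        raise ValueError("length must be >= 8")
    ca, sides = _GEOMETRIES[geometry](length)
    bb = _place_backbone(ca, sides, chain)
    seq = toy_sequence_from_geometry(bb, alphabet_size)
    bb.sequence = seq
    rng = seed_stream(seed, f"toy-backbone-{geometry}-{length}")
    rot, trans = _random_rigid(rng)
    return _transform(bb, rot, trans)


def make_toy_complex(len_a: int, len_b: int, gap: float = 4.0, seed: int = 0,
                     cutoff: float = 5.0) -> tuple[BackboneStructure, InterfaceAnnotation]:
    """Two strand chains facing each other at distance ``gap``.

    Returns the complex plus a ground-truth interface mask computed by an
    exhaustive all-pairs distance scan over the generator's own closed-form
    coordinates at ``cutoff`` (independent of backbone_io.detect_interface).
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    ca_a, sides_a = _strand_ca(len_a)
    ca_b, sides_b = _strand_ca(len_b)
    # antiparallel partner: reverse direction, offset in z, centre the overlap
    ca_b = ca_b[::-1].copy()
    ca_b[:, 2] += gap
    ca_b[:, 0] += 0.5 * STRAND_RISE * (len_a - len_b)
    sides_b = -sides_b[::-1]
    bb_a = _place_backbone(ca_a, sides_a, "A")
    bb_b = _place_backbone(ca_b, sides_b, "B", start_id=1)
    bb = BackboneStructure(
        chain_ids=np.concatenate([bb_a.chain_ids, bb_b.chain_ids]),
        residue_ids=np.concatenate([bb_a.residue_ids, bb_b.residue_ids]),
        coords_N=np.concatenate([bb_a.coords_N, bb_b.coords_N]),
        coords_CA=np.concatenate([bb_a.coords_CA, bb_b.coords_CA]),
        coords_C=np.concatenate([bb_a.coords_C, bb_b.coords_C]),
        coords_O=np.concatenate([bb_a.coords_O, bb_b.coords_O]),
    )
    bb.sequence = toy_sequence_from_geometry(bb)
    # ground truth by brute force over every backbone-atom pair
    atoms = [np.stack([bb.coords_N[i], bb.coords_CA[i], bb.coords_C[i], bb.coords_O[i]])
             for i in range(len(bb))]
    mask = np.zeros(len(bb), dtype=bool)
    for i in range(len_a):
        for j in range(len_a, len_a + len_b):
            dmin = np.min(np.linalg.norm(atoms[i][:, None, :] - atoms[j][None, :, :], axis=2))
            if dmin <= cutoff:
                mask[i] = True
                mask[j] = True
    rng = seed_stream(seed, f"toy-complex-{len_a}-{len_b}")
    rot, trans = _random_rigid(rng)
    return _transform(bb, rot, trans), InterfaceAnnotation(interface_mask=mask, cutoff=cutoff)


def make_toy_dataset(n: int, config: ToyWorldConfig | None = None,
                     seed: int = 0) -> list[BackboneStructure]:
    """A mixed helix/strand/hairpin dataset for toy training."""
    config = config or ToyWorldConfig()
    rng = seed_stream(seed, "toy-dataset")
    geoms = list(_GEOMETRIES)
    out = []
    lo, hi = config.length_range
    for k in range(n):
        geometry = geoms[int(rng.integers(len(geoms)))]
        length = int(rng.integers(lo, hi + 1))
        out.append(make_toy_backbone(length, geometry, seed=int(rng.integers(2**31 - 1)),
                                     alphabet_size=config.alphabet_size))
    return out


def make_synthetic_profiles(
    length: int,
    n_natural: int,
    n_designed: int,
    functional_sites,
    seed: int = 0,
    structural_sites=None,
    functional_dominant: float = 0.95,
    structural_dominant: float = 0.95,
    background_dominant: float = 0.5,
) -> tuple[SequenceProfile, SequenceProfile, dict]:
    """Aligned natural/designed profiles with planted functional sites.

    Natural columns are strongly conserved (one dominant residue at frequency
    ``functional_dominant``) at functional sites and at a disjoint structural
    site set; the designed profile keeps the structural-site conservation but
    is uniform over the 20 letters at functional sites, mirroring the absence
    of functional constraints in structure-only design.  All other columns use
    identical moderate-conservation distributions in both profiles.
    """
    if n_natural <= 0 or n_designed <= 0:
        raise ValueError("profile depths must be positive")
    functional = set(int(i) for i in functional_sites)
    if functional and (min(functional) < 0 or max(functional) >= length):
        raise ValueError("functional site out of range")
    rng = seed_stream(seed, "synthetic-profiles")
    if structural_sites is None:
        pool = np.array(sorted(set(range(length)) - functional))
        k = min(max(2, length // 10), len(pool))
        structural = set(int(i) for i in rng.choice(pool, size=k, replace=False))
    else:
        structural = set(int(i) for i in structural_sites)
    if functional & structural:
        raise ValueError("functional and structural site sets must be disjoint")

    def column(dominant_aa: int, dominant_freq: float) -> np.ndarray:
        f = np.full(20, (1.0 - dominant_freq) / 19.0)
        f[dominant_aa] = dominant_freq
        return f

    def background_column(dominant_aa: int) -> np.ndarray:
        # moderate conservation over a small residue repertoire, as in real
        # alignment columns; keeps column-to-column sampling TV small
        f = np.zeros(20)
        f[dominant_aa] = background_dominant
        others = [x for x in range(20) if x != dominant_aa]
        minor = rng.choice(others, size=3, replace=False)
        f[minor] = (1.0 - background_dominant) / 3.0
        return f

    uniform = np.full(20, 0.05)
    dominant_aas = rng.integers(0, 20, size=length)
    nat_cols, des_cols = [], []
    for i in range(length):
        aa = int(dominant_aas[i])
        if i in functional:
            nat_cols.append(column(aa, functional_dominant))
            des_cols.append(uniform)
        elif i in structural:
            f = column(aa, structural_dominant)
            nat_cols.append(f)
            des_cols.append(f)
        else:
            f = background_column(aa)
            nat_cols.append(f)
            des_cols.append(f)

    def sample(cols: list[np.ndarray], n: int) -> list[str]:
        letters = np.empty((n, length), dtype="U1")
        for i, f in enumerate(cols):
            draws = rng.choice(20, size=n, p=f)
            letters[:, i] = [AMINO_ACIDS[d] for d in draws]
        return ["".join(row) for row in letters]

    natural = SequenceProfile(sample(nat_cols, n_natural))
    designed = SequenceProfile(sample(des_cols, n_designed))
    annotations = {
        "functional_sites": functional,
        "structural_sites": structural,
        "dominant_aas": dominant_aas,
    }
    return natural, designed, annotations


def make_synthetic_ipae(
    n_binders: int,
    n_targets: int,
    on_target_mean: float,
    off_target_mean: float,
    noise_sd: float,
    seed: int = 0,
    ptm_fail_fraction: float = 0.2,
    backbones_per_target: int = 2,
) -> pd.DataFrame:
    """All-against-all ipAE table with a planted on/off-target confidence gap.

    Each binder has a designated target; its on-target ipAE is drawn around
    ``on_target_mean`` and every off-target value around ``off_target_mean``
    (positive-truncated).  A ``ptm`` column is drawn so that roughly
    ``ptm_fail_fraction`` of binders fail the pTM > 0.8 criterion.
    Long-form columns: binder_id, backbone_id, designated_target, target_id,
    ipae_i, ptm.
    """
    if on_target_mean >= off_target_mean:
        raise ValueError("on_target_mean must be below off_target_mean")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_targets < 1 or n_binders < 1:
        raise ValueError("need at least one binder and one target")
    rng = seed_stream(seed, "synthetic-ipae")
    targets = [f"T{j}" for j in range(n_targets)]
    rows = []
    for i in range(n_binders):
        t = i % n_targets
        backbone = f"{targets[t]}_bb{(i // n_targets) % backbones_per_target}"
        binder = f"{targets[t]}_binder{i // n_targets}"
        fail = rng.uniform() < ptm_fail_fraction
        ptm = float(rng.uniform(0.5, 0.8)) if fail else float(rng.uniform(0.81, 0.98))
        for j, tgt in enumerate(targets):
            mean = on_target_mean if j == t else off_target_mean
            val = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({
                "binder_id": binder,
                "backbone_id": backbone,
                "designated_target": targets[t],
                "target_id": tgt,
                "ipae_i": max(float(val), 1e-6),
                "ptm": ptm,
            })
    return pd.DataFrame(rows)
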