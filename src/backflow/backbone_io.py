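"""Backbone structure I/O, rigid frames, coordinate noise, interfaces, crops.

Structures are reduced to their backbone atoms (N, CA, C, O): the design model
is conditioned on backbone geometry only.  PDB and mmCIF files are parsed with
gemmi; residues missing any of N/CA/C are dropped (a missing O is tolerated
since frames only need N/CA/C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .utils import AMINO_ACIDS, UNKNOWN, seed_stream

__all__ = [
    "BackboneStructure",
    "RigidFrames",
    "InterfaceAnnotation",
    "read_backbone",
    "write_pdb",
    "build_frames",
    "add_backbone_noise",
    "detect_interface",
    "crop_example",
]

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class BackboneStructure:
    """Per-residue backbone coordinates with chain labels and author numbering.

    ``coords_O`` rows may be NaN where the carbonyl oxygen was absent in the
    input.  ``sequence`` uses one-letter codes with ``X`` for unknown residues.
    """

    chain_ids: np.ndarray          # (L,) unicode chain label per residue
    residue_ids: np.ndarray        # (L,) author residue numbers
    coords_N: np.ndarray           # (L, 3) angstrom
    coords_CA: np.ndarray
    coords_C: np.ndarray
    coords_O: np.ndarray
    sequence: str | None = None

    def __post_init__(self):
        n = len(self.chain_ids)
        for name in ("residue_ids", "coords_N", "coords_CA", "coords_C", "coords_O"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length {len(getattr(self, name))} != {n}")
        if self.sequence is not None and len(self.sequence) != n:
            raise ValueError("sequence length mismatch")
        if n and not np.all(np.isfinite(self.coords_CA)):
            raise ValueError("non-finite CA coordinate")

    def __len__(self) -> int:
        return len(self.chain_ids)

    @property
    def chains(self) -> list[str]:
        """Unique chain labels in file order."""
        out: list[str] = []
        for c in self.chain_ids:
            if not out or out[-1] != c:
                if c in out:
                    raise ValueError(f"chain {c} is not contiguous")
                out.append(str(c))
        return out

    def chain_mask(self, chain: str) -> np.ndarray:
        mask = self.chain_ids == chain
        if not mask.any():
            raise KeyError(f"unknown chain label {chain!r}")
        return mask

    def select(self, indices: np.ndarray) -> "BackboneStructure":
        """Subset by residue indices (kept in the given order)."""
        indices = np.asarray(indices)
        seq = None
        if self.sequence is not None:
            seq = "".join(self.sequence[i] for i in indices)
        return BackboneStructure(
            chain_ids=self.chain_ids[indices].copy(),
            residue_ids=self.residue_ids[indices].copy(),
            coords_N=self.coords_N[indices].copy(),
            coords_CA=self.coords_CA[indices].copy(),
            coords_C=self.coords_C[indices].copy(),
            coords_O=self.coords_O[indices].copy(),
            sequence=seq,
        )

    def backbone_coords(self) -> np.ndarray:
        """All finite backbone atom coordinates as (n_atoms, 3) with residue index map."""
        coords, owners = [], []
        for arr in (self.coords_N, self.coords_CA, self.coords_C, self.coords_O):
            finite = np.isfinite(arr).all(axis=1)
            coords.append(arr[finite])
            owners.append(np.nonzero(finite)[0])
        return np.concatenate(coords), np.concatenate(owners)


@dataclass
class RigidFrames:
    """Per-residue rotation + translation (the IPA conditioning frames)."""

    rotations: np.ndarray     # (L, 3, 3)
    translations: np.ndarray  # (L, 3)

    def __post_init__(self):
        if len(self.rotations) != len(self.translations):
            raise ValueError("rotations/translations length mismatch")
        ident = np.einsum("lij,lkj->lik", self.rotations, self.rotations)
        if len(self.rotations):
            if not np.allclose(ident, np.eye(3), atol=1e-6):
                raise ValueError("rotation not orthonormal")
            if not np.allclose(np.linalg.det(self.rotations), 1.0, atol=1e-6):
                raise ValueError("rotation not right-handed")

    def __len__(self) -> int:
        return len(self.rotations)


@dataclass
class InterfaceAnnotation:
    interface_mask: np.ndarray  # (L,) bool over the whole structure
    cutoff: float
    partner_chain: str = ""

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def read_backbone(path: str | Path, model_index: int = 0) -> BackboneStructure:
    """Parse a PDB or mmCIF file into a backbone-only structure.

    Residues lacking any of N/CA/C are dropped with a warning; altlocs take the
    highest-occupancy copy (ties go to the first in file); insertion codes are
    flattened in file order.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if model_index >= len(st):
        raise IndexError(f"model_index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    chain_ids, residue_ids, seq = [], [], []
    coords = {a: [] for a in BACKBONE_ATOMS}
    n_dropped = 0
    for chain in model:
        for res in chain:
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.name not in BACKBONE_ATOMS:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            if not all(a in best for a in ("N", "CA", "C")):
                if any(a in best for a in BACKBONE_ATOMS):
                    n_dropped += 1
                continue
            chain_ids.append(chain.name)
            residue_ids.append(res.seqid.num)
            seq.append(THREE_TO_ONE.get(res.name, UNKNOWN))
            for a in BACKBONE_ATOMS:
                if a in best:
                    p = best[a].pos
                    coords[a].append([p.x, p.y, p.z])
                else:
                    coords[a].append([np.nan] * 3)
    if n_dropped:
        warnings.warn(f"{path.name}: dropped {n_dropped} residue(s) missing backbone atoms")
    if not chain_ids:
        raise ValueError(f"{path}: no residue with complete N/CA/C backbone")
    return BackboneStructure(
        chain_ids=np.array(chain_ids, dtype="U4"),
        residue_ids=np.array(residue_ids, dtype=np.int64),
        coords_N=np.array(coords["N"]),
        coords_CA=np.array(coords["CA"]),
        coords_C=np.array(coords["C"]),
        coords_O=np.array(coords["O"]),
        sequence="".join(seq),
    )


def write_pdb(bb: BackboneStructure, path: str | Path) -> None:
    """Write backbone atoms (skipping NaN oxygens) as a PDB file."""
    st = gemmi.Structure()
    st.name = "backflow"
    model = gemmi.Model("1")
    for chain_name in bb.chains:
        chain = gemmi.Chain(chain_name)
        for i in np.nonzero(bb.chain_ids == chain_name)[0]:
            aa = bb.sequence[i] if bb.sequence else UNKNOWN
            res = gemmi.Residue()
            res.name = ONE_TO_THREE.get(aa, "UNK")
            res.seqid = gemmi.SeqId(int(bb.residue_ids[i]), " ")
            for name, arr, element in (
                ("N", bb.coords_N, "N"), ("CA", bb.coords_CA, "C"),
                ("C", bb.coords_C, "C"), ("O", bb.coords_O, "O"),
            ):
                xyz = arr[i]
                if not np.all(np.isfinite(xyz)):
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(element)
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def build_frames(bb: BackboneStructure) -> RigidFrames:
    """Gram-Schmidt frames: x along C-CA, N in the xy half-plane, CA as origin."""
    e1 = bb.coords_C - bb.coords_CA
    n1 = np.linalg.norm(e1, axis=1, keepdims=True)
    u = bb.coords_N - bb.coords_CA
    bad = np.nonzero(n1[:, 0] < 1e-8)[0]
    if bad.size:
        raise ValueError(f"degenerate frame: zero C-CA vector at residue index {bad[0]}")
    e1 = e1 / n1
    u_perp = u - (u * e1).sum(axis=1, keepdims=True) * e1
    n2 = np.linalg.norm(u_perp, axis=1, keepdims=True)
    bad = np.nonzero(n2[:, 0] < 1e-8)[0]
    if bad.size:
        raise ValueError(f"degenerate frame: collinear N/CA/C at residue index {bad[0]}")
    e2 = u_perp / n2
    e3 = np.cross(e1, e2)
    rot = np.stack([e1, e2, e3], axis=2)  # columns are local axes in global coords
    return RigidFrames(rotations=rot, translations=bb.coords_CA.copy())


def add_backbone_noise(bb: BackboneStructure, sigma: float, seed: int) -> BackboneStructure:
    """Add iid Gaussian noise (std ``sigma`` per coordinate) to every backbone atom."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return replace(bb)
    rng = seed_stream(seed, "backbone-noise")
    new = {}
    for name in ("coords_N", "coords_CA", "coords_C", "coords_O"):
        arr = getattr(bb, name)
        noisy = arr + rng.normal(0.0, sigma, size=arr.shape)
        # keep missing-atom NaNs missing
        noisy[~np.isfinite(arr)] = np.nan
        new[name] = noisy
    return replace(bb, **new)


def detect_interface(
    bb: BackboneStructure,
    chain_a: str,
    chain_b: str,
    cutoff: float = 5.0,
    min_residues: int = 5,
) -> InterfaceAnnotation | None:
    """Flag residues of two chains whose backbone atoms approach within ``cutoff``.

    Returns ``None`` unless each chain has at least ``min_residues`` flagged
    residues (``min_residues=0`` disables the qualification rule).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mask_a = bb.chain_mask(chain_a)
    mask_b = bb.chain_mask(chain_b)
    coords, owners = bb.backbone_coords()
    in_a = mask_a[owners]
    in_b = mask_b[owners]
    tree_b = cKDTree(coords[in_b])
    flagged = np.zeros(len(bb), dtype=bool)
    hits_a = tree_b.query_ball_point(coords[in_a], cutoff)
    owners_a = owners[in_a]
    owners_b = owners[in_b]
    for atom_idx, hits in enumerate(hits_a):
        if hits:
            flagged[owners_a[atom_idx]] = True
            for h in hits:
                flagged[owners_b[h]] = True
    if min_residues > 0:
        if (flagged & mask_a).sum() < min_residues or (flagged & mask_b).sum() < min_residues:
            return None
    if not flagged.any() and min_residues == 0:
        return None
    return InterfaceAnnotation(interface_mask=flagged, cutoff=cutoff, partner_chain=chain_b)


def crop_example(
    bb: BackboneStructure,
    crop_size: int,
    mode: str = "spatial_interface",
    seed: int = 0,
    interface: InterfaceAnnotation | None = None,
) -> BackboneStructure:
    """Crop a training example to ``crop_size`` residues.

    ``spatial_interface`` keeps the residues CA-nearest to a randomly chosen
    interface residue (any residue if there is no interface); ``contiguous``
    takes one random contiguous window per chain, sized proportionally to
    chain length.
    """
    if crop_size < 1:
        raise ValueError("crop_size must be >= 1")
    L = len(bb)
    if crop_size >= L:
        return bb.select(np.arange(L))
    rng = seed_stream(seed, "crop")
    if mode == "spatial_interface":
        if interface is None:
            interface = _any_interface(bb)
        if interface is not None and interface.interface_mask.any():
            candidates = np.nonzero(interface.interface_mask)[0]
        else:
            candidates = np.arange(L)
        center = int(rng.choice(candidates))
        d = np.linalg.norm(bb.coords_CA - bb.coords_CA[center], axis=1)
        order = np.argsort(d, kind="stable")[:crop_size]
        return bb.select(np.sort(order))
    if mode == "contiguous":
        chains = bb.chains
        lengths = np.array([int((bb.chain_ids == c).sum()) for c in chains])
        # proportional allocation, largest-remainder rounding
        exact = crop_size * lengths / lengths.sum()
        alloc = np.floor(exact).astype(int)
        rem = crop_size - alloc.sum()
        for i in np.argsort(exact - np.floor(exact))[::-1][:rem]:
            alloc[i] += 1
        alloc = np.minimum(alloc, lengths)
        keep: list[np.ndarray] = []
        for c, n_keep in zip(chains, alloc):
            if n_keep == 0:
                continue
            idx = np.nonzero(bb.chain_ids == c)[0]
            start = int(rng.integers(0, len(idx) - n_keep + 1))
            keep.append(idx[start:start + n_keep])
        return bb.select(np.concatenate(keep))
    raise ValueError(f"unknown crop mode {mode!r}")


def _any_interface(bb: BackboneStructure) -> InterfaceAnnotation | None:
    """Union of pairwise chain interfaces at the default 5 A rule (no qualification)."""
    chains = bb.chains
    combined = np.zeros(len(bb), dtype=bool)
    found = False
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            ann = detect_interface(bb, chains[i], chains[j], cutoff=5.0, min_residues=0)
            if ann is not None:
                combined |= ann.interface_mask
                found = True
    if not found:
        return None
    return InterfaceAnnotation(interface_mask=combined, cutoff=5.0)
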