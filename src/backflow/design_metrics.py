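"""Design evaluation: sequence recovery, coupling-contact agreement, refold filters.

The coupling estimator is mutual information with average-product correction
(APC) over a designed sequence profile — a desk-scale stand-in for
pseudolikelihood direct-coupling analysis with the same ranking semantics; an
externally computed coupling matrix can be supplied to ``contact_agreement``
instead.  Refold filters apply the published AlphaFold2/AlphaFold3 confidence
thresholds as strict inequalities, and success rates aggregate pass flags per
designed backbone (structure rate) and per designed sequence (sequence rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backbone_io import BackboneStructure
from .profile_analysis import SequenceProfile
from .utils import AA_TO_INDEX

__all__ = [
    "ContactMap",
    "sequence_recovery",
    "estimate_couplings",
    "contact_map",
    "contact_agreement",
    "apply_refold_filters",
    "success_rates",
    "kabsch_rmsd",
    "SEPARATION_STRATA",
    "FILTER_CRITERIA",
]

# sequence-separation strata for contact ranking
SEPARATION_STRATA = {
    "short": (6, 12),
    "medium": (12, 24),
    "long": (24, None),
}

# confidence thresholds a designed binder must pass after refolding
# (column, comparison, threshold); all inequalities strict
FILTER_CRITERIA = {
    "AF2": (
        ("rmsd_binder", "lt", 1.5),
        ("pae_interface", "lt", 7.0),
        ("plddt", "gt", 90.0),
    ),
    "AF3": (
        ("ipae_i", "lt", 1.5),
        ("ptm", "gt", 0.8),
        ("rmsd_complex", "lt", 2.5),
    ),
}


@dataclass
class ContactMap:
    """Boolean residue-contact matrix with its defining atom rule."""

    contacts: np.ndarray          # (L, L) bool, symmetric, zero diagonal
    definition: str = "CA_8A"

    def __post_init__(self):
        c = np.asarray(self.contacts, dtype=bool)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("contact map must be square")
        if not np.array_equal(c, c.T):
            raise ValueError("contact map must be symmetric")
        np.fill_diagonal(c, False)
        self.contacts = c

    def __len__(self) -> int:
        return len(self.contacts)


def sequence_recovery(designed: str, native: str) -> float:
    """Fraction of positions where designed and native share the amino acid."""
    if len(designed) != len(native):
        raise ValueError(f"length mismatch: {len(designed)} vs {len(native)}")
    if not designed:
        raise ValueError("empty sequences")
    return sum(a == b for a, b in zip(designed, native)) / len(designed)


def _pseudo_cb(bb: BackboneStructure) -> np.ndarray:
    """Idealised CB from N, CA, C (the standard tetrahedral construction)."""
    b = bb.coords_CA - bb.coords_N
    c = bb.coords_C - bb.coords_CA
    a = np.cross(b, c)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c + bb.coords_CA


def contact_map(bb: BackboneStructure, definition: str = "CA_8A",
                cutoff: float = 8.0) -> ContactMap:
    """Native contacts from CA (or pseudo-CB) pairwise distances below ``cutoff``."""
    if definition == "CA_8A":
        xyz = bb.coords_CA
    elif definition == "CB_8A":
        xyz = _pseudo_cb(bb)
    else:
        raise ValueError("definition must be 'CA_8A' or 'CB_8A'")
    d = np.linalg.norm(xyz[None, :, :] - xyz[:, None, :], axis=-1)
    contacts = d < cutoff
    np.fill_diagonal(contacts, False)
    return ContactMap(contacts=contacts, definition=definition)


def estimate_couplings(profile: SequenceProfile, pseudocount: float = 1.0) -> np.ndarray:
    """APC-corrected mutual information between alignment columns.

    MI_ij from empirical pair frequencies with a uniform pseudocount, then the
    average-product correction MI_ij - MI_i. * MI_.j / MI_.. that removes
    per-column background (phylogenetic/compositional) signal before contact
    ranking.  Diagonal is -inf so self-pairs never rank.  All-gap columns are
    excluded (zero row/column) with a warning.
    """
    if profile.depth < 2:
        raise ValueError("need at least 2 sequences to estimate couplings")
    L = profile.length
    # integer encoding, -1 for gaps/unknown
    enc = np.full((profile.depth, L), -1, dtype=np.int64)
    for s, seq in enumerate(profile.sequences):
        for i, ch in enumerate(seq):
            enc[s, i] = AA_TO_INDEX.get(ch, -1)
    valid_cols = (enc >= 0).any(axis=0)
    if not valid_cols.all():
        warnings.warn(f"{(~valid_cols).sum()} all-gap column(s) excluded from couplings")
    mi = np.zeros((L, L))
    q = 20
    for i in range(L):
        if not valid_cols[i]:
            continue
        for j in range(i + 1, L):
            if not valid_cols[j]:
                continue
            ok = (enc[:, i] >= 0) & (enc[:, j] >= 0)
            if ok.sum() < 2:
                continue
            pair = np.zeros((q, q))
            np.add.at(pair, (enc[ok, i], enc[ok, j]), 1.0)
            pair += pseudocount / (q * q)
            pair /= pair.sum()
            pi = pair.sum(axis=1, keepdims=True)
            pj = pair.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = pair * np.log(pair / (pi * pj))
            mi[i, j] = mi[j, i] = np.nansum(terms)
    # average-product correction over off-diagonal entries
    row_mean = mi.sum(axis=1) / max(L - 1, 1)
    total_mean = mi.sum() / max(L * (L - 1), 1)
    if total_mean > 0:
        apc = np.outer(row_mean, row_mean) / total_mean
        couplings = mi - apc
    else:
        couplings = mi
    couplings = 0.5 * (couplings + couplings.T)
    np.fill_diagonal(couplings, -np.inf)
    return couplings


def contact_agreement(couplings: np.ndarray, contacts: ContactMap,
                      fractions: tuple[int, ...] = (1, 2, 5),
                      strata: dict | None = None) -> pd.DataFrame:
    """Precision of top-ranked coupling pairs against native contacts.

    For each sequence-separation stratum and each fraction f, the top
    floor(L/f) pairs by coupling (ties broken by (i, j) lexicographic order)
    are compared with the contact map; strata with no eligible pair report
    NaN, not zero.  Rows: (stratum, top_fraction, n_selected, precision).
    """
    couplings = np.asarray(couplings, dtype=float)
    L = len(contacts)
    if couplings.shape != (L, L):
        raise ValueError("couplings and contacts must have matching shapes")
    strata = strata or SEPARATION_STRATA
    iu, ju = np.triu_indices(L, k=1)
    sep = ju - iu
    rows = []
    for name, (lo, hi) in strata.items():
        eligible = sep >= lo if hi is None else (sep >= lo) & (sep < hi)
        ei, ej = iu[eligible], ju[eligible]
        for f in fractions:
            k = L // f
            label = "L" if f == 1 else f"L/{f}"
            if ei.size == 0 or k == 0:
                rows.append({"stratum": name, "top_fraction": label,
                             "n_selected": 0, "precision": np.nan})
                continue
            # sort by descending coupling, then lexicographic (i, j)
            order = np.lexsort((ej, ei, -couplings[ei, ej]))[:k]
            hits = contacts.contacts[ei[order], ej[order]]
            rows.append({"stratum": name, "top_fraction": label,
                         "n_selected": int(order.size),
                         "precision": float(hits.mean())})
    return pd.DataFrame(rows)


def apply_refold_filters(table: pd.DataFrame, criteria: str = "AF3") -> pd.Series:
    """Row-wise pass flags under the AF2 or AF3 refold-confidence thresholds."""
    if criteria not in FILTER_CRITERIA:
        raise ValueError(f"criteria must be one of {sorted(FILTER_CRITERIA)}")
    rules = FILTER_CRITERIA[criteria]
    missing = [col for col, _, _ in rules if col not in table.columns]
    if missing:
        raise KeyError(f"metrics table lacks column(s) {missing} required by {criteria}")
    passed = pd.Series(True, index=table.index)
    for col, op, threshold in rules:
        vals = table[col]
        passed &= (vals < threshold) if op == "lt" else (vals > threshold)
    return passed


def success_rates(table: pd.DataFrame, pass_col: str = "passed",
                  target_col: str = "target_id", backbone_col: str = "backbone_id"
                  ) -> pd.DataFrame:
    """Per-target structure and sequence success rates (in percent).

    structure success rate: % of designed backbones with >= 1 passing sequence;
    sequence success rate: % of designed sequences that pass.
    """
    if len(table) == 0:
        raise ValueError("empty metrics table: success rates undefined")
    for col in (pass_col, target_col, backbone_col):
        if col not in table.columns:
            raise KeyError(f"metrics table lacks column {col!r}")
    rows = []
    for target, grp in table.groupby(target_col, sort=True):
        by_backbone = grp.groupby(backbone_col)[pass_col].any()
        rows.append({
            "target_id": target,
            "n_backbones": int(by_backbone.size),
            "n_sequences": int(len(grp)),
            "structure_success_rate": 100.0 * float(by_backbone.mean()),
            "sequence_success_rate": 100.0 * float(grp[pass_col].mean()),
        })
    return pd.DataFrame(rows)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares RMSD after optimal superposition (toy coordinate checks)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("need matching (N, 3) coordinate arrays")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = ac @ rot.T - bc
    return float(np.sqrt((diff**2).sum() / len(a)))
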