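"""Natural-vs-designed sequence-profile comparison and functional-site scoring.

A designed profile (many sequences sampled for one fixed backbone) encodes
purely structural constraints; a natural alignment additionally encodes
functional constraints.  Contrasting the two highlights functional sites:
positions conserved in evolution but free under structure-only design.

Conservation is the normalized-entropy index C = 1 - H(f)/ln(20) computed from
per-column amino-acid frequencies (gaps excluded from the normalisation); an
externally computed per-column index can be supplied wherever one is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import average_precision_score, precision_recall_curve
from statsmodels.stats.multitest import multipletests

from .utils import AA_TO_INDEX, AMINO_ACIDS, seed_stream

__all__ = [
    "SequenceProfile",
    "DivergenceRecord",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "conservation_index",
    "conservation_track",
    "relative_conservation",
    "profile_divergence",
    "annotation_divergence_test",
    "functional_site_scores",
    "pr_evaluation",
]

GAP_CHARS = set("-.")


@dataclass
class SequenceProfile:
    """An aligned set of sequences over the 20-letter alphabet plus gaps."""

    sequences: list[str]

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("profile needs at least one sequence")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("all sequences must share the alignment length")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def depth(self) -> int:
        return len(self.sequences)

    def frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-column frequency matrix (L, 20) over non-gap residues + gap fraction (L,).

        Columns that are entirely gaps get a zero frequency row.
        """
        L = self.length
        counts = np.zeros((L, 20))
        gaps = np.zeros(L)
        for s in self.sequences:
            for i, c in enumerate(s):
                if c in GAP_CHARS:
                    gaps[i] += 1
                elif c in AA_TO_INDEX:
                    counts[i, AA_TO_INDEX[c]] += 1
                # unknown letters (X) are ignored like gaps but not counted as gaps
        totals = counts.sum(axis=1, keepdims=True)
        freqs = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
        return freqs, gaps / self.depth


@dataclass
class DivergenceRecord:
    """Per-domain profile divergence with its annotation terms."""

    domain_id: str
    pd: float
    annotations: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.pd < 0:
            raise ValueError("profile divergence must be non-negative")


def read_aligned_fasta(path: str | Path) -> SequenceProfile:
    seqs, cur = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                    cur = []
            else:
                cur.append(line.upper())
    if cur:
        seqs.append("".join(cur))
    return SequenceProfile(seqs)


def write_aligned_fasta(profile: SequenceProfile, path: str | Path,
                        names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(profile.sequences):
            name = names[i] if names else f"seq{i}"
            fh.write(f">{name}\n{s}\n")


def conservation_index(f: np.ndarray) -> float:
    """Normalized-entropy conservation of one column: 1 for invariant, 0 for uniform."""
    f = np.asarray(f, dtype=float)
    total = f.sum()
    if total <= 0:
        raise ValueError("all-gap column has undefined conservation")
    if not np.isclose(total, 1.0, atol=1e-6):
        f = f / total
    nz = f[f > 0]
    h = -(nz * np.log(nz)).sum()
    return float(1.0 - h / np.log(20.0))


def conservation_track(profile: SequenceProfile) -> np.ndarray:
    """Per-column conservation; NaN at all-gap columns."""
    freqs, gap_frac = profile.frequencies()
    out = np.full(profile.length, np.nan)
    for i in range(profile.length):
        if freqs[i].sum() > 0:
            out[i] = conservation_index(freqs[i])
    return out


def relative_conservation(profile: SequenceProfile, positions: np.ndarray | list[int]) -> float:
    """Mean conservation over ``positions`` minus the global mean over all columns."""
    track = conservation_track(profile)
    positions = np.asarray(list(positions), dtype=int)
    if positions.size == 0:
        raise ValueError("category has no positions")
    if positions.min() < 0 or positions.max() >= profile.length:
        raise IndexError("category position out of range")
    cat = np.nanmean(track[positions])
    return float(cat - np.nanmean(track))


def profile_divergence(natural: SequenceProfile, designed: SequenceProfile,
                       max_gap_fraction: float = 0.5) -> float:
    """Mean per-position distance between the two column distributions.

    Under the discrete 0/1 ground metric the 1-Wasserstein distance between two
    20-dim frequency vectors equals their total-variation distance; positions
    whose natural column exceeds ``max_gap_fraction`` gaps (or with no data in
    either profile) are excluded from the average.
    """
    if natural.length != designed.length:
        raise ValueError("profiles must be aligned to the same length")
    f_nat, gap_nat = natural.frequencies()
    f_des, _ = designed.frequencies()
    keep = (f_nat.sum(axis=1) > 0) & (f_des.sum(axis=1) > 0) & (gap_nat <= max_gap_fraction)
    if not keep.any():
        raise ValueError("no positions with data in both profiles")
    tv = 0.5 * np.abs(f_nat[keep] - f_des[keep]).sum(axis=1)
    return float(tv.mean())


def annotation_divergence_test(records: list[DivergenceRecord],
                               terms: list[str] | None = None) -> pd.DataFrame:
    """Mann-Whitney U of PD for annotated vs non-annotated domains, per term.

    All tested terms form one Benjamini-Hochberg family; terms with an empty
    group are skipped.  Returns columns term, n_annotated, n_other, U, p, q.
    """
    if terms is None:
        terms = sorted({t for r in records for t in r.annotations})
    pds = np.array([r.pd for r in records])
    rows = []
    for term in terms:
        mask = np.array([term in r.annotations for r in records])
        if mask.sum() == 0 or (~mask).sum() == 0:
            continue
        u, p = mannwhitneyu(pds[mask], pds[~mask], alternative="two-sided")
        rows.append({"term": term, "n_annotated": int(mask.sum()),
                     "n_other": int((~mask).sum()), "U": float(u), "p": float(p)})
    df = pd.DataFrame(rows, columns=["term", "n_annotated", "n_other", "U", "p"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def functional_site_scores(natural_cons: np.ndarray, designed_cons: np.ndarray) -> np.ndarray:
    """Subtraction score: natural minus designed conservation, per position."""
    natural_cons = np.asarray(natural_cons, dtype=float)
    designed_cons = np.asarray(designed_cons, dtype=float)
    if natural_cons.shape != designed_cons.shape:
        raise ValueError("conservation tracks must have equal length")
    return natural_cons - designed_cons


def pr_evaluation(scores: np.ndarray, positives, negatives, neg_ratio: int = 10,
                  seed: int = 0) -> dict:
    """Precision-recall of per-position scores for separating functional sites.

    Negatives are subsampled (seeded) to ``neg_ratio`` times the positive count,
    matching a 1:10 class prior.  Returns the PR curve and average precision.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(sorted(positives), dtype=int)
    neg = np.asarray(sorted(negatives), dtype=int)
    if pos.size == 0:
        raise ValueError("positive set is empty")
    if neg.size == 0:
        raise ValueError("negative set is empty")
    rng = seed_stream(seed, "pr-negative-subsample")
    n_neg = min(neg.size, neg_ratio * pos.size)
    neg = rng.choice(neg, size=n_neg, replace=False)
    idx = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = scores[idx]
    precision, recall, thresholds = precision_recall_curve(y, s)
    return {
        "precision": precision,
        "recall": recall,
        "thresholds": thresholds,
        "average_precision": float(average_precision_score(y, s)),
        "n_positive": int(pos.size),
        "n_negative": int(neg.size),
    }
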