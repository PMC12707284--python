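"""Binder specificity scoring from all-against-all interface-confidence tables.

For a binder intended for target t, the specificity score is

    S_spec = min_{j != t} ipAE_i(binder, T_j)  -  ipAE_i(binder, T_t),

the gap between the most confident off-target interaction and the on-target
one (larger = more specific; ipAE is lower when the predictor is more
confident).  Selection additionally requires binder pTM > 0.8.  The scaling
analysis resamples N designed sequences per backbone and reports the average
maximal S_spec over repetitions, reproducing how specificity grows with the
number of designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .utils import seed_stream

__all__ = [
    "SpecificityResult",
    "specificity_score",
    "score_table",
    "select_best_binder",
    "specificity_scaling",
]

PTM_MIN = 0.8


@dataclass
class SpecificityResult:
    binder_id: str
    target_id: str
    ipae_on: float
    ipae_off_best: float
    s_spec: float
    ptm: float
    backbone_id: str = ""

    def __post_init__(self):
        if self.ipae_on < 0 or self.ipae_off_best < 0:
            raise ValueError("ipAE values must be non-negative")
        if not np.isclose(self.s_spec, self.ipae_off_best - self.ipae_on):
            raise ValueError("s_spec must equal ipae_off_best - ipae_on")


def specificity_score(ipae_row, target_index: int, binder_id: str = "",
                      ptm: float = np.nan, backbone_id: str = "",
                      target_ids: list[str] | None = None) -> SpecificityResult:
    """Score one binder's all-targets ipAE row against its designated target."""
    row = np.asarray(ipae_row, dtype=float)
    if row.ndim != 1 or row.size < 2:
        raise ValueError("specificity is undefined with fewer than 2 targets")
    if not 0 <= target_index < row.size:
        raise IndexError("target_index out of range")
    ipae_on = float(row[target_index])
    off = np.delete(row, target_index)
    ipae_off_best = float(off.min())
    name = target_ids[target_index] if target_ids else str(target_index)
    return SpecificityResult(
        binder_id=binder_id,
        target_id=name,
        ipae_on=ipae_on,
        ipae_off_best=ipae_off_best,
        s_spec=ipae_off_best - ipae_on,
        ptm=float(ptm),
        backbone_id=backbone_id,
    )


def score_table(table: pd.DataFrame) -> list[SpecificityResult]:
    """Score every binder in a long-form all-against-all table.

    Expects columns binder_id, designated_target, target_id, ipae_i, ptm and
    optionally backbone_id (see synthetic_data.make_synthetic_ipae).
    """
    required = {"binder_id", "designated_target", "target_id", "ipae_i", "ptm"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"table lacks column(s) {sorted(missing)}")
    targets = sorted(table["target_id"].unique())
    if len(targets) < 2:
        raise ValueError("specificity is undefined with fewer than 2 targets")
    pos = {t: i for i, t in enumerate(targets)}
    results = []
    for binder, grp in table.groupby("binder_id", sort=True):
        if len(grp) != len(targets):
            raise ValueError(f"binder {binder} lacks a complete all-targets row")
        row = np.empty(len(targets))
        row[[pos[t] for t in grp["target_id"]]] = grp["ipae_i"].to_numpy()
        designated = grp["designated_target"].iloc[0]
        backbone = grp["backbone_id"].iloc[0] if "backbone_id" in grp.columns else ""
        results.append(specificity_score(
            row, pos[designated], binder_id=str(binder), ptm=float(grp["ptm"].iloc[0]),
            backbone_id=str(backbone), target_ids=targets,
        ))
    return results


def select_best_binder(results: list[SpecificityResult],
                       ptm_min: float = PTM_MIN) -> SpecificityResult | None:
    """Highest-S_spec binder among those with pTM strictly above ``ptm_min``.

    Ties break toward lower on-target ipAE, then lexicographic binder id.
    Returns None (an empty selection, not an error) if nothing passes.
    """
    if not results:
        raise ValueError("empty result list")
    eligible = [r for r in results if r.ptm > ptm_min]
    if not eligible:
        return None
    return min(eligible, key=lambda r: (-r.s_spec, r.ipae_on, r.binder_id))


def specificity_scaling(results: list[SpecificityResult], n_design_grid: list[int],
                        reps: int = 100, seed: int = 0, ptm_min: float = PTM_MIN,
                        apply_ptm_in_resampling: bool = True) -> pd.DataFrame:
    """Average maximal S_spec as a function of designs sampled per backbone.

    For each target and each N in the grid: sample min(N, available) sequences
    per backbone without replacement, pool them, take the best S_spec subject
    to the pTM constraint, and average over ``reps`` repetitions.  Targets with
    no scored binder are skipped with a warning column in the output absent.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    by_target: dict[str, dict[str, list[SpecificityResult]]] = {}
    for r in results:
        by_target.setdefault(r.target_id, {}).setdefault(r.backbone_id, []).append(r)
    rng = seed_stream(seed, "specificity-scaling")
    rows = []
    for target in sorted(by_target):
        backbones = by_target[target]
        for n in n_design_grid:
            if n < 1:
                raise ValueError("n_design values must be >= 1")
            vals = []
            for _ in range(reps):
                pool: list[SpecificityResult] = []
                for _, rs in sorted(backbones.items()):
                    take = min(n, len(rs))
                    chosen = rng.choice(len(rs), size=take, replace=False)
                    pool.extend(rs[c] for c in chosen)
                if apply_ptm_in_resampling:
                    pool = [r for r in pool if r.ptm > ptm_min]
                vals.append(max((r.s_spec for r in pool), default=np.nan))
            vals = np.asarray(vals, dtype=float)
            ok = np.isfinite(vals)
            rows.append({
                "target_id": target,
                "n_design": n,
                "mean_max_s_spec": float(vals[ok].mean()) if ok.any() else np.nan,
                "sd_max_s_spec": float(vals[ok].std(ddof=1)) if ok.sum() > 1 else 0.0,
                "n_reps_valid": int(ok.sum()),
            })
    return pd.DataFrame(rows)
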