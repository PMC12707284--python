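"""Specificity scoring and inference-time scaling on a synthetic campaign.

Each binder is refolded against every target in a family; its specificity is
S_spec = (best off-target ipAE_i) - (on-target ipAE_i).  Designing more
sequences per backbone and keeping the most specific one raises the expected
maximum - fastest at small design counts.
"""

from backflow.specificity import score_table, select_best_binder, specificity_scaling
from backflow.synthetic_data import make_synthetic_ipae

# 120 binders across 4 targets, true on/off-target gap of 4 ipAE units
table = make_synthetic_ipae(n_binders=120, n_targets=4, on_target_mean=1.0,
                            off_target_mean=5.0, noise_sd=0.8, seed=2)
results = score_table(table)
best = select_best_binder([r for r in results if r.target_id == "T0"])
print(f"best T0 binder: {best.binder_id}  S_spec={best.s_spec:.2f}  pTM={best.ptm:.2f}")

curve = specificity_scaling(results, n_design_grid=[1, 2, 5, 10, 30], reps=100, seed=3)
mean_curve = curve.groupby("n_design")["mean_max_s_spec"].mean()
print("designs/backbone -> mean best S_spec across targets:")
for n, v in mean_curve.items():
    print(f"  n={n:>2d}: {v:.2f}")
# the curve is nondecreasing with diminishing returns: most of the specificity
# gain comes from the first handful of designs per backbone
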