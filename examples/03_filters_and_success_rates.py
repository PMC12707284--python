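"""Refold-confidence filtering and binder success rates.

Designed binders are judged by refolding their complexes with a structure
predictor and thresholding its confidence: ipAE_i < 1.5, binder pTM > 0.8
and complex RMSD < 2.5 (all strict).  The structure success rate counts
backbones with at least one passing sequence; the sequence success rate
counts passing sequences.
"""

import numpy as np
import pandas as pd

from backflow.design_metrics import apply_refold_filters, success_rates

rng = np.random.default_rng(0)
n = 200
table = pd.DataFrame({
    "target_id": rng.choice(["EGFR", "IL7RA"], n),
    "backbone_id": rng.choice([f"bb{i}" for i in range(8)], n),
    "ipae_i": rng.uniform(0.5, 3.0, n),
    "ptm": rng.uniform(0.6, 1.0, n),
    "rmsd_complex": rng.uniform(0.5, 5.0, n),
})
table["passed"] = apply_refold_filters(table, criteria="AF3")
print(f"{int(table.passed.sum())}/{n} sequences pass the AF3 thresholds")
print(success_rates(table).to_string(index=False))
# structure rates exceed sequence rates here because a backbone passes as soon
# as any one of its sequences does
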