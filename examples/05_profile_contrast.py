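"""Functional-site prediction by contrasting natural and designed profiles.

Natural alignments conserve functional sites (catalysis, ligand binding) and
structural sites alike; sequences designed for a fixed backbone conserve only
the structural ones.  Subtracting designed from natural conservation cancels
the structural term and highlights function.
"""

import numpy as np

from backflow.profile_analysis import (conservation_track, functional_site_scores,
                                       pr_evaluation, profile_divergence)
from backflow.synthetic_data import make_synthetic_profiles

length = 100
functional_sites = {7, 23, 41, 58, 76, 90}
natural, designed, ann = make_synthetic_profiles(
    length, n_natural=400, n_designed=400, functional_sites=functional_sites, seed=4)

nat_c = conservation_track(natural)
des_c = conservation_track(designed)
scores = functional_site_scores(nat_c, des_c)
print(f"profile divergence PD = {profile_divergence(natural, designed):.3f}")
top = np.argsort(scores)[::-1][:len(functional_sites)]
print(f"planted sites:           {sorted(functional_sites)}")
print(f"top difference scores:   {sorted(int(i) for i in top)}")

positives = sorted(ann["functional_sites"])
# conserved structural sites stay in the negatives: they are the confounder
# that makes natural conservation alone imprecise
negatives = sorted(set(range(length)) - ann["functional_sites"])
for name, s in (("natural", nat_c), ("designed", des_c), ("difference", scores)):
    ap = pr_evaluation(s, positives, negatives, neg_ratio=10, seed=5)["average_precision"]
    print(f"average precision ({name:>10s}): {ap:.3f}")
# the difference score should rank all planted sites first and dominate both
# single-profile baselines at the 1:10 positive:negative prior
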