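"""Robustness to low-resolution (Cα-only, noisy) structural models.

Corrupts an interface the way a low-resolution trace would look —
side chains gone, each Cα displaced by a half-normal magnitude with
sigma = 1 A — and shows the PC-score still clearly separates the true
match from the unrelated-pair background.
"""

import numpy as np

import pcalign as pc

iface = pc.generate_synthetic_interface(pc.FixtureSpec(n_per_fragment=20, seed=3))
noisy = pc.perturb_backbone(iface, sigma=1.0, seed=30)
score = pc.align_and_score(iface, noisy).pc
print(f"PC-score(original vs 1A-perturbed copy) = {score:.3f}")

# a small seeded background of unrelated pairs gives the null distribution
background = pc.background_scores(n=99, seed=0)
print(f"background of 99 unrelated pairs: median {np.median(background):.3f}, "
      f"max {background.max():.3f}")

p = pc.empirical_pvalue(score, background)
print(f"empirical p-value of the perturbed match: {p:.3f} "
      f"(add-one tail frequency; 1/{len(background) + 1} is the floor)")
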