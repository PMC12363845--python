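"""Fit psychophysical curve families to one odorant's panel ratings.

Builds a small synthetic rating set from a known Hill curve with panel noise,
fits all four families (Hill, Beidler, Stevens, Fechner), and prints the
recovered parameters and the per-family RMSE ranking.
"""

import numpy as np

from odorint import HillParams, RatingPoint, compare_families, hill_intensity

true = HillParams(imax=80.0, ec50=1e-6, n=2.0)
rng = np.random.default_rng(7)

points = []
for rep in range(2):  # rated in duplicate
    for c in true.ec50 * 10.0 ** np.linspace(-3, 3, 9):
        intensity = max(hill_intensity(true, c) + rng.normal(0, 3.0), 0.0)
        points.append(RatingPoint("linalool-like", float(c), intensity, rep))

ranked = compare_families(points)

print(f"true curve: Imax={true.imax} EC50={true.ec50:.1e} n={true.n}")
print(f"{'family':<10}{'rmse (gLMS)':>12}  params")
for fit in ranked:
    print(f"{fit.family:<10}{fit.rmse:>12.2f}  {fit.params}")
best = ranked[0]
print(
    f"\nBest family: {best.family}. With sigmoidal concentration-intensity data "
    "the 3-parameter Hill curve should fit best; its RMSE approaches the panel "
    "noise (3 gLMS) and its fitted Imax/EC50/n approach the generating values."
)
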