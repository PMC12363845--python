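"""Evaluate the seven analytic mixture-intensity models on one mixture.

Builds a binary mixture of two odorants with known Hill curves and prints
every model's prediction.  Note how ADD overestimates, the biophysical
models (CB, PRI) compress, and how VEC becomes undefined for a large
all-equal mixture (its negative-cosine radicand goes negative).
"""

from odorint import (
    ComponentState,
    HillParams,
    MixtureModelConfig,
    MixtureSpec,
    hill_intensity,
    predict_all,
)

cfg = MixtureModelConfig()  # cos_alpha=-0.3, fmax=1, 20% primacy fraction

h1 = HillParams(imax=80.0, ec50=1e-6, n=1.5)
h2 = HillParams(imax=55.0, ec50=3e-7, n=2.5)
c1, c2 = 4e-6, 9e-7  # both above their inflection points

mix = MixtureSpec(
    "binary",
    (
        ComponentState("odor-A", c1, float(hill_intensity(h1, c1)), hill=h1),
        ComponentState("odor-B", c2, float(hill_intensity(h2, c2)), hill=h2),
    ),
)

print("component intensities alone:",
      [round(c.intensity_alone, 1) for c in mix.components])
for pred in predict_all(mix, cfg):
    value = f"{pred.value:8.2f}" if pred.valid else f"  undefined ({pred.reason})"
    print(f"  {pred.model:<4} {value}")

# a 10-component mixture of equal intensities: VEC's radicand is negative
big = MixtureSpec("ten", tuple(ComponentState(f"c{i}", 1e-6, 20.0) for i in range(10)))
vec = [p for p in predict_all(big, cfg) if p.model == "VEC"][0]
print(f"\n10 equal components -> VEC valid={vec.valid} ({vec.reason})")
print("ADD sums intensities (upper bound); SC takes the max; the biophysical "
      "models lie between, matching the compression panels report for mixtures.")
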