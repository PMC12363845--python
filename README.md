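# odorint

Quantitative prediction of perceived odor intensity — for single molecules
and for mixtures — from gas-phase concentration and physicochemical
structure.

Unlike brightness (lumens) or loudness (decibels), smell has no standard
intensity axis: equal concentrations of two odorants can smell wildly
different, and the ranking can flip as concentration changes. `odorint`
implements a complete modeling stack for this problem, aimed at olfactory
psychophysicists, flavor chemists and sensory data scientists:

* **Single-odorant psychophysics** — the concentration–intensity relationship
  is modeled with the three-parameter Hill equation

  $$I(C) = \frac{I_{max}\,C^{n}}{C^{n} + EC_{50}^{n}}$$

  fitted by bounded nonlinear least squares in log-concentration space, and
  compared against Stevens' power law, Beidler's function and Fechner's
  logarithmic law by RMSE.
* **Analytic mixture models** — seven predictors of mixture intensity from
  component information: linear addition (ADD), strongest component (SC),
  Euclidean addition (EUC), the vector model (VEC, fixed pairwise cosine
  −0.3), the U model (all k-subset interactions), competitive receptor
  binding (CB), and primacy coding (PRI, the LogSumExp of component
  intensities evaluated at 20 % of ambient concentration).
* **Neural intensity prediction** — a fully connected network (4 × 300 hidden
  units with batch normalization and ReLU, SGD with momentum, MSE loss) maps
  preprocessed molecular descriptors plus log10 concentration to intensity;
  mixtures are encoded as concentration-weighted descriptor averages.
  Includes curve up-sampling augmentation, molecule-stratified and
  component-disjoint ("clean") cross-validation and shuffled-label controls.
* **Descriptor preprocessing** — variance/zero filtering, log transformation,
  correlation-based selection against the fitted Hill parameters, forced
  transport features (MW, MLOGP, vapor pressure, boiling point) and the
  alpha-shape surface area of the 3-D structure.
* **Key-odorant screening** — replaces the classical odor-activity-value
  heuristic (OAV = concentration / detection threshold) with simulated
  omission tests: the predicted intensity drop `Imix − Imix−i` when each
  component is removed, under any mixture predictor.
* **Synthetic ground truth** — a seeded generator emulating the full study
  design (62 molecules rated in duplicate at 9 concentrations; 216 binary,
  20 tertiary, 16 five- and 8 ten-component mixtures from a 24-molecule
  pool), so every pipeline is testable end to end without external data.

## Worked example

```python
import numpy as np
from odorint import (HillParams, RatingPoint, compare_families,
                     hill_intensity)

true = HillParams(imax=80.0, ec50=1e-6, n=2.0)
rng = np.random.default_rng(7)
points = [
    RatingPoint("linalool-like", float(c),
                max(hill_intensity(true, c) + rng.normal(0, 3.0), 0.0), rep)
    for rep in range(2)
    for c in true.ec50 * 10.0 ** np.linspace(-3, 3, 9)
]
for fit in compare_families(points):
    print(f"{fit.family:<10}{fit.rmse:8.2f}")
```

prints

```
hill          1.79
beidler       4.66
fechner      13.29
stevens      19.19
```

— the Hill fit's RMSE (1.79 gLMS) sits below the simulated panel noise
(σ = 3 gLMS) and recovers Imax ≈ 79.7, EC50 ≈ 1.06 × 10⁻⁶ and n ≈ 1.97,
while the two-parameter alternatives fit the sigmoid visibly worse. More
narrative walk-throughs live in `examples/` (mixture-model comparison,
network training, key-odorant screening), and a thin CLI (`odorint simulate
/ fit-curves / predict-mixtures / preprocess-descriptors / train / predict /
screen`) wraps the same library calls for shell use.

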