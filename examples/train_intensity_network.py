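"""Train the descriptor-based intensity network on synthetic ground truth.

Generates a small synthetic study (molecules with descriptors and known Hill
curves, noisy duplicate ratings), fits Hill curves, up-samples them into
training examples, trains the network with held-out molecules, and prints the
held-out error next to a shuffled-label control.

Runs in under a minute; for the full-scale benchmark see
scripts/acceptance.py.
"""

import numpy as np

from odorint.benchmarks import BENCH_NET_CONFIG, single_molecule_benchmark

result = single_molecule_benchmark(
    seed=7,
    n_molecules=30,            # scaled down for a quick demonstration
    folds_evaluated=1,
    config=BENCH_NET_CONFIG,
)

print(f"held-out molecules, test RMSE : {result['test_rmse']:.2f} gLMS")
print(f"held-out molecules, Pearson r : {result['test_r']:.3f}")
print(f"shuffled-label control RMSE   : {result['shuffled_rmse']:.2f} gLMS")
print(f"control / intact ratio        : {result['shuffled_over_intact']:.1f}x")
print(
    "\nThe intact network predicts concentration-intensity curves of molecules "
    "it never saw (r near 1); the control trained on permuted intensities "
    "carries no structure, so its error is several times larger. The gap is "
    "the evidence that descriptors, not molecule identity, drive predictions."
)
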