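"""Generate a layered synthetic dataset and look at its structure.

The generator builds a binary phenotype Y and four blocks of variables:
a first layer directly driven by Y (eight strong uniform-shift variables
plus correlated normal pairs/triplets), second- and third-layer "children"
that sum back to their parent, and independent noise whose univariate
association with Y can be bounded away from significance (delta).
"""

import numpy as np

from bcrange import SimulationDesign, Structure, generate_dataset
from bcrange.simdata import Layer

design = SimulationDesign(
    n_samples=200,
    structure=Structure.THREE_LAYER,
    delta=0.0,
    seed=7,
)
table, truth = generate_dataset(design)

print(f"dataset: {table.n_samples} samples x {table.n_features} features")
print(f"class balance: {int(table.labels.sum())} of {table.n_samples} in group 1")
print()

print("layer sizes:")
for layer in Layer:
    print(f"  {layer.value:<14} {len(truth.indices(layer)):>4}")
print()

y = table.labels.astype(float)
print("absolute correlation with Y (first strong variable of each kind):")
for j, name in [(0, "x1 (strong, shift +0.8-2Y)"),
                (4, "x5 (strong, shift -1.2-2Y)"),
                (9, "x10 (pair member, shift 0.5Y)"),
                (18, "x19 (triplet member, shift 1Y)")]:
    r = abs(np.corrcoef(table.X[:, j], y)[0, 1])
    print(f"  {name:<32} |r| = {r:.3f}")
print()

# children of x1 occupy columns 31-33 (1-based) and sum back to x1 + eps
child_sum = table.X[:, 30:33].sum(axis=1)
r = np.corrcoef(child_sum, table.X[:, 0])[0, 1]
print(f"corr(x31+x32+x33, x1) = {r:.4f}  (children reconstruct their parent)")
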