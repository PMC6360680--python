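"""Compare BCR against FDR and correlation-cutoff baselines on simulations.

Runs a small benchmark grid (10 replicates for speed; raise n_reps for
stable numbers) and prints mean per-layer selection counts for each
method. Layer 1 holds the truly driven variables; counts in the noise row
are false selections.
"""

from bcrange import BenchmarkGrid, run_benchmark
from bcrange.simdata import Structure

grid = BenchmarkGrid(
    structures=(Structure.TWO_LAYER,),
    deltas=(0.0,),
    levels=(0.05,),
    methods=("bcr", "fdr_bh", "fdr_by", "stocsyo"),
    n_reps=10,
    base_seed=42,
)
result = run_benchmark(grid)

print(f"two-layer structure, delta=0, level 0.05, {grid.n_reps} replicates")
print()
print(f"{'method':<10} {'layer1':>8} {'layer2':>8} {'noise':>8}")
for method in grid.methods:
    row = [
        result.mean_count("two_layer", 0.0, 0.05, method, layer)
        for layer in ("layer1", "layer2", "noise")
    ]
    print(f"{method:<10} {row[0]:>8.1f} {row[1]:>8.1f} {row[2]:>8.1f}")

print()
print("note: layer-2 children inherit a third of their parent's group")
print("separation by construction, so per-variable tests flag them in bulk;")
print("BCR's per-wedge budget keeps its counts lower (see docs/methods.md).")
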