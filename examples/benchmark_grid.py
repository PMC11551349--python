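"""Run a miniature method-comparison grid over all 11 dataset variants.

Compares VCA+FCLS against the dense autoencoder on every (mixture
scenario, abundance scene) variant at a small scene size, reporting the
Hungarian-matched endmember SAD and abundance MSE per cell.
"""

from ramanmix.evaluate import BenchmarkGrid, run_benchmark

grid = BenchmarkGrid(
    methods=("vca_fcls", "dense"),
    dataset_seeds=(0,),
    model_seeds=(0,),
    H=40,
    W=40,
    b=500,
    n_true=4,
    epochs=15,
)
df = run_benchmark(grid)
summary = (
    df.groupby(["scenario", "scene", "method"])[["sad", "mse"]].mean().round(4)
)
print(summary)
print(f"\n{len(df)} cells; aggregation: {df.attrs['aggregation']}")
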