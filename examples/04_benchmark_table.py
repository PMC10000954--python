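"""A small optimizer-by-classifier benchmark table.

Crosses the three optimizers with two classifier back-ends on one
synthetic dataset and prints per-cell test-set metrics: accuracy (AC),
balanced accuracy (BA), F1 (F), recall (R), precision (P) and the
search time in seconds (ET).
"""

from aoahg import BenchmarkConfig, generate_embedding_dataset, run_benchmark

data = generate_embedding_dataset(
    n=240, dim=16, k_informative=4, class_sep=3.0, seed=7
)
config = BenchmarkConfig(
    optimizers=("aoahg", "aoa", "hgs"),
    classifiers=("svm", "knn"),
    pop_size=15,
    max_iter=8,
    seeds=(0, 1),
)
table = run_benchmark(config, data)
cols = ["optimizer", "classifier", "seed", "AC", "BA", "F", "ET", "selected"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# Rows with seed="mean" average the per-seed rows; every metric is
# computed on the held-out test split with the final selected subset.
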