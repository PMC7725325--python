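"""Generate a labeled fragment benchmark.

Simulates labeled plasmid-surrogate genomes, extracts random error-free
fragments in the standard length strata (train/A 100-400 bp here) with a
strict genome-level train/test split, and prints the resulting manifest
summary.
"""

from plastrans.simulator import (BenchmarkConfig, build_benchmark,
                                 synthetic_cohort)

genomes = synthetic_cohort(4, n_hosts=2, divergence=1.0, seed=3)
config = BenchmarkConfig(n_train_per_class=500,
                         n_test_per_class={"A": 100, "B": 50}, seed=3)
train, test, manifest = build_benchmark(genomes, config)

print(manifest.groupby(["group", "label"]).size().unstack())
print()
print(manifest.groupby("group").length.agg(["min", "max"]))
train_ids = set(manifest[manifest.group == "train"].genome_id)
test_ids = set(manifest[manifest.group != "train"].genome_id)
print("\ntrain/test genome overlap:", train_ids & test_ids or "none")
# counts are balanced per class within every group, fragment lengths sit in
# each group's stratum, and no genome contributes to both splits.
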