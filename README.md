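# plastrans

Annotate plasmid DNA fragments as **transmissible** (derived from conjugative
or mobilizable plasmids) or **non-transmissible**, from sequence signatures
alone — no marker-gene search, no database alignment.

Plasmidome assemblies are highly fragmented: most contigs are a few hundred
base pairs and rarely cover the relaxase gene or *oriT* that would identify a
transmissible plasmid directly. `plastrans` exploits a compositional signal
instead: through genome amelioration a plasmid converges on its host's codon
preferences, so a plasmid that moves between hosts accumulates *mixed*
preferences. Its synonymous codon usage is measurably more random.

The package has three pillars:

1. **IEA — information entropy of amino acid** (`plastrans.codon_entropy`).
   For amino acid *i* with *nᵢ* synonymous codons and observed usage
   frequencies *pᵢⱼ*,

   IEAᵢ = Σⱼ pᵢⱼ · log_{nᵢ}(1/pᵢⱼ),  0 ≤ IEAᵢ ≤ 1,

   computed per genome for 19 categories (18 degenerate amino acids plus a
   pooled stop category, bacterial translation table 11). IEA = 1 means
   uniform synonymous usage, 0 means a single codon used exclusively.
   `compare_groups` contrasts two genome groups per category (means,
   single-feature AUC, two-sided Wilcoxon rank-sum p-value).

2. **A two-branch convolutional classifier** (`plastrans.model`,
   `plastrans.encoding`, `plastrans.network`). A fragment is encoded two
   ways: the connected six-frame triplet sequence (one-hot over 64 codons)
   and the connected dual-strand base sequence (one-hot over 4 bases). Each
   branch applies a 1-D convolution (512 kernels of length 6, ReLU) and a
   masked global average pool to a 512-d vector; the 1024-d concatenation
   passes through batch-norm/dense/batch-norm blocks to a logistic score in
   (0, 1). Sequences longer than 400 bp are scored with a non-overlapping
   400 bp scan window and the window-mean score. Scores within
   |score − 0.5| < *t* are labelled *uncertain* for a user threshold *t*.
   The network is implemented in numpy, with the one-hot convolution
   evaluated as an embedding lookup for CPU efficiency.

3. **A synthetic benchmark and the evaluation protocol**
   (`plastrans.simulator`, `plastrans.evaluation`). Labeled surrogate
   genomes: non-transmissible genomes draw codons from a single host usage
   table, transmissible genomes from a blend of divergent tables. Fragments
   are extracted uniformly at random in the standard length strata (train/A
   100–400 bp, B 401–800, C 801–1200, D 5000–10000) with a strict
   train/test genome split. Evaluation reports recall, precision, F1
   (certain predictions only) and rank-based AUC across uncertainty
   thresholds.

## Worked example

```python
import numpy as np
from plastrans import (build_genetic_code, iea_profile, compare_groups,
                       build_model, train_model, score_sequence, ModelConfig)
from plastrans.simulator import synthetic_cohort, build_benchmark, BenchmarkConfig
from plastrans.evaluation import auc

code = build_genetic_code(11)
genomes = synthetic_cohort(10, n_hosts=2, divergence=1.0, seed=11)

# 1. codon-entropy contrast between the two classes
trans = [iea_profile(g, code) for g in genomes
         if g.annotations["transmissibility"] == "transmissible"]
non = [iea_profile(g, code) for g in genomes
       if g.annotations["transmissibility"] == "non-transmissible"]
table = compare_groups(trans, non, code)
print(table.head(3).to_string(index=False))

# 2. train the classifier on fragments and score held-out data
train, test, _ = build_benchmark(genomes, BenchmarkConfig(
    n_train_per_class=2000, n_test_per_class={"A": 500}, seed=11))
cfg = ModelConfig(triplet_kernels=128, base_kernels=128, hidden_dim=128,
                  batch_size=128, max_epochs=6, seed=0)
model = train_model(build_model(cfg), train, cfg)
scores = model.score_batch([f.sequence for f in test["A"]])
y = [1 if f.label == "transmissible" else 0 for f in test["A"]]
print("held-out group-A AUC:", round(auc(scores.tolist(), y), 3))
```

Output (abridged):

```
category  n_codons   mean_a   mean_b  auc      p_value flag
       A         4 0.530229 0.056732  1.0 1.450889e-11
       C         2 0.995017 0.102874  1.0 6.786039e-08
       D         2 0.997121 0.054009  1.0 6.681468e-08
held-out group-A AUC: 0.999
```

`mean_a`/`mean_b` are the class-average IEA values: mixed-host surrogate
genomes use synonymous codons far more randomly than single-host surrogates
(≈0.06); two-fold degenerate categories approach the entropy maximum of 1,
while alanine (4 codons, two preferred at this divergence) sits near
log 2 / log 4 = 0.5. Every category separates the classes perfectly (AUC
1.0; the rank-sum p-value is exact for tie-free 20 vs 20 groups), and the
fragment classifier transfers the signal to unseen 100–400 bp fragments
from held-out genomes (AUC ≈ 1).

The same workflow is available from the shell:

```bash
plastrans simulate --out run/ --seed 1
plastrans train --train run/train.fasta --out run/ --kernels 128 --epochs 6
plastrans predict --in run/test_A.fasta --model run/model.npz --t 0.2 --out run/
plastrans evaluate --pred run/predictions.tsv --t 0 --t 0.2 --out run/
plastrans iea compute --in run/genomes.gbk --labels run/labels.tsv --out run/profiles.tsv
```

or as a single YAML-configured pipeline (`plastrans pipeline --config cfg.yaml`);
`examples/` contains one short narrative script per capability.

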