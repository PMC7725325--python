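"""Shared fixtures: genetic code, synthetic cohorts, and one trained
desk-scale classifier reused by the model, evaluation and acceptance tests
(training is the expensive step, so it happens once per session)."""

from __future__ import annotations

import numpy as np
import pytest

from plastrans.codon_entropy import build_genetic_code
from plastrans.evaluation import auc
from plastrans.model import ModelConfig, build_model, train_model
from plastrans.simulator import (BenchmarkConfig, build_benchmark,
                                 synthetic_cohort)

#: desk-scale architecture: same topology as the full model, fewer kernels
#: so the parameter-recovery run fits a single CPU.
DESK_CONFIG = dict(
    triplet_kernels=128, base_kernels=128, hidden_dim=128,
    batch_size=128, learning_rate=1e-3,
)


@pytest.fixture(scope="session")
def code():
    return build_genetic_code(11)


@pytest.fixture(scope="session")
def cohort():
    """20 transmissible + 20 non-transmissible synthetic genomes (10 per
    class per split), two host tables at divergence 1."""
    return synthetic_cohort(10, n_hosts=2, divergence=1.0, seed=11)


@pytest.fixture(scope="session")
def benchmark(cohort):
    """Desk-scale fragment benchmark: 2000 train fragments per class,
    500 group-A test fragments per class."""
    cfg = BenchmarkConfig(n_train_per_class=2000,
                          n_test_per_class={"A": 500}, seed=11)
    return build_benchmark(cohort, cfg)


@pytest.fixture(scope="session")
def trained_model(benchmark):
    """Classifier trained on the separable desk benchmark (6 epochs)."""
    train, _, _ = benchmark
    cfg = ModelConfig(max_epochs=6, early_stop_patience=6, seed=0, **DESK_CONFIG)
    return train_model(build_model(cfg), train, cfg)


@pytest.fixture(scope="session")
def heldout_scores(trained_model, benchmark):
    """(scores, truth01, fragments) on the group-A held-out set."""
    _, test, _ = benchmark
    frags = test["A"]
    scores = trained_model.score_batch([f.sequence for f in frags])
    y = np.array([1 if f.label == "transmissible" else 0 for f in frags])
    return scores, y, frags


@pytest.fixture(scope="session")
def heldout_auc(heldout_scores):
    scores, y, _ = heldout_scores
    return auc(scores.tolist(), y.tolist())


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
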