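"""Shared fixtures.

The synthetic benchmark and the trained models are session-scoped: the
learning-recovery and ablation tests all evaluate the same strong-signal
dataset (planted-alert generative AUC ~0.97) so each variant is trained
exactly once per session.
"""

import numpy as np
import pytest

from molcarc.chemio import MoleculeRecord, split_train_external
from molcarc.model import CarcinogenicityModel, TrainConfig
from molcarc.synthetic import SyntheticSpec, generate

BENCH_SEED = 11
BENCH_EPOCHS = 30
TRAIN_SEED = 5


@pytest.fixture(scope="session")
def benchmark_spec():
    # strong planted signal: generative (Bayes) AUC ~0.97 at these log-odds
    return SyntheticSpec(n_molecules=1000, alert_log_odds=6.0, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def benchmark_data(benchmark_spec):
    records = generate(benchmark_spec)
    train, held_out = split_train_external(records, 200, seed=0)
    return {"records": records, "train": train, "held_out": held_out}


def _train_variant(train_records, variant):
    model = CarcinogenicityModel(train_records, fingerprint="CDKExt",
                                 variant=variant,
                                 config=TrainConfig(epochs=BENCH_EPOCHS))
    return model.fit(seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def trained_full(benchmark_data):
    return _train_variant(benchmark_data["train"], "full")


@pytest.fixture(scope="session")
def trained_of(benchmark_data):
    return _train_variant(benchmark_data["train"], "OF")


@pytest.fixture(scope="session")
def trained_og(benchmark_data):
    return _train_variant(benchmark_data["train"], "OG")


@pytest.fixture(scope="session")
def permuted_benchmark(benchmark_data):
    """Same molecules, labels permuted: any signal left is spurious."""
    records = benchmark_data["records"]
    rng = np.random.default_rng(3)
    perm = rng.permutation([r.label for r in records])
    permuted = [MoleculeRecord(r.id, r.smiles, int(l), r.source)
                for r, l in zip(records, perm)]
    train, held_out = split_train_external(permuted, 200, seed=0)
    return {"train": train, "held_out": held_out}


@pytest.fixture(scope="session")
def trained_permuted(permuted_benchmark):
    return _train_variant(permuted_benchmark["train"], "full")


@pytest.fixture
def toy_records():
    """Mixed-validity set exercising every curation rule."""
    return [
        MoleculeRecord("keep1", "c1ccccc1O", 1, "toy"),
        MoleculeRecord("small", "CCO", 1, "toy"),          # two carbons
        MoleculeRecord("metal", "CCCC[Pb](CCCC)(CCCC)CCCC", 1, "toy"),
        MoleculeRecord("mixture", "CCO.CCN", 0, "toy"),
        MoleculeRecord("polymer", "CCC*", 0, "toy"),
        MoleculeRecord("keep2", "CCCO", 0, "toy"),
        MoleculeRecord("dup", "C1=CC=CC=C1O", 1, "toy"),   # same as keep1
    ]
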