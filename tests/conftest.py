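import numpy as np
import pytest

import phagefs as pf


@pytest.fixture
def seq_acdk():
    return pf.ProteinSequence("t1", "ACDK")


@pytest.fixture
def all_residue_seq():
    # every canonical residue once, then doubled so every encoder applies
    return pf.ProteinSequence("full", pf.AMINO_ACIDS + pf.AMINO_ACIDS)


@pytest.fixture(scope="session")
def planted_spec():
    """Study conditions with a recoverable class signal: multiplier 3 on
    K and V in the positive class, 100 samples per class, lengths 80-120."""
    return pf.SyntheticSpec(
        n_pos=100, n_neg=100, min_length=80, max_length=120,
        bias={"K": 3.0, "V": 3.0}, seed=7,
    )


@pytest.fixture(scope="session")
def null_spec():
    """No class signal: identical residue distributions in both classes."""
    return pf.SyntheticSpec(
        n_pos=100, n_neg=100, min_length=80, max_length=120, seed=11,
    )


@pytest.fixture(scope="session")
def planted_data(planted_spec):
    return pf.generate(planted_spec)


@pytest.fixture(scope="session")
def null_data(null_spec):
    return pf.generate(null_spec)


@pytest.fixture(scope="session")
def planted_aac(planted_data):
    return pf.encode_dataset(planted_data, "aac")


@pytest.fixture(scope="session")
def tiny_data():
    """10-sample separable toy set for degenerate-scale smoke runs."""
    rng = np.random.default_rng(3)
    seqs, labels = [], []
    for i in range(5):
        L = 30
        # positives rich in K, negatives rich in D
        pos = "".join(rng.choice(list("KKKAG"), size=L))
        neg = "".join(rng.choice(list("DDDAG"), size=L))
        seqs.append(pf.ProteinSequence(f"p{i}", pos))
        labels.append(1)
        seqs.append(pf.ProteinSequence(f"n{i}", neg))
        labels.append(0)
    return pf.LabeledDataset(seqs, labels)


@pytest.fixture(scope="session")
def pipeline_runs(planted_spec):
    """Two identically-seeded end-to-end runs on the planted fixture.

    Shared session-wide: the first run backs the recovery checks, the pair
    backs the determinism check.  AAC encoder, 50 importance rounds,
    5-fold CV; the test split is an independent draw from the same
    conditions.
    """
    import dataclasses

    train = pf.generate(planted_spec)
    test = pf.generate(dataclasses.replace(planted_spec, seed=8))
    runs = [
        pf.run_pipeline(
            train, test, encoders=("aac",),
            rounds=50, folds=5, seed=42, baseline=True,
        )
        for _ in range(2)
    ]
    return runs
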