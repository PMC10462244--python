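import pytest

from frasebot import fixtures, nativeness


@pytest.fixture(scope="session")
def separable_set():
    """500 planted true FRASEs + 1000 fragment-shuffled decoys (seed 0)."""
    return fixtures.make_separable_frase_set(n_true=500, multiplicity=2, seed=0)


@pytest.fixture(scope="session")
def trained_model(separable_set):
    """Nativeness model trained on the separable set at 50 epochs."""
    truths, decoys = separable_set
    cfg = nativeness.TrainConfig(epochs=50)
    return nativeness.train_model(truths, decoys, cfg, seed=0)


@pytest.fixture(scope="session")
def small_frase_pool():
    """A small mixed pool of FRASEs for featurization oracles."""
    truths, decoys = fixtures.make_separable_frase_set(n_true=30, multiplicity=1, seed=7)
    return truths + decoys


@pytest.fixture(scope="session")
def planted_db():
    """Database built from one planted benzene complex."""
    from frasebot import frase_db

    cx = fixtures.make_planted_complex(seed=2)
    return cx, frase_db.build_frase_db([cx])
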