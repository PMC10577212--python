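"""Shared fixtures: the synthetic study task and trained model grids.

The heavyweight fixtures are session-scoped so the end-to-end behavioural
tests (learning, FS-vs-FR contrast, delay trend) share trained models
instead of retraining per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from fscode import SpikingClassifier, SynthSpec, generate, train_test_split

MUS = (1, 4, 12)
SEEDS = range(5)


@pytest.fixture(scope="session")
def study_task():
    """The 3-class nonrepetitive audio-like task: F=20, T=50, 100 trials/class.

    Returns the 80/20 split plus a larger freshly generated evaluation set
    (300 trials, generator seed 1) used for low-variance accuracy curves.
    """
    ds = generate(SynthSpec(seed=0))
    train, test = train_test_split(ds, 0.8, seed=0)
    big = generate(SynthSpec(seed=1))
    return {
        "X_train": train.to_tensors(),
        "y_train": train.labels,
        "X_test": test.to_tensors(),
        "y_test": test.labels,
        "X_eval": big.to_tensors(),
        "y_eval": big.labels,
        "spec": ds.spec,
    }


@pytest.fixture(scope="session")
def fs_grid(study_task):
    """FS models over mu x seed, 50 epochs each (arch 20-FC64(R)-3)."""
    grid = {}
    for mu in MUS:
        for seed in SEEDS:
            grid[(mu, seed)] = SpikingClassifier(
                loss="fs", mu=mu, epochs=50, random_state=seed
            ).fit(study_task["X_train"], study_task["y_train"])
    return grid


@pytest.fixture(scope="session")
def fr_seed0(study_task):
    """The FR baseline under the stated conditions (50 epochs, seed 0)."""
    return SpikingClassifier(loss="fr", epochs=50, random_state=0).fit(
        study_task["X_train"], study_task["y_train"]
    )


@pytest.fixture(scope="session")
def matched_pairs(study_task):
    """FS/FR pairs with matched 80-epoch budgets across 5 seeds."""
    pairs = {}
    for seed in SEEDS:
        for loss in ("fs", "fr"):
            pairs[(loss, seed)] = SpikingClassifier(
                loss=loss, epochs=80, random_state=seed
            ).fit(study_task["X_train"], study_task["y_train"])
    return pairs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
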