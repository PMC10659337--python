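import numpy as np
import pandas as pd
import pytest

import flmm
from flmm.data import FunctionalDataset, TimeGrid


@pytest.fixture(scope="session")
def small_truth():
    """Desk-size delay truth: 4 subjects, 2 sessions x 10 trials, S = 45."""
    return flmm.delay_template(n_subjects=4, trials_per_session=10)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    ds, latents = flmm.generate_functional(small_truth, seed=1234)
    return ds, latents


@pytest.fixture()
def toy_dataset():
    """Tiny deterministic dataset: 2 subjects x 2 sessions x 3 trials, S = 6."""
    rng = np.random.default_rng(7)
    rows = []
    for subj in ("a", "b"):
        for sess in (1, 2):
            for tr in (1, 2, 3):
                rows.append((subj, sess, tr, float(sess == 2)))
    trials = pd.DataFrame(rows, columns=["subject", "session", "trial", "delay"])
    grid = TimeGrid.regular(-0.2, 6, 15.0)
    Y = rng.normal(size=(len(trials), 6)) + trials["delay"].to_numpy()[:, None]
    return FunctionalDataset(Y=Y, grid=grid, trials=trials)
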