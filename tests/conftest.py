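"""Shared fixtures.

Desk-scale study conditions: the CNN keeps the full fixed architecture,
so every training fixture runs on the smallest admissible grids
(62-64 voxels per dimension) with small cohorts and a short training
schedule — the problem sizes documented in the methods note.  Expensive
runs are session-scoped and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

try:  # avoid BLAS oversubscription when the CPU quota is below the core count
    from threadpoolctl import threadpool_limits
    _blas_limiter = threadpool_limits(limits=1)  # keep alive
except Exception:  # pragma: no cover
    pass

from comanet import CNN3DClassifier, SyntheticConfig, synthesize_cohort_arrays
from comanet.experiments import (DESK_TRAIN, null_experiment,  # noqa: F401
                                 recovery_experiment)

SEED = 1


@pytest.fixture(scope="session")
def tiny_fitted_clf():
    """A quick fit on 6 subjects at the minimal 62^3 grid, for prediction
    and activation-map tests that need a fitted model of the real cascade."""
    cfg = SyntheticConfig(grid_shape=(62, 62, 62), n_controls=3, n_patients=3,
                          index_names=("GM",), seed=SEED)
    table, _, vols = synthesize_cohort_arrays(cfg)
    x = vols["GM"]
    x = (x - x.min()) / (x.max() - x.min())
    clf = CNN3DClassifier(epochs=2, batch_size=3, learning_rate=1e-3,
                          random_state=SEED)
    clf.fit(x, table["class"].to_numpy())
    return clf, x.astype(np.float32), table["class"].to_numpy()


@pytest.fixture(scope="session")
def recovery_run():
    """The shared strong-effect experiment: 10 controls + 10 patients at
    64^3, five informative indices (effect 3 x noise SD) and one
    pure-noise index (T1, effect 0), one stratified 2-fold split."""
    return recovery_experiment(seed=SEED)


@pytest.fixture(scope="session")
def null_run():
    """Zero effect everywhere: the no-signal control condition."""
    return null_experiment(seed=SEED + 1)
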