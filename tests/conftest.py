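import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

import dfcstates as d


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced 3-state cohort: 6 control subjects, 24 ROIs, 229 volumes.

    Returns (config, subjects, manifest, truth, windowed) with windowed FC
    precomputed per subject.
    """
    cfg = d.SyntheticConfig(
        n_rois=24, n_per_group=(("NC", 6), ("SCD", 0), ("AD", 0)), seed=0
    )
    subjects, manifest, truth = d.simulate_cohort(cfg)
    windowed = {ts.subject_id: d.compute_dynamic_fc(ts) for ts in subjects}
    return cfg, subjects, manifest, truth, windowed


def interior_window_states(state_sequence: np.ndarray, window_len: int = 15):
    """(window state label, interior mask) for sliding windows of a sequence.

    A window is interior when all its volumes share one latent state; the
    label column gives the state of the window's first volume.
    """
    win = sliding_window_view(np.asarray(state_sequence), window_len)
    interior = (win == win[:, :1]).all(axis=1)
    return win[:, 0], interior
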