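"""Shared fixtures.

The default 11-subject cohort is expensive to simulate and preprocess, so it
is built once per session and shared by every test that needs cohort-scale
data: per-subject analysis epochs (-100..800 ms), the pooled classification
epochs (0..500 ms), and asynchronous evaluation blocks for a 4-subject
subset.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ernbci import preprocess as pp
from ernbci import synth_eeg as se
from ernbci.async_detect import build_blocks

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")

COHORT_SEED = 42
N_SUBJECTS = 11
N_ASYNC_SUBJECTS = 4


class CohortData:
    def __init__(self):
        self.analysis_epochs = []      # list[EpochSet], one per subject
        self.classify_epochs = None    # pooled ndarray (n, ch, 125)
        self.classify_labels = None
        self.blocks = []               # EvaluationBlocks, first 4 subjects


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, fully preprocessed (built once)."""
    data = CohortData()
    pools_e, pools_l = [], []
    cfg = pp.PreprocConfig()
    for i, (rec, ev) in enumerate(se.iter_cohort(N_SUBJECTS, COHORT_SEED)):
        cont, _, rejected = pp.preprocess_continuous(rec, cfg)
        ev250 = pp.rescale_events(ev, rec.fs, cont.fs)
        eps = pp.epoch(cont, ev250, cfg.analysis_window_ms,
                       subject_id=f"S{i + 1:02d}")
        data.analysis_epochs.append(pp.reject_epochs(eps, cfg.epoch_reject_uv))
        ceps = pp.epoch(cont, ev250, cfg.classify_window_ms,
                        subject_id=f"S{i + 1:02d}")
        ceps = pp.reject_epochs(ceps, cfg.epoch_reject_uv)
        pools_e.append(ceps.epochs)
        pools_l.append(ceps.labels)
        if i < N_ASYNC_SUBJECTS:
            data.blocks += build_blocks(cont, ev250,
                                        subject_id=f"S{i + 1:02d}")
        del rec, cont
    data.classify_epochs = np.concatenate(pools_e)
    data.classify_labels = np.concatenate(pools_l)
    return data


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
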