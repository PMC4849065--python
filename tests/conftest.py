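import numpy as np
import pytest

from jmdropout.synthetic_trial import (
    magnetic_like_config,
    recovery_config,
    trial_from_dropout_counts,
)
from jmdropout.trial_data import Cause


@pytest.fixture(scope="session")
def table1_trial():
    """Trial skeleton reproducing the published per-arm dropout counts."""
    return trial_from_dropout_counts(seed=0)


@pytest.fixture(scope="session")
def paper_allocation(table1_trial):
    """The published scenario-1 split: 6/5 good-poor active, 4/5 control."""
    alloc = {}
    for arm, n_good in ((1, 6), (0, 4)):
        ids = [
            r.patient_id
            for r in table1_trial.records
            if r.arm == arm and r.cause is Cause.UNKNOWN
        ]
        for i, pid in enumerate(ids):
            alloc[pid] = "good" if i < n_good else "poor"
    return alloc


@pytest.fixture(scope="session")
def small_trial():
    """A small synthetic trial with all dropout causes present."""
    from jmdropout.synthetic_trial import generate_trial

    return generate_trial(magnetic_like_config(n_per_arm=60), seed=7)


@pytest.fixture(scope="session")
def recovery_trial():
    """One full-size trial from the recovery configuration (causes unmasked)."""
    from jmdropout.synthetic_trial import generate_trial

    return generate_trial(recovery_config(), seed=11)
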