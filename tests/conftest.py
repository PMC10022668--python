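import logging

import numpy as np
import pytest

from duoscale.scale_model import reference_axis
from duoscale.task_design import StimulusEpoch, TaskSchedule

# The packaged tables each contain one known inversion; the repair path logs
# it loudly on every axis build, which would swamp the test logs.
logging.getLogger("duoscale.scale_model").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def pain_axis():
    return reference_axis("pain")


@pytest.fixture(scope="session")
def fatigue_axis():
    return reference_axis("fatigue")


def toy_visual_schedule(values, durations, conditions=None, baseline=None):
    """Hand-built schedule for alignment fixtures (not design-validated)."""
    conditions = conditions or ["initial"] + ["change_both"] * (len(values) - 1)
    onsets = np.concatenate([[0], np.cumsum(durations)[:-1]]).astype(int)
    epochs = tuple(
        StimulusEpoch(int(o), int(d), v1, v2, c)
        for o, d, (v1, v2), c in zip(onsets, durations, values, conditions)
    )
    return TaskSchedule(
        task="visual",
        epochs=epochs,
        total_duration=int(sum(durations)),
        baseline=baseline,
    )
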