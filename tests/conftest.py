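import numpy as np
import pytest

from workcap.trials import TrialRecord, score_trial


def make_trial(
    condition,
    rt=None,
    rt_right=None,
    participant="P01",
    load="single",
    interval=1,
    onset=1000.0,
):
    """Build a TrialRecord with sensible defaults for tests."""
    responded = rt is not None or rt_right is not None
    return TrialRecord(
        participant_id=participant,
        task_load=load,
        interval_index=interval,
        onset_ms=onset,
        condition=condition,
        rt_left_ms=rt,
        rt_right_ms=rt_right,
        responded=responded,
    )


def make_scored(condition, rt=None, **kwargs):
    return score_trial(make_trial(condition, rt=rt, **kwargs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
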