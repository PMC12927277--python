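"""Shared fixtures: small designs and deterministic random streams."""

import numpy as np
import pandas as pd
import pytest

import pupilpipe as pp
from pupilpipe.preprocess import VALID, CleanRecording


@pytest.fixture
def small_design():
    """Two blocks of three pulses: 6 trials, ~2.6 min sessions."""
    return pp.StudyDesign(n_participants=4, n_blocks=2, pulses_per_block=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_clean_recording(
    trace,
    onset_ms,
    rate=100.0,
    participant=0,
    condition="sham",
    left=None,
    right=None,
    left_flags=None,
    right_flags=None,
):
    """CleanRecording wrapper around a single-trial constructed trace."""
    trace = np.asarray(trace, float)
    n = len(trace)
    time_ms = np.arange(n) * (1000.0 / rate)
    left = trace if left is None else np.asarray(left, float)
    right = trace if right is None else np.asarray(right, float)
    lf = (
        np.full(n, VALID, dtype=np.int8)
        if left_flags is None
        else np.asarray(left_flags, np.int8)
    )
    rf = (
        np.full(n, VALID, dtype=np.int8)
        if right_flags is None
        else np.asarray(right_flags, np.int8)
    )
    onsets = np.atleast_1d(onset_ms)
    events = pd.DataFrame(
        {
            "onset_ms": onsets,
            "duration_ms": 1000,
            "block": 0,
            "trial_index": np.arange(len(onsets)),
            "condition": condition,
        }
    )
    return CleanRecording(
        participant=participant,
        condition=condition,
        time_ms=time_ms,
        left=left,
        right=right,
        left_flags=lf,
        right_flags=rf,
        windows=pd.DataFrame(columns=["eye", "start_ms", "end_ms", "source"]),
        events=events,
        rate=rate,
    )
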