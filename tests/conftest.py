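"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from physiotrack.fcn import PredictionSeries


def make_series(stream, window_s=10.0, patient_id="p0", setting="home",
                start=datetime(2021, 1, 4, 10, 0)):
    """Build a PredictionSeries from a 0/1 window stream."""
    stream = np.asarray(stream, dtype=int)
    n = len(stream)
    from datetime import timedelta
    times = np.arange(n) * window_s
    probs = np.stack([1.0 - stream, stream], axis=1).astype(float)
    return PredictionSeries(
        patient_id=patient_id, session_id="s0", setting=setting,
        window_s=window_s, start_times_s=times,
        start_datetimes=[start + timedelta(seconds=float(t)) for t in times],
        probabilities=probs, classes=np.array([0, 1]), predicted=stream)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
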