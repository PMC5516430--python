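import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_series(nn_ms, subject_id="T01", session_id="Pre", start_clock_h=7.0):
    """NNSeries with beat times accumulated from the intervals."""
    from fractalhrv import NNSeries

    nn = np.asarray(nn_ms, dtype=float)
    return NNSeries(
        subject_id=subject_id,
        session_id=session_id,
        beat_times=np.cumsum(nn) / 1000.0,
        nn_ms=nn,
        start_clock_h=start_clock_h,
    )
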