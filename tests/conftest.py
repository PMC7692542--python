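import logging

import numpy as np
import pytest

from dyadsync.config import PipelineConfig, SynthConfig
from dyadsync.core import TimestampedStream, UniformSeries
from dyadsync.synthetic import generate_session

logging.getLogger("dyadsync").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def pipe_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def coupled_session():
    """One strongly coupled dyad session (alpha 0.8, lag 0.3 s, 120 s)."""
    cfg = SynthConfig(duration_s=120.0, coupling_alpha=0.8, coupling_lag_s=0.3)
    return generate_session(cfg, seed=20240917)


def make_uniform(values, rate_hz=30.0, valid=None, channels=("v",)):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if valid is None:
        valid = np.ones(len(values), dtype=bool)
    return UniformSeries(rate_hz, 0.0, channels, values, np.asarray(valid, bool))


def make_stream(timestamps, values, channels=("v",), valid=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return TimestampedStream(np.asarray(timestamps, float), values,
                             channels, valid)
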