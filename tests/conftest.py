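import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ppgstress.fiducials import extract_ac_series
from ppgstress.synthetic import CHANNELS, SimConfig, generate_subject


def clean_config(seed: int = 1, **kw) -> SimConfig:
    """Study config with sensor noise and baseline wander switched off."""
    cfg = SimConfig(seed=seed, **kw)
    return replace(cfg, noise_sd={c: 0.0 for c in CHANNELS}, wander_amplitude=0.0)


@pytest.fixture(scope="session")
def clean_subject():
    """One noise-free subject plus its green-channel extraction chain."""
    cfg = clean_config(seed=1)
    record, truth = generate_subject(cfg, 0)
    ac, fiducials, filtered = extract_ac_series(record.channel("green"), cfg.fs)
    return dict(config=cfg, record=record, truth=truth, ac=ac,
                fiducials=fiducials, filtered=filtered)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
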