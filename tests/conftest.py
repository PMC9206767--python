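from __future__ import annotations

import numpy as np
import pytest

from codmotion.pipeline import make_fixtures
from codmotion.trace import CODTrace


def axis_trace(values, counts=None, bin_duration=1.0) -> CODTrace:
    """A CODTrace carrying the same values on all three axes."""
    values = np.asarray(values, dtype=float)
    if counts is None:
        counts = np.where(np.isfinite(values), 1000, 0)
    return CODTrace(bin_duration=bin_duration, cx=values.copy(), cy=values.copy(),
                    cz=values.copy(), counts=np.asarray(counts))


@pytest.fixture(scope="session")
def fixtures(tmp_path_factory):
    """Canonical miniature inputs (step, three-level, seeded random + oracle table)."""
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixtures(seed=0, out_dir=out)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
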