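import numpy as np
import pytest

from tempoevo.phylo import Chronogram
from tempoevo.series import ActivityTimeSeries

# 6-tip ultrametric chronogram (height 1) used across comparative tests
SIX_TIP_NEWICK = (
    "((A:0.3,B:0.3):0.7,((C:0.2,D:0.2):0.5,(E:0.4,F:0.4):0.3):0.3);"
)


@pytest.fixture(scope="session")
def six_tip_tree() -> Chronogram:
    return Chronogram.from_newick(SIX_TIP_NEWICK)


@pytest.fixture(scope="session")
def star_tree() -> Chronogram:
    return Chronogram.from_newick("(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1);")


def sine_series(period_min: float, n: int = 1020, dt_s: float = 30.0,
                amplitude: float = 1.0, noise_sd: float = 0.0,
                seed: int = 0, **tags) -> ActivityTimeSeries:
    """Nonnegative sinusoid sampled like a study recording."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt_s
    x = amplitude * (1.0 + np.sin(2 * np.pi * t / (period_min * 60.0)))
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    x = x - x.min()  # keep values nonnegative
    return ActivityTimeSeries(values=x, sample_interval_s=dt_s, **tags)
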