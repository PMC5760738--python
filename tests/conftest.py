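import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@st.composite
def chain_params(draw, min_comps=1, max_comps=6, r_min=-2.0, r_max=0.0):
    """Random valid unidirectional chains: m in [0.2, 5], r in [r_min, r_max]."""
    n = draw(st.integers(min_comps, max_comps))
    m = [
        draw(st.floats(0.2, 5.0, allow_nan=False, allow_infinity=False))
        for _ in range(n)
    ]
    r = [
        draw(st.floats(r_min, r_max, allow_nan=False, allow_infinity=False))
        for _ in range(n)
    ]
    return m, r


def random_chain(rng, min_comps=3, max_comps=6):
    """Random valid chain drawn from a numpy Generator (for seeded loops)."""
    n = int(rng.integers(min_comps, max_comps + 1))
    m = rng.uniform(0.2, 5.0, size=n)
    r = rng.uniform(-2.0, 0.0, size=n)
    return m, r


@pytest.fixture
def table1_partitions():
    """Per-sample egested/retained/lysed fractions of the published fate
    experiment (three axenic and two gnotobiotic vials across three
    replicate days), plus the zero-recovery outlier replicate whose
    retained/lysed values are unknown."""
    rows = [
        dict(replicate_day=1, fly_treatment="axenic", egested=0.11, retained=0.09, lysed=0.80),
        dict(replicate_day=1, fly_treatment="axenic", egested=0.10, retained=0.03, lysed=0.87),
        dict(replicate_day=3, fly_treatment="axenic", egested=0.26, retained=0.09, lysed=0.65),
        dict(replicate_day=2, fly_treatment="gnotobiotic", egested=0.64, retained=0.10, lysed=0.25),
        dict(replicate_day=3, fly_treatment="gnotobiotic", egested=0.42, retained=0.16, lysed=0.42),
        dict(replicate_day=2, fly_treatment="axenic", egested=0.0, retained=math.nan, lysed=math.nan),
    ]
    return pd.DataFrame(rows)


def summary_cell(summary, treatment, fraction):
    row = summary[
        (summary["fly_treatment"] == treatment) & (summary["fraction"] == fraction)
    ]
    assert len(row) == 1
    return float(row["mean"].iloc[0]), float(row["sem"].iloc[0])
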