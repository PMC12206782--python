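import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gaitnld import (
    GaitRecord,
    Group,
    Phase,
    SeriesKind,
    Side,
    SimConfig,
    Unit,
    generate_cohort,
)
from gaitnld.gait_io import SERIES_COLUMNS


def make_record(
    n: int = 24,
    subject_id: str = "control1",
    group: Group = Group.CTRL,
    stride: float = 1.1,
    rng: np.random.Generator | None = None,
) -> GaitRecord:
    """Small hand-built record honouring the constructional identities
    (stance = stride - swing, percent = 100*phase/stride)."""
    rng = rng or np.random.default_rng(7)
    left = stride + 0.05 * rng.standard_normal(n)
    right = stride + 0.05 * rng.standard_normal(n)
    series = {}
    for side, s in ((Side.LEFT, left), (Side.RIGHT, right)):
        swing = 0.35 * s + 0.01 * rng.standard_normal(n)
        stance = s - swing
        series[SeriesKind(side, Phase.STRIDE, Unit.SECONDS)] = s
        series[SeriesKind(side, Phase.SWING, Unit.SECONDS)] = swing
        series[SeriesKind(side, Phase.SWING, Unit.PERCENT)] = 100 * swing / s
        series[SeriesKind(side, Phase.STANCE, Unit.SECONDS)] = stance
        series[SeriesKind(side, Phase.STANCE, Unit.PERCENT)] = 100 * stance / s
    ds = np.maximum(
        series[SeriesKind(Side.LEFT, Phase.STANCE, Unit.SECONDS)]
        + series[SeriesKind(Side.RIGHT, Phase.STANCE, Unit.SECONDS)]
        - left,
        0.01,
    )
    series[SeriesKind(Side.BOTH, Phase.DOUBLE_SUPPORT, Unit.SECONDS)] = ds
    series[SeriesKind(Side.BOTH, Phase.DOUBLE_SUPPORT, Unit.PERCENT)] = 100 * ds / left
    return GaitRecord(
        subject_id=subject_id, group=group, elapsed_time=np.cumsum(left), series=series
    )


@pytest.fixture(scope="session")
def small_record() -> GaitRecord:
    return make_record()


@pytest.fixture(scope="session")
def default_cohort():
    """One full synthetic cohort at the documented seed, shared across tests."""
    return generate_cohort(SimConfig(seed=42))
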