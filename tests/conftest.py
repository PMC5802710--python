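import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epmcbc import BehaviorTable, MeasureSpec, ProfilingConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def three_measure_config():
    """Small configuration: three measures, q=0.2, k=2, open group list."""
    return ProfilingConfig(
        measures=(
            MeasureSpec("m1", "cm", "flag-low"),
            MeasureSpec("m2", "s", "flag-high"),
            MeasureSpec("m3", "ratio", "flag-low"),
        ),
        q=0.2,
        criterion_k=2,
        control_group="control",
        groups=(),
        min_control_n=5,
    )


@pytest.fixture
def ladder_table(three_measure_config):
    """Ten control animals whose measures are the ladder 1..10."""
    rows = [
        {"animal_id": f"c{i}", "group": "control",
         "m1": float(i), "m2": float(i), "m3": float(i)}
        for i in range(1, 11)
    ]
    return BehaviorTable.from_records(rows, three_measure_config.measure_names)


def random_table(rng: np.random.Generator, n: int, measures, group="control"):
    """Distinct-valued helper table for property tests."""
    rows = []
    for i in range(n):
        rec = {"animal_id": f"{group}-{i}", "group": group}
        rec.update({m: float(v) for m, v in zip(measures, rng.random(len(measures)) * 100)})
        rows.append(rec)
    return BehaviorTable.from_records(rows, measures)
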