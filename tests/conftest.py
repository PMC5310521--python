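import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vehitox as vt

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_key(compound_id="cmpd1", **overrides):
    base = dict(
        compound_id=compound_id,
        route="ip",
        species="mouse",
        n_injections=1,
        injection_interval=1,
        first_injection_day=1,
        n_repetitions=1,
        assessment_day=5,
        restart_days=(),
    )
    base.update(overrides)
    return vt.ConditionKey(**base)


def make_curve(points, compound_id="cmpd1", vehicle="saline", **key_overrides):
    return vt.AggregateCurve(
        key=make_key(compound_id, **key_overrides),
        vehicle=vehicle,
        points=tuple(points),
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """120-compound dataset with ten predictive binary keys shifting ln LD50 by 2."""
    config = vt.SimulationConfig(n_compounds=120, effect_fraction=1.0, seed=11)
    records, truth, features = vt.simulate(config)
    curves = vt.aggregate(records)
    verdicts, _ = vt.compare_conditions(curves, "saline", "CMC", "highlow", 30)
    dataset = vt.build_dataset(vt.roll_up(verdicts), features, min_n=50)
    return dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
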