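import numpy as np
import pytest

from accethogram.synthgen import default_cohort_config, simulate_cohort
from accethogram.types import BehaviourSpec, CohortConfig, PositionEffect


def single_behaviour_config(spec: BehaviourSpec, duration_s: float = 60.0, **kw) -> CohortConfig:
    """Minimal one-behaviour cohort config used by many unit tests."""
    defaults = dict(
        species="test",
        n_individuals=4,
        behaviours=[spec],
        transition_weights=np.zeros((1, 1)),
        duration_s=duration_s,
        position_effect={"scute1": PositionEffect(), "scute3": PositionEffect()},
        seed=0,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default cohort shared by read-only tests."""
    cfg = default_cohort_config(seed=7, n_individuals=4, duration_s=120)
    return cfg, simulate_cohort(cfg)
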