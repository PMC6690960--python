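import numpy as np
import pytest

from recoilkit import BI213, CountingSeries, ingrowth_activity

LAM2 = BI213.lam_per_min  # min^-1


@pytest.fixture
def lam2() -> float:
    return LAM2


@pytest.fixture
def schedule() -> np.ndarray:
    """10-min counting cycles over 18 h."""
    return np.arange(0.0, 1081.0, 10.0)


@pytest.fixture
def make_series(schedule):
    """Factory for noise-free ingrowth series with given amplitudes."""

    def _make(a_eq: float, a0: float, times=None, organ="organ", animal="a1"):
        t = schedule if times is None else np.asarray(times, dtype=float)
        return CountingSeries(animal_id=animal, organ=organ, times_min=t,
                              values=ingrowth_activity(a_eq, a0, LAM2, t))

    return _make
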