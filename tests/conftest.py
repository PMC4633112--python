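import numpy as np
import pytest

from scrkit.data import CaptureHistory, OccasionCalendar, TrapArray
from scrkit.simulate import default_config, simulate_dataset


@pytest.fixture
def square_traps() -> TrapArray:
    """2x2 unit square of traps."""
    return TrapArray(
        trap_id=("A", "B", "C", "D"),
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
    )


@pytest.fixture
def tiny_history(square_traps) -> CaptureHistory:
    """Two individuals, four traps, three daily occasions."""
    y = np.zeros((2, 4, 3), dtype=int)
    y[0, 0, 0] = 1
    y[0, 1, 2] = 1
    y[1, 3, 1] = 1
    return CaptureHistory(
        y=y,
        individual_id=("i1", "i2"),
        sex=np.array(["F", "M"]),
        calendar=OccasionCalendar.daily(3),
        traps=square_traps,
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """One reference-protocol simulated dataset (seed-pinned)."""
    return simulate_dataset(default_config(), seed=42)
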