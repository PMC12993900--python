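import numpy as np
import pandas as pd
import pytest

from glyco.io_formats import GlucoseTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20240304)


@pytest.fixture
def toy_trace():
    """The worked excursion example: 10 samples at 5-min spacing."""
    return GlucoseTrace.from_values(
        [100, 105, 120, 130, 115, 100, 85, 80, 95, 100], source="repaired"
    )


@pytest.fixture
def random_trace(rng):
    """100-point raw trace with a couple of missing readings."""
    values = 100 + 15 * np.sin(np.arange(100) / 7.0) + rng.normal(0, 3, 100)
    values[[20, 45, 46, 47]] = np.nan
    return GlucoseTrace.from_values(values, animal_id="pig01")


def make_trace(values, step_min=5.0, start="2024-01-01 00:00", source="repaired"):
    return GlucoseTrace.from_values(values, start=start, step_min=step_min, source=source)
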