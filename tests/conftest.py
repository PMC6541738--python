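import numpy as np
import pytest

from duotune import (
    MeasurementParams,
    density_gate,
    fit_values,
    simulate_control_sample,
)


@pytest.fixture(scope="session")
def measurement() -> MeasurementParams:
    return MeasurementParams()


@pytest.fixture(scope="session")
def control_mean(measurement) -> float:
    """Gated + fitted mean of one default autofluorescence-only control."""
    ctrl = simulate_control_sample(measurement, seed=np.random.SeedSequence(987))
    gate = density_gate(ctrl, 1.0 / 3.0)
    return fit_values(ctrl.column("fl1_area")[gate.retain]).mu


def gated_fit_mean(table, n_bins: int = 48, column: str = "fl1_area") -> float:
    gate = density_gate(table, 1.0 / 3.0)
    return fit_values(table.column(column)[gate.retain], n_bins=n_bins).mu
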