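import numpy as np
import pytest

from meascreen.io import PlateLayout
from meascreen.simulate import WellActivityParams, simulate_spike_trains


@pytest.fixture
def one_well_layout():
    return PlateLayout("test", n_wells=1, electrodes_per_well=16)


@pytest.fixture
def poisson_params():
    """Pure Poisson firing: no bursts, no rate heterogeneity."""
    return WellActivityParams(
        baseline_rate=3.0, burst_rate=0.0, rate_cv=0.0, fraction_active=1.0
    )


@pytest.fixture
def poisson_plate(one_well_layout, poisson_params):
    trains, truth = simulate_spike_trains(
        one_well_layout, poisson_params, duration=300.0, seed=11
    )
    return trains, truth


def match_trains(true_ts, found_ts, tol=0.0005):
    """Greedy one-to-one timestamp matching within ±tol seconds."""
    i = j = tp = 0
    true_ts = np.asarray(true_ts)
    found_ts = np.asarray(found_ts)
    while i < true_ts.size and j < found_ts.size:
        if abs(true_ts[i] - found_ts[j]) <= tol:
            tp += 1
            i += 1
            j += 1
        elif found_ts[j] < true_ts[i] - tol:
            j += 1
        else:
            i += 1
    return tp


@pytest.fixture
def spike_matcher():
    return match_trains
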