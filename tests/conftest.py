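"""Shared fixtures: small synthetic cohorts generated at test time."""

import pytest

from resilio.preprocessing import filter_probes
from resilio.synthetic import (dose_response_scenario, null_scenario,
                               simulate_dataset)

# one small RF configuration keeps the resampling loops desk-scale
RF_GRID = ({"mtry": "sqrt", "n_trees": 50, "min_node": 1, "max_depth": None},)


@pytest.fixture(scope="session")
def spiked_cohort():
    """3,000-probe, 200-sample cohort with 3 dose-responsive spiked regions."""
    cfg = dose_response_scenario(n_probes=3000, n_samples=200, seed=3)
    ds, truth = simulate_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def spiked_filtered(spiked_cohort):
    _, ds, truth = spiked_cohort
    filtered, report = filter_probes(ds)
    return filtered, truth, report


@pytest.fixture(scope="session")
def null_cohort():
    """2,000-probe, 80-sample pure-noise cohort (no spikes/effects)."""
    cfg = null_scenario(n_probes=2000, n_samples=80, seed=17)
    ds, truth = simulate_dataset(cfg)
    return cfg, ds, truth
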