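import numpy as np
import pytest

from catrace.data import CohortConfig, GroupParams, TimeGrid


@pytest.fixture(scope="session")
def small_grid() -> TimeGrid:
    """Short grid (2.5 min at 2 Hz) for fast unit tests."""
    return TimeGrid(n_frames=300, rate=2.0, lh_start=120, lh_end=192)


def small_group(**overrides) -> GroupParams:
    base = dict(responder_fraction=0.9, peak_amp_mean=0.4, peak_amp_sd=0.1,
                latency_mean=5.0, latency_sd=2.0, rise_tau=8.0, decay_tau=20.0,
                basal_osc_amp=0.04, basal_osc_freq_range=(0.02, 0.08),
                drift_amp=0.02, noise_sd=0.02)
    base.update(overrides)
    return GroupParams(**base)


@pytest.fixture
def small_cohort_config(small_grid) -> CohortConfig:
    het = small_group()
    hom = small_group(responder_fraction=0.3, peak_amp_mean=0.25,
                      latency_mean=12.0, rise_tau=20.0, decay_tau=8.0,
                      basal_osc_amp=0.025, basal_osc_freq_range=(0.10, 0.16))
    return CohortConfig(grid=small_grid,
                        groups={"HET": (het, 40, 3), "HOM": (hom, 40, 3)},
                        seed=7, sex="male")
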