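import numpy as np
import pytest

from ventriculometry import CohortConfig, LinearMeasurementSet, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A 35-vs-39 cohort simulated at the default (published) parameters."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture
def example_measurements():
    """Round-number measurement set: BLM 0.25, MRHI 0.5, EI 35/120."""
    return LinearMeasurementSet(
        fh_width=35.0,
        oh_width=30.0,
        th_width=10.0,
        bip_at_fh=105.0,
        bip_at_oh=100.0,
        bit_at_th=95.0,
        ctw=60.0,
        inner_skull_diameter=120.0,
        ei_skull_diameter=120.0,
    )


def brute_force_auc(pos, neg):
    """All-pairs rank statistic: wins + half-ties over n_pos * n_neg."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    wins = sum(float(p > n) + 0.5 * float(p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)
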