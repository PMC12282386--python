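import numpy as np
import pytest

from angiopattern import resample_curve, simulate_cohort


def make_step_curve(length=80.0, drop=0.30, start=36.0, width=7.0, spacing=0.35, top=1.0):
    """Piecewise-linear pullback: flat, a linear drop over `width` mm, flat."""
    raw_pos = [0.0, start, start + width, length]
    raw_val = [top, top, top - drop, top - drop]
    return resample_curve(raw_pos, raw_val, spacing)


def make_ramp_curve(length=80.0, top=1.0, bottom=0.70, spacing=0.35):
    """Uniform linear decline over the whole vessel."""
    return resample_curve([0.0, length], [top, bottom], spacing)


@pytest.fixture
def step_curve():
    return make_step_curve()


@pytest.fixture
def ramp_curve():
    return make_ramp_curve()


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-vessel synthetic cohort shared across tests (seed-fixed)."""
    return simulate_cohort(80, rng_seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """The 343-vessel cohort at the reference class proportions, seed 1."""
    return simulate_cohort(343, rng_seed=1)
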