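import numpy as np
import pytest

from nprm.comp2c import TwoCParams, residue_2c
from nprm.frames import build_schedule, fit_weights
from nprm.phantom import AifParams, make_aif, default_phantom_schedule


@pytest.fixture(scope="session")
def full_schedule():
    """The 62-frame, 65-min acquisition layout."""
    return default_phantom_schedule()


@pytest.fixture(scope="session")
def short_schedule():
    """A fast 25-frame, ~12-min layout for unit tests."""
    return build_schedule([(4, 5), (8, 10), (6, 30), (7, 60)])


@pytest.fixture(scope="session")
def short_weights(short_schedule):
    return fit_weights(short_schedule)


@pytest.fixture(scope="session")
def full_weights(full_schedule):
    return fit_weights(full_schedule)


@pytest.fixture(scope="session")
def short_aif(short_schedule):
    return make_aif(AifParams(), short_schedule)


@pytest.fixture(scope="session")
def full_aif(full_schedule):
    return make_aif(AifParams(), full_schedule)


@pytest.fixture(scope="session")
def truth_residues(short_schedule):
    """Three distinct admissible residues defined through the short schedule."""
    T = short_schedule.total_duration_s
    from nprm.residue import Residue

    r1 = residue_2c(TwoCParams(0.30, 0.40, 0.06, 0.0, 0.05), T_end_s=T)
    r2 = residue_2c(TwoCParams(0.55, 0.65, 0.01, 0.0, 0.09), T_end_s=T)
    grid = np.union1d(np.arange(0.0, 61.0, 2.0), np.arange(60.0, T + 1e-9, 10.0))
    grid = np.union1d(grid, [T])
    vals = np.where(grid <= 45.0, 0.45, 0.02 + 0.43 * np.exp(-(grid - 45.0) / 90.0))
    r3 = Residue(grid, vals)
    return [r1, r2, r3]


@pytest.fixture(scope="session")
def truth_basis(truth_residues, short_schedule, short_aif):
    from nprm.basis import TissueBasisSet

    return TissueBasisSet(truth_residues, [0.0, 4.0, 8.0], short_schedule, short_aif)
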