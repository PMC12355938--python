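import numpy as np
import pytest

import tprs
from tprs.designs import PhaseSample


@pytest.fixture(scope="session")
def pop_beta2():
    """Moderate-size benchmark population (beta=2, superpopulation R^2=0.8)."""
    return tprs.make_simulation_population(20_000, 2.0, seed=101)


@pytest.fixture(scope="session")
def pop_tiny():
    """Eight-unit population for exhaustive enumeration checks."""
    rng = np.random.default_rng(42)
    return tprs.FinitePopulation(
        unit_id=np.arange(8), x=rng.normal(size=8), y=rng.normal(size=8)
    )


@pytest.fixture(scope="session")
def two_phase_srs(pop_beta2):
    """A plain (non-rejective) two-phase SRS draw: nI=1000, nII=200."""
    sI = tprs.draw_srs(pop_beta2, 1000, seed=7)
    sII = tprs.draw_srs(sI, 200, seed=8)
    return sI, sII


def manual_phase2(parent, selected, design_info=None):
    """Build a phase-2 SRS PhaseSample with explicit membership (test helper)."""
    selected = np.asarray(selected)
    M = parent.n
    n = selected.size
    pi = n / M
    pos = np.searchsorted(parent.selected, selected)
    return PhaseSample(
        selected=selected,
        cond_pi=np.full(n, pi),
        cum_pistar=parent.cum_pistar[pos] * pi,
        design_kind="srs",
        parent=parent,
        phase_index=parent.phase_index + 1,
        design_info=design_info or {"n": int(n), "M": int(M)},
    )
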