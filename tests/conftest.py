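"""Shared fixtures: a Brownian-dynamics trace reused by the end-to-end tests.

The 60-s particle simulation is the most expensive fixture (minutes at
desk scale), so it is computed once per session and shared by every test
that consumes the photon trace or its segment-averaged ACF.
"""

import numpy as np
import pytest

import rnpquant as rq
from rnpquant.simulate import FcsSimConfig, SimSpecies, simulate_fcs_trace


OMEGA1_CM = 2.04e-5
S_FACTOR = 0.17
TAU_TRUE = 1e-3  # s
N_TRUE = 5.0  # mean molecules in V_eff


@pytest.fixture(scope="session")
def bd_truth():
    v_eff = rq.effective_volume(OMEGA1_CM, S_FACTOR)
    return {
        "omega1_cm": OMEGA1_CM,
        "s": S_FACTOR,
        "tau_diff_s": TAU_TRUE,
        "n_molecules": N_TRUE,
        "v_eff_l": v_eff,
        "concentration_m": N_TRUE / (rq.CONSTANTS.avogadro * v_eff),
    }


@pytest.fixture(scope="session")
def bd_trace(bd_truth):
    """60-s photon trace of one species at <N>=5 in V_eff (seeded)."""
    cfg = FcsSimConfig(
        species=(
            SimSpecies(
                concentration_m=bd_truth["concentration_m"], tau_diff_s=TAU_TRUE
            ),
        ),
        omega1_cm=OMEGA1_CM,
        structure_factor=S_FACTOR,
        duration_s=60.0,
        seed=1,
    )
    return simulate_fcs_trace(cfg)


@pytest.fixture(scope="session")
def bd_acf(bd_trace):
    return rq.segment_and_average(bd_trace, n_segments=10)
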