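"""Shared fixtures: small synthetic ensembles and the (expensive) shared
well-tempered metadynamics run on the calibrated double well."""

import numpy as np
import pytest

from switchscape.core import KT_300
from switchscape.metad import DoubleWell1D, IdentityCV, wt_metad
from switchscape.synthetic import StateSpec, gen_loop_ensemble, gen_reference_pair


@pytest.fixture(scope="session")
def two_state_spec():
    return StateSpec.two_state(separation_deg=90.0, kappa=50.0,
                               weights=(0.5, 0.5))


@pytest.fixture(scope="session")
def small_loop(two_state_spec):
    """200-frame two-state 13-residue loop ensemble with ground truth."""
    ens, labels = gen_loop_ensemble(two_state_spec, n_res=13, n_frames=200,
                                    seed=11)
    return ens, labels


@pytest.fixture(scope="session")
def reference_pair(two_state_spec):
    return gen_reference_pair(two_state_spec, n_res=13)


@pytest.fixture(scope="session")
def double_well_run():
    """One well-tempered metadynamics run on the kT-calibrated double well
    (dG = 2.0 kcal/mol, barrier = 4.0 kcal/mol), shared by the estimator
    tests.  1e6 overdamped Langevin steps, hills every 0.5 ps."""
    pot = DoubleWell1D.with_free_energy(delta_g=2.0, barrier=4.0, kT=KT_300)
    traj, bias = wt_metad(
        pot, [IdentityCV(pot.domain)], W=0.1, widths=0.1, stride_ps=0.5,
        bias_factor=10.0, kT=KT_300, dt=0.002, n_steps=1_000_000,
        friction=1.0, seed=7, x0=pot.minima()[0], record_stride=10)
    return pot, traj, bias


@pytest.fixture(scope="session")
def fes_grid():
    return [np.linspace(-2.0, 2.0, 161)]
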