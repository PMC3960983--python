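"""Shared fixtures: thermodynamic state and the long Langevin runs reused by
sampling/reweighting tests (session-scoped — each takes a few seconds)."""

import pytest

import amdkit as ak

#: Double-well study conditions used by the sampling and flattening tests:
#: 2 kcal/mol barrier (≈3.4 k_BT at 300 K), wells at ±1.
DW_BARRIER = 2.0
DW_SEP = 1.0
#: Moderate-acceleration boost: reference energy just above the barrier.
BOOST_E = 2.5
BOOST_ALPHA = 2.5

LONG_STEPS = 1_000_000
SAVE_STRIDE = 100
SEED = 11


@pytest.fixture(scope="session")
def state():
    return ak.ThermodynamicState(temperature=300.0)


@pytest.fixture(scope="session")
def double_well():
    return ak.make_double_well(DW_BARRIER, DW_SEP)


@pytest.fixture(scope="session")
def unboosted_run(double_well):
    cfg = ak.SimulationConfig(
        timestep=0.01, friction=1.0, temperature=300.0,
        n_steps=LONG_STEPS, save_stride=SAVE_STRIDE, rng_seed=SEED,
        initial_position=-1.0,
    )
    return ak.langevin_simulate(double_well, cfg)


@pytest.fixture(scope="session")
def boosted_run(double_well):
    cfg = ak.SimulationConfig(
        timestep=0.01, friction=1.0, temperature=300.0,
        n_steps=LONG_STEPS, save_stride=SAVE_STRIDE, rng_seed=SEED,
        initial_position=-1.0,
        boost=ak.BoostSpec(BOOST_E, BOOST_ALPHA),
    )
    return ak.langevin_simulate(double_well, cfg)


@pytest.fixture(scope="session")
def boosted_series(boosted_run):
    return ak.RCSeries(
        boosted_run.coordinate(), unit="reduced", name="x",
        delta_v=boosted_run.delta_v,
    )


@pytest.fixture(scope="session")
def ionic_lock_series():
    """10⁵-frame synthetic three-well ionic-lock distance series (defaults)."""
    return ak.synth_rc_series(n_frames=100_000, rng_seed=17)
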