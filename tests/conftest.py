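import numpy as np
import pytest

import fsacreg as fr


@pytest.fixture(scope="session")
def lattice_5x5():
    return fr.build_lattice_weights(5, 5, "rook")


@pytest.fixture(scope="session")
def lattice_7x7():
    return fr.build_lattice_weights(7, 7, "rook")


@pytest.fixture(scope="session")
def brownian_2000():
    return fr.simulate_brownian_curves(2000, 101, seed=42)


def make_problem(R=7, T=7, rho=0.3, lam=0.5, seed=7, p=60, variant="fsac"):
    """One simulated dataset reduced to an FSACSpec ready to fit."""
    cfg = fr.SimulationConfig(R=R, T=T, rho=rho, lam=lam, reps=1, seed=seed, p=p)
    y, curves, w = fr.generate_dataset(cfg, cfg.rep_seed(0))
    basis = fr.fpca(curves)
    sc = fr.scores(curves, basis)
    return fr.FSACSpec(y, sc, w, variant=variant), basis, curves


@pytest.fixture(scope="session")
def small_problem():
    return make_problem()
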