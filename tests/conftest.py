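"""Shared fixtures: expensive sampling runs are session-scoped so the
double-well calibration and the cryptic-toy production are computed once."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from mcfold import engine, reweight, synth

warnings.filterwarnings("ignore", message=".*empty energy bins.*")
warnings.filterwarnings("ignore", message=".*effective sample size.*")
warnings.filterwarnings("ignore", message=".*probability mass outside.*")


@pytest.fixture(scope="session")
def dw1_system():
    return synth.make_double_well(3.0)


@pytest.fixture(scope="session")
def dw2_run():
    """Calibrated 2-D double-well multicanonical run with 1e5 frames."""
    system, oracle = synth.make_double_well(3.0, dims=2)
    cfg = engine.McMDConfig(base_seed=5, n_parallel=20, save_interval=2,
                            bin_width=0.1)
    bias, _, diag = engine.calibrate_bias(system, cfg)
    production = engine.run_mcmd(system, bias, 10000, seed=11, n_walkers=20,
                                 save_interval=2)
    return {"system": system, "oracle": oracle, "cfg": cfg, "bias": bias,
            "production": production, "diagnostics": diag}


@pytest.fixture(scope="session")
def dw1_run():
    """1-D double-well multicanonical run (fine bias bins) with 1e5 frames."""
    system, oracle = synth.make_double_well(3.0, dims=1)
    cfg = engine.McMDConfig(base_seed=3, n_parallel=20, save_interval=2,
                            bin_width=0.05)
    bias, _, _ = engine.calibrate_bias(system, cfg)
    production = engine.run_mcmd(system, bias, 10000, seed=99, n_walkers=20,
                                 save_interval=2)
    return {"system": system, "oracle": oracle, "cfg": cfg, "bias": bias,
            "production": production}


CRYPTIC_SCHEDULE = (1500, 1500, 2000, 2000, 3000, 3000, 4000, 4000, 5000)


@pytest.fixture(scope="session")
def cryptic_run():
    """Cryptic-toy McMD: calibration plus a 20-trajectory production run."""
    system, oracle = synth.make_cryptic_toy()
    cfg = engine.McMDConfig(base_seed=1, n_parallel=20, save_interval=5,
                            schedule=CRYPTIC_SCHEDULE)
    bias, _, diag = engine.calibrate_bias(system, cfg)
    production = engine.run_mcmd(system, bias, 30000, seed=42, n_walkers=20,
                                 save_interval=5)
    weights = reweight.canonical_weights(production, bias, 300.0)
    return {"system": system, "oracle": oracle, "cfg": cfg, "bias": bias,
            "production": production, "weights": weights,
            "diagnostics": diag}


@pytest.fixture(scope="session")
def planted_two():
    return synth.two_mode_ensemble(600, seed=3)


@pytest.fixture(scope="session")
def planted_five():
    return synth.five_mode_ensemble(1500, seed=4)


def identity_weights(ens, t_target=300.0):
    """Canonical weights for a planted ensemble (identity bias at its T_mc)."""
    bias = engine.BiasFunction.identity(
        float(ens.metadata.get("t_mc", 700.0)),
        (ens.energies.min() - 1.0, ens.energies.max() + 1.0))
    return reweight.canonical_weights(ens, bias, t_target)
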