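"""Sampler, restraints and the multicanonical bias machinery."""

import numpy as np
import pytest

from mcfold import engine, reweight, synth
from mcfold.constants import R_KCAL
from mcfold.engine import (BiasFunction, HarmonicWell, McMDConfig,
                           RestraintSpec, ToySystem, estimate_initial_bias,
                           restraint_energy, run_canonical, run_mcmd,
                           update_bias)
from mcfold.synth import _bead_topology


def _one_particle_system(term, dims=1, step=0.5):
    top = _bead_topology([("A", "ligand", 1, np.zeros((1, dims)))], {"A": "ligand"})
    return ToySystem(top, [term], step_size=step)


# ---------------------------------------------------------------------------
# Restraints
# ---------------------------------------------------------------------------


class TestRestraints:
    def test_flat_region_is_zero(self):
        spec = RestraintSpec("flat_bottom_distance", np.array([0]),
                             np.array([1]), lower=0.0, upper=4.5, k=10.0)
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        assert restraint_energy(coords, spec) == 0.0

    def test_quadratic_beyond_flat_region(self):
        spec = RestraintSpec("flat_bottom_distance", np.array([0]),
                             np.array([1]), lower=0.0, upper=4.5, k=10.0)
        coords = np.array([[0.0, 0.0, 0.0], [5.5, 0.0, 0.0]])
        # excess 1.0 A at k = 10 kcal/mol/A^2
        assert restraint_energy(coords, spec) == pytest.approx(10.0)

    def test_com_axis_box_inside_is_zero(self):
        spec = RestraintSpec("com_axis_box", np.array([0, 1]), lower=-2.5,
                             upper=40.0, k=10.0, axis=0)
        coords = np.array([[8.0, 0.0, 0.0], [12.0, 0.0, 0.0]])  # COM x = 10
        assert restraint_energy(coords, spec) == 0.0

    def test_com_axis_box_outside(self):
        spec = RestraintSpec("com_axis_box", np.array([0]), lower=-2.5,
                             upper=40.0, k=10.0, axis=0)
        coords = np.array([[42.0, 0.0, 0.0]])
        assert restraint_energy(coords, spec) == pytest.approx(10.0 * 2.0**2)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            RestraintSpec("flat_bottom_distance", np.array([0]), np.array([1]),
                          lower=5.0, upper=1.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty selection"):
            RestraintSpec("com_axis_box", np.array([]), lower=0, upper=1)


class TestForceConsistency:
    """Analytic forces match central finite differences for every term."""

    def test_all_cryptic_terms(self):
        system, _ = synth.make_cryptic_toy()
        rng = np.random.default_rng(0)
        x = system.x0 + 0.1 * rng.standard_normal(system.x0.shape)
        f = system.force(x)
        h = 1e-6
        fd = np.zeros_like(x)
        for i in range(x.shape[0]):
            for d in range(x.shape[1]):
                xp, xm = x.copy(), x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                fd[i, d] = -(system.energy(xp) - system.energy(xm)) / (2 * h)
        scale = np.max(np.abs(fd))
        assert np.max(np.abs(f - fd)) / scale < 1e-5

    def test_double_well_force(self, dw1_system):
        system, _ = dw1_system
        x = np.array([[0.37]])
        h = 1e-6
        fd = -(system.energy(np.array([[0.37 + h]]))
               - system.energy(np.array([[0.37 - h]]))) / (2 * h)
        assert system.force(x)[0, 0] == pytest.approx(fd, rel=1e-5)


# ---------------------------------------------------------------------------
# Canonical sampling
# ---------------------------------------------------------------------------


class TestCanonicalSampling:
    def test_equipartition_harmonic_well(self):
        system = _one_particle_system(HarmonicWell(0, kappa=2.0))
        ens = run_canonical(system, 300.0, 4000, seed=1, n_walkers=10,
                            save_interval=2)
        expected = 0.5 * R_KCAL * 300.0  # <U> = RT/2 per quadratic DOF
        se = ens.energies.std() / np.sqrt(len(ens) / 50)  # crude corr. factor
        assert abs(ens.energies.mean() - expected) < 3 * se + 0.01

    def test_quench_energy_non_increasing(self):
        system = _one_particle_system(HarmonicWell(0, kappa=2.0))
        x0 = np.array([[5.0]])
        ens = run_canonical(system, 0.0, 500, seed=2, save_interval=1,
                            x0=x0, quench=True)
        assert np.all(np.diff(ens.energies) <= 1e-12)

    def test_same_seed_identical_energy_series(self):
        system = _one_particle_system(HarmonicWell(0, kappa=2.0))
        e1 = run_canonical(system, 300.0, 200, seed=7, n_walkers=3,
                           save_interval=2).energies
        e2 = run_canonical(system, 300.0, 200, seed=7, n_walkers=3,
                           save_interval=2).energies
        np.testing.assert_array_equal(e1, e2)

    def test_nonpositive_temperature_rejected(self):
        system = _one_particle_system(HarmonicWell(0, kappa=2.0))
        with pytest.raises(ValueError):
            run_canonical(system, -1.0, 10, seed=0)

    def test_canonical_well_populations_match_boltzmann(self):
        """Acceptance rule reproduces the canonical two-well distribution."""
        system, oracle = synth.make_double_well(2.0, asymmetry=1.0)
        ens = run_canonical(system, 400.0, 6000, seed=3, n_walkers=16,
                            save_interval=2)
        left = (ens.coords[:, 0, 0] < 0).mean()
        expected, _ = oracle.well_populations(400.0)
        assert left == pytest.approx(expected, abs=0.05)


# ---------------------------------------------------------------------------
# Bias estimation and update
# ---------------------------------------------------------------------------


class TestBiasFunction:
    def test_identity_bias(self):
        b = BiasFunction.identity(700.0, (0.0, 10.0))
        e = np.linspace(-5, 15, 50)
        np.testing.assert_allclose(b(e), e, atol=1e-9)

    def test_monotone_after_construction(self):
        rng = np.random.default_rng(1)
        knots = np.linspace(0, 5, 20)
        values = np.cumsum(np.abs(rng.normal(size=20))) + rng.normal(0, 0.2, 20)
        b = BiasFunction(knots, values, 700.0)
        assert b.is_monotone()

    def test_too_few_bins_is_error(self):
        system = _one_particle_system(HarmonicWell(0, kappa=2.0))
        # quench run collapses to near-constant energy -> too few bins
        ens = run_canonical(system, 0.0, 50, seed=0, save_interval=1,
                            quench=True, x0=np.array([[0.01]]))
        with pytest.raises(ValueError, match="bins"):
            estimate_initial_bias(ens, McMDConfig(bin_width=0.5))


class TestUpdateBias:
    def _flat_production(self, bias, energies):
        top = _bead_topology([("A", "ligand", 1, np.zeros((1, 1)))], {"A": "ligand"})
        from mcfold.core import Ensemble
        coords = np.zeros((len(energies), 1, 1))
        return Ensemble(top, coords, energies, metadata={"t_mc": bias.t_mc})

    def test_flat_histogram_is_fixed_point(self):
        cfg = McMDConfig(bin_width=0.5, smooth_window=0)
        bias = BiasFunction.identity(700.0, (0.0, 10.0))
        energies = np.repeat(np.arange(0.25, 10.0, 0.5), 100)
        new = update_bias(bias, self._flat_production(bias, energies), cfg)
        e = np.linspace(0.5, 9.5, 50)
        delta = new(e) - bias(e)
        assert np.ptp(delta) < 1e-6  # constant shift only

    def test_overpopulated_bin_raised_by_rt_ln2(self):
        cfg = McMDConfig(bin_width=0.5, smooth_window=0)
        bias = BiasFunction.identity(700.0, (0.0, 10.0))
        energies = np.repeat(np.arange(0.25, 10.0, 0.5), 100)
        doubled = np.concatenate([energies, np.full(100, 5.25)])
        new = update_bias(bias, self._flat_production(bias, doubled), cfg)
        e = np.linspace(0.5, 9.5, 200)
        delta = new(e) - bias(e)
        bump = delta[np.argmin(np.abs(e - 5.25))] - np.median(delta)
        assert bump == pytest.approx(R_KCAL * 700.0 * np.log(2), rel=0.05)

    def test_monotonicity_preserved_after_update(self, dw2_run):
        cfg = dw2_run["cfg"]
        new = update_bias(dw2_run["bias"], dw2_run["production"], cfg)
        assert new.is_monotone()


class TestMcMD:
    def test_flatness_reached_within_schedule(self, dw2_run):
        history = dw2_run["diagnostics"]["history"]
        assert len(history) <= 8
        assert history[-1]["flatness"] <= dw2_run["cfg"].flatness_tol

    def test_identity_bias_matches_canonical(self):
        """With E_mc = E and T_mc = T, multicanonical sampling is canonical."""
        from scipy.stats import ks_2samp

        system = _one_particle_system(HarmonicWell(0, kappa=2.0))
        bias = BiasFunction.identity(300.0, (0.0, 5.0))
        mc = run_mcmd(system, bias, 2500, seed=4, n_walkers=4, save_interval=2)
        ca = run_canonical(system, 300.0, 2500, seed=8, n_walkers=4,
                           save_interval=2)
        assert ks_2samp(mc.energies, ca.energies).pvalue > 0.01

    def test_parallel_trajectories_distinct(self):
        system = _one_particle_system(HarmonicWell(0, kappa=2.0))
        ens = run_canonical(system, 300.0, 100, seed=5, n_walkers=30,
                            save_interval=2)
        assert len(np.unique(ens.traj_ids)) == 30
        by_traj = [ens.energies[ens.traj_ids == t] for t in range(30)]
        assert not np.allclose(by_traj[0], by_traj[1])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            McMDConfig(t_low=700.0, t_high=280.0)
        with pytest.raises(ValueError):
            McMDConfig(schedule=(100, -1))
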