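"""Distance features, PCA and free-energy landscapes."""

import numpy as np
import pytest

from mcfold import fel
from mcfold.constants import R_KCAL
from mcfold.core import Ensemble
from mcfold.fel import (FeatureMatrix, Projection, SelectionSpec,
                        build_distance_features, compute_fel, default_grid,
                        fel_value_at, pca_fit_project)
from mcfold.reweight import WeightVector
from mcfold.synth import _bead_topology


def _chain_topology(n=6):
    coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
    return _bead_topology([("L", "ligand", n, coords)], {"L": "ligand"})


class TestSelections:
    def test_exclusion_window_brute_force(self):
        """6-residue chain, i±3 exclusion keeps exactly (1,5), (1,6), (2,6)."""
        top = _chain_topology(6)
        spec = SelectionSpec.build(top, receptor_anchors=np.array([], dtype=int),
                                   ligand_atoms=np.arange(6), exclusion=3)
        # brute-force oracle over residue indices
        expected = {(i, j) for i in range(6) for j in range(i + 1, 6)
                    if abs((i + 1) - (j + 1)) > 3}
        got = {tuple(p) for p in spec.pairs}
        assert got == expected == {(0, 4), (0, 5), (1, 5)}

    def test_self_pairs_rejected(self):
        with pytest.raises(ValueError, match="self-pairs"):
            SelectionSpec(np.array([[2, 2]]))

    def test_intermolecular_pairs_cross_roles(self):
        rec = np.zeros((2, 3))
        lig = np.ones((3, 3))
        top = _bead_topology([("R", "receptor", 2, rec), ("L", "ligand", 3, lig)],
                             {"R": "receptor", "L": "ligand"})
        spec = SelectionSpec.build(top, intra_ligand=False)
        assert len(spec) == 6  # 2 anchors x 3 ligand atoms


class TestDistanceFeatures:
    def test_fixed_distances_per_frame(self):
        top = _chain_topology(2)
        coords = np.zeros((2, 2, 3))
        coords[0, 1, 0] = 3.0
        coords[1, 1, 0] = 4.0
        ens = Ensemble(top, coords, np.zeros(2))
        spec = SelectionSpec(np.array([[0, 1]]))
        feats = build_distance_features(ens, spec)
        np.testing.assert_allclose(feats.values[:, 0], [3.0, 4.0])

    def test_rotation_translation_invariance(self):
        """Distance features are invariant to per-frame rigid motion."""
        from scipy.spatial.transform import Rotation

        top = _chain_topology(5)
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 3)) * 3.0
        rot = Rotation.random(4, rng=1).as_matrix()
        coords = np.stack([base @ r.T + rng.normal(size=3) for r in rot])
        ens = Ensemble(top, coords, np.zeros(4))
        spec = SelectionSpec.build(top, receptor_anchors=np.array([], dtype=int),
                                   ligand_atoms=np.arange(5), exclusion=0)
        feats = build_distance_features(ens, spec)
        for row in feats.values:
            np.testing.assert_allclose(row, feats.values[0], atol=1e-9)

    def test_minimum_image_with_box(self):
        top = _chain_topology(2)
        top.box = np.array([10.0, 10.0, 10.0])
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 9.0  # min-image distance is 1.0
        ens = Ensemble(top, coords, np.zeros(1))
        feats = build_distance_features(ens, SelectionSpec(np.array([[0, 1]])))
        assert feats.values[0, 0] == pytest.approx(1.0)

    def test_missing_atoms_reported(self):
        top = _chain_topology(3)
        ens = Ensemble(top, np.zeros((1, 3, 3)) + np.arange(3)[None, :, None],
                       np.zeros(1))
        with pytest.raises(ValueError, match="missing"):
            build_distance_features(ens, SelectionSpec(np.array([[0, 7]])))


class TestPCA:
    def _features(self, values):
        return FeatureMatrix(values, [f"p{i}" for i in range(values.shape[1])])

    def test_single_direction_gives_full_contribution(self):
        t = np.linspace(1, 2, 50)
        values = np.column_stack([t, 2 * t, 3 * t])
        proj = pca_fit_project(self._features(values))
        assert proj.contributions[0] == pytest.approx(100.0)

    def test_isotropic_cloud_splits_evenly(self):
        rng = np.random.default_rng(11)
        values = 5.0 + rng.normal(size=(10_000, 2)) * 0.5
        proj = pca_fit_project(self._features(values))
        assert proj.contributions[0] == pytest.approx(50.0, abs=3.0)
        assert proj.contributions[1] == pytest.approx(50.0, abs=3.0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        values = np.abs(rng.normal(size=(200, 4))) + 1.0
        p1 = pca_fit_project(self._features(values))
        p2 = pca_fit_project(self._features(values.copy()))
        np.testing.assert_array_equal(p1.components, p2.components)
        for comp in p1.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_retained_dimension_rule(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(500, 5)) * np.array([10.0, 5.0, 1.0, 0.5, 0.1])
        proj = pca_fit_project(self._features(np.abs(base) + 20.0))
        m = proj.n_components_for(90.0)
        cum = np.cumsum(proj.contributions)
        assert cum[m - 1] > 90.0
        assert m == 1 or cum[m - 2] <= 90.0

    def test_rank_zero_rejected(self):
        values = np.full((10, 3), 2.0)
        with pytest.raises(ValueError, match="rank-0"):
            pca_fit_project(self._features(values))

    def test_scores_reconstruct_centered_data(self):
        rng = np.random.default_rng(4)
        values = np.abs(rng.normal(size=(100, 3))) + 5.0
        proj = pca_fit_project(self._features(values))
        recon = proj.scores @ proj.components + proj.mean
        np.testing.assert_allclose(recon, values, atol=1e-8)


class TestFEL:
    def test_single_occupied_bin(self):
        scores = np.tile([[0.25, 0.75]], (10, 1))
        proj = Projection.from_scores(scores + np.random.default_rng(0)
                                      .normal(0, 1e-9, scores.shape))
        w = WeightVector.uniform(10)
        grid = (np.linspace(0, 1, 3), np.linspace(0, 1, 3))
        out = compute_fel(proj, w, grid=grid)
        assert np.nanmin(out.pmf) == 0.0
        assert out.above_cutoff.sum() == 3  # all other bins empty

    def test_two_bin_mass_ratio_closed_form(self):
        scores = np.array([[0.25, 0.5]] * 2 + [[0.75, 0.5]])
        proj = Projection.from_scores(scores)
        w = WeightVector.uniform(3)
        grid = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 1.0]))
        out = compute_fel(proj, w, grid=grid, T=300.0)
        dpmf = np.nanmax(out.pmf[np.isfinite(out.pmf)])
        assert dpmf == pytest.approx(R_KCAL * 300.0 * np.log(2), rel=1e-9)

    def test_grid_not_covering_is_error(self):
        proj = Projection.from_scores(np.array([[0.0, 0.0], [5.0, 5.0]]))
        grid = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="suggested bounds"):
            compute_fel(proj, WeightVector.uniform(2), grid=grid)

    def test_cutoff_flags(self):
        rng = np.random.default_rng(5)
        scores = np.concatenate([np.zeros((5000, 2)),
                                 rng.uniform(0.6, 1.0, size=(2, 2))])
        proj = Projection.from_scores(scores + rng.normal(0, 0.01, scores.shape))
        w = WeightVector.uniform(len(scores))
        grid = (np.linspace(-0.2, 1.1, 8), np.linspace(-0.2, 1.1, 8))
        out = compute_fel(proj, w, grid=grid, cutoff=2.0)
        occupied_pmfs = out.pmf[np.isfinite(out.pmf)]
        assert (occupied_pmfs > 2.0).any()
        assert out.above_cutoff[np.isnan(out.pmf)].all()

    def test_landscape_matches_quadrature_pmf(self, dw2_run):
        """Reweighted FEL of the 2-D double well reproduces the analytic PMF
        within 0.3 kcal/mol in every bin below 3 kcal/mol."""
        prod, bias, oracle = (dw2_run["production"], dw2_run["bias"],
                              dw2_run["oracle"])
        from mcfold.reweight import canonical_weights

        w = canonical_weights(prod, bias, 300.0)
        scores = prod.coords[:, 0, :]
        xe = np.linspace(-1.8, 1.8, 13)
        ye = np.linspace(-1.5, 1.5, 11)
        inside = ((scores[:, 0] > xe[0]) & (scores[:, 0] < xe[-1])
                  & (scores[:, 1] > ye[0]) & (scores[:, 1] < ye[-1]))
        proj = Projection.from_scores(scores[inside])
        w_in = WeightVector(w.weights[inside] / w.weights[inside].sum(), 300.0)
        out = compute_fel(proj, w_in, grid=(xe, ye), T=300.0)
        pmf_ref = oracle.pmf_2d(300.0, xe, ye)
        mask = pmf_ref < 3.0
        assert mask.sum() > 20
        assert np.nanmax(np.abs(out.pmf - pmf_ref)[mask]) < 0.3

    def test_default_grid_covers_scores(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=(100, 2))
        xe, ye = default_grid(scores)
        assert xe[0] < scores[:, 0].min() and xe[-1] > scores[:, 0].max()
        assert len(xe) == 101

    def test_fel_value_lookup(self):
        proj = Projection.from_scores(np.array([[0.25, 0.25], [0.75, 0.75]]))
        grid = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]))
        out = compute_fel(proj, WeightVector.uniform(2), grid=grid)
        assert fel_value_at(out, 0.25, 0.25) == pytest.approx(0.0)
        assert np.isnan(fel_value_at(out, 0.25, 0.75))
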