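"""Contact sets, R-value similarity and RMSD."""

import numpy as np
import pytest

from mcfold import rvalue as rv
from mcfold.synth import _bead_topology


def _two_chain(rec_coords, lig_coords):
    rec = np.atleast_2d(rec_coords).astype(float)
    lig = np.atleast_2d(lig_coords).astype(float)
    return _bead_topology([("R", "receptor", len(rec), rec),
                           ("L", "ligand", len(lig), lig)],
                          {"R": "receptor", "L": "ligand"})


def brute_force_contacts(model, scope, cutoff):
    """Independent O(n²) scan used as the oracle."""
    out = set()
    heavy = np.nonzero(model.heavy_mask())[0]
    for ai in range(len(heavy)):
        for bi in range(ai + 1, len(heavy)):
            a, b = int(heavy[ai]), int(heavy[bi])
            same = model.chain_ids[a] == model.chain_ids[b]
            if same and (scope == "inter"
                         or abs(int(model.res_ids[a]) - int(model.res_ids[b])) <= 2):
                continue
            if (not same) and scope == "intra":
                continue
            if np.linalg.norm(model.coords[a] - model.coords[b]) < cutoff:
                out.add((a, b))
    return out


class TestContactSet:
    def test_pair_inside_cutoff(self):
        top = _two_chain([[0, 0, 0]], [[4.0, 0, 0]])
        assert len(rv.contact_set(top, "inter", 4.5)) == 1

    def test_pair_outside_cutoff(self):
        top = _two_chain([[0, 0, 0]], [[4.6, 0, 0]])
        assert len(rv.contact_set(top, "inter", 4.5)) == 0

    @pytest.mark.parametrize("scope", ["inter", "intra", "both"])
    def test_random_atoms_match_brute_force(self, scope):
        rng = np.random.default_rng(8)
        top = _two_chain(rng.uniform(0, 10, (10, 3)), rng.uniform(0, 10, (10, 3)))
        got = rv.contact_set(top, scope, 4.5).pairs
        assert set(got) == brute_force_contacts(top, scope, 4.5)

    def test_bad_scope_and_cutoff(self):
        top = _two_chain([[0, 0, 0]], [[1, 0, 0]])
        with pytest.raises(ValueError):
            rv.contact_set(top, "x", 4.5)
        with pytest.raises(ValueError):
            rv.contact_set(top, "inter", -1.0)


class TestRValue:
    def _reference(self):
        # ligand bead near each of 3 receptor beads: 6 inter contacts
        rec = [[0, 0, 0], [6, 0, 0], [12, 0, 0]]
        lig = [[0, 3, 0], [6, 3, 0], [12, 3, 0]]
        return _two_chain(rec, lig)

    def test_self_comparison_is_exactly_one(self):
        top = self._reference()
        assert rv.r_value(top, top) == 1.0

    def test_disjoint_contacts_zero(self):
        ref = self._reference()
        far = ref.with_coords(ref.coords + np.array([0, 100.0, 0])
                              * ref.role_mask("ligand")[:, None])
        assert rv.r_value(far, ref) == 0.0

    def test_half_preserved_is_half(self):
        # reference: 2 ligand beads x 3 contacts each (hand-placed); move one
        # bead away to break exactly half of the 6 reference contacts
        rec = [[0, 0, 0], [3, 0, 0], [6, 0, 0]]
        lig = [[3.0, 2, 0], [3.0, -2, 0]]  # each bead contacts all 3 beads
        ref = _two_chain(rec, lig)
        assert len(rv.contact_set(ref, "inter", 4.5)) == 6
        moved = np.array(lig)
        moved[1] += [0, 50, 0]
        query = _two_chain(rec, moved)
        assert rv.r_value(query, ref) == pytest.approx(0.5)

    def test_reference_without_contacts_is_error(self):
        empty = _two_chain([[0, 0, 0]], [[50, 0, 0]])
        with pytest.raises(ValueError, match="undefined"):
            rv.r_value(empty, empty)

    def test_monotone_under_progressive_contact_loss(self):
        ref = self._reference()
        rng = np.random.default_rng(0)
        lig_idx = np.nonzero(ref.role_mask("ligand"))[0]
        values = []
        coords = ref.coords.copy()
        for k in range(len(lig_idx) + 1):
            model = ref.with_coords(coords)
            values.append(rv.r_value(model, ref))
            if k < len(lig_idx):
                coords = coords.copy()
                coords[lig_idx[k]] += rng.normal(100, 1, 3)
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert values[0] == 1.0 and values[-1] == 0.0

    def test_asymmetry(self):
        """R depends on which structure supplies the reference contacts."""
        rec = [[0, 0, 0], [3, 0, 0]]
        ref = _two_chain(rec, [[1.5, 2, 0], [4.5, 2, 0]])
        sub = _two_chain(rec, [[1.5, 2, 0], [4.5, 50, 0]])  # subset of contacts
        assert rv.r_value(sub, ref) < 1.0
        assert rv.r_value(ref, sub) == 1.0


class TestPerResidue:
    def _reference(self):
        rec = [[0, 0, 0], [4, 0, 0], [8, 0, 0]]
        lig = [[0, 3, 0], [4, 3, 0], [8, 3, 0]]
        return _two_chain(rec, lig)

    def test_self_comparison_all_ones(self):
        top = self._reference()
        rep = rv.per_residue_r_value(top, top)
        defined = ~np.isnan(rep.residue_r)
        assert np.all(rep.residue_r[defined] == 1.0)
        assert rep.global_r == 1.0

    def test_locality_of_perturbation(self):
        ref = self._reference()
        coords = ref.coords.copy()
        lig_idx = np.nonzero(ref.role_mask("ligand"))[0]
        coords[lig_idx[1]] += [0, 50, 0]
        rep = rv.per_residue_r_value(ref.with_coords(coords), ref, chain="L")
        # only ligand residue 2 loses its contacts
        assert rep.residue_r[rep.residue_ids == 2][0] == 0.0
        assert np.all(rep.residue_r[rep.residue_ids != 2] == 1.0)

    def test_contact_weighted_mean_equals_global(self):
        rng = np.random.default_rng(3)
        rec = rng.uniform(0, 8, (8, 3))
        lig = rng.uniform(0, 8, (8, 3))
        ref = _two_chain(rec, lig)
        query = ref.with_coords(ref.coords + rng.normal(0, 1.5, ref.coords.shape))
        rep = rv.per_residue_r_value(query, ref)
        defined = rep.residue_n_ref > 0
        weighted = np.sum(rep.residue_r[defined] * rep.residue_n_ref[defined])
        assert weighted / rep.residue_n_ref.sum() == pytest.approx(rep.global_r)


def quaternion_rmsd(x, y):
    """Independent quaternion-method optimal-superposition RMSD oracle."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    sxx = x.T @ y
    k = np.empty((4, 4))
    k[0, 0] = sxx[0, 0] + sxx[1, 1] + sxx[2, 2]
    k[0, 1] = k[1, 0] = sxx[1, 2] - sxx[2, 1]
    k[0, 2] = k[2, 0] = sxx[2, 0] - sxx[0, 2]
    k[0, 3] = k[3, 0] = sxx[0, 1] - sxx[1, 0]
    k[1, 1] = sxx[0, 0] - sxx[1, 1] - sxx[2, 2]
    k[1, 2] = k[2, 1] = sxx[0, 1] + sxx[1, 0]
    k[1, 3] = k[3, 1] = sxx[0, 2] + sxx[2, 0]
    k[2, 2] = -sxx[0, 0] + sxx[1, 1] - sxx[2, 2]
    k[2, 3] = k[3, 2] = sxx[1, 2] + sxx[2, 1]
    k[3, 3] = -sxx[0, 0] - sxx[1, 1] + sxx[2, 2]
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (np.sum(x * x) + np.sum(y * y)) / 2.0
    return np.sqrt(max(2.0 * (e0 - lam), 0.0) / len(x))


class TestRMSD:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(1)
        top = _two_chain(rng.normal(size=(4, 3)), rng.normal(size=(3, 3)))
        assert rv.rmsd(top, top) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_translation_removed(self):
        rng = np.random.default_rng(2)
        top = _two_chain(rng.normal(size=(4, 3)), rng.normal(size=(3, 3)))
        moved = top.with_coords(top.coords + [10.0, -5.0, 2.0])
        assert rv.rmsd(moved, top, superpose=True) == pytest.approx(0.0, abs=1e-9)
        assert rv.rmsd(moved, top, superpose=False) > 1.0

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(4, 3)) * 3
        b = a + rng.normal(0, 0.8, size=(4, 3))
        top_a = _two_chain(a, [[0, 0, 0]])
        top_b = _two_chain(b, [[0, 0, 0]])
        sel = np.arange(4)
        assert rv.rmsd(top_b, top_a, selection=sel) == pytest.approx(
            quaternion_rmsd(b, a), abs=1e-6)

    def test_invariant_under_proper_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        a = rng.normal(size=(6, 3))
        b = a + rng.normal(0, 0.5, size=(6, 3))
        top_a = _two_chain(a, [[0, 0, 0]])
        base = rv.rmsd(_two_chain(b, [[0, 0, 0]]), top_a, selection=np.arange(6))
        for i in range(3):
            rot = Rotation.random(rng=i).as_matrix()
            b2 = b @ rot.T + rng.normal(size=3)
            got = rv.rmsd(_two_chain(b2, [[0, 0, 0]]), top_a,
                          selection=np.arange(6))
            assert got == pytest.approx(base, abs=1e-9)

    def test_ligand_rmsd_receptor_frame(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(6)
        ref = _two_chain(rng.normal(size=(5, 3)) * 4, rng.normal(size=(3, 3)))
        rot = Rotation.random(rng=7).as_matrix()
        moved = ref.with_coords(ref.coords @ rot.T + [3.0, 1.0, -2.0])
        # a rigid motion of the whole complex leaves the complex-frame RMSD 0
        assert rv.ligand_rmsd_receptor_frame(moved, ref) == pytest.approx(0.0, abs=1e-9)
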