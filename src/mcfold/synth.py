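"""Synthetic systems and ensembles with analytically known ground truth.

Three families cover the statistical structure the pipeline assumes:

* :func:`make_double_well` — a particle in a quartic double well (1-D or
  2-D), whose canonical densities, well populations and potentials of mean
  force are computable by quadrature: the oracle for the reweighting and
  free-energy-landscape contracts.
* :func:`make_cryptic_toy` — a coarse-grained cryptic-pocket system: a fixed
  receptor groove with four attraction sites (P1–P4 analogs), a gated
  double-well coordinate whose closed state is favored when the inner sites
  are empty, and a ligand chain whose "helix" angle stiffness grows with
  site occupancy (coupled folding and binding).
* :func:`make_planted_ensemble` — multi-modal structural ensembles with
  planted cluster weights and contact templates, with energies arranged so
  canonical reweighting at 300 K recovers the planted masses exactly.

A deterministic ideal-geometry peptide-backbone builder provides
helix/strand/coil fixtures for secondary-structure validation.  Oracle
values are computed by quadrature or enumeration only, independent of the
sampling and analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import R_KCAL
from .core import Ensemble, StructureModel
from .engine import (ChainAngleTerm, DoubleWell1D, GaussianSite, HarmonicBond,
                     HarmonicWell, RestraintSpec, SoftRepulsion, Tether1D,
                     ToySystem)


def _bead_topology(groups: list[tuple[str, str, int, np.ndarray]],
                   roles: dict[str, str]) -> StructureModel:
    """Topology of coarse-grained beads: one 'CA' carbon bead per residue.

    ``groups`` is a list of (chain_id, role, n_beads, coords) blocks.
    """
    names, elements, res_names, res_ids, chain_ids, coords = [], [], [], [], [], []
    for chain, _role, n, xyz in groups:
        for r in range(n):
            names.append("CA")
            elements.append("C")
            res_names.append("BEA")
            res_ids.append(r + 1)
            chain_ids.append(chain)
            coords.append(xyz[r])
    return StructureModel(
        atom_names=np.asarray(names, dtype=object),
        elements=np.asarray(elements, dtype=object),
        res_names=np.asarray(res_names, dtype=object),
        res_ids=np.asarray(res_ids, dtype=int),
        chain_ids=np.asarray(chain_ids, dtype=object),
        coords=np.asarray(coords, dtype=float),
        chain_roles=dict(roles),
    )


# ---------------------------------------------------------------------------
# Double well + quadrature oracle
# ---------------------------------------------------------------------------


@dataclass
class DoubleWellOracle:
    """Quadrature oracle for the quartic double well.

    U(x[, y]) = barrier (x² − 1)² + asymmetry x / 2 [+ ½ κ_y y²].
    All canonical quantities are computed by dense-grid quadrature.
    """

    barrier: float
    asymmetry: float = 0.0
    dims: int = 1
    kappa_y: float = 2.0
    x_range: tuple[float, float] = (-2.6, 2.6)
    y_range: tuple[float, float] = (-2.6, 2.6)
    n_grid: int = 2001

    def potential(self, x, y=None):
        u = self.barrier * (np.asarray(x) ** 2 - 1.0) ** 2 \
            + 0.5 * self.asymmetry * np.asarray(x)
        if self.dims == 2:
            u = u + 0.5 * self.kappa_y * np.asarray(y) ** 2
        return u

    def _grids(self):
        x = np.linspace(*self.x_range, self.n_grid)
        if self.dims == 1:
            return x, None, self.potential(x)
        y = np.linspace(*self.y_range, self.n_grid // 4 * 2 + 1)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        return x, y, self.potential(xx, yy)

    def _boltzmann(self, T):
        x, y, u = self._grids()
        w = np.exp(-(u - u.min()) / (R_KCAL * T))
        return x, y, u, w / w.sum()

    def mean_energy(self, T: float) -> float:
        _, _, u, p = self._boltzmann(T)
        return float(np.sum(u * p))

    def well_populations(self, T: float) -> tuple[float, float]:
        """Canonical mass at x<0 and x>0."""
        x, _, _, p = self._boltzmann(T)
        if self.dims == 1:
            left = float(p[x < 0].sum() + 0.5 * p[x == 0].sum())
        else:
            left = float(p[x < 0, :].sum() + 0.5 * p[x == 0, :].sum())
        return left, 1.0 - left

    def energy_cdf(self, T: float, e_values: np.ndarray) -> np.ndarray:
        """P(U ≤ e) under the canonical distribution at T."""
        _, _, u, p = self._boltzmann(T)
        u, p = u.ravel(), p.ravel()
        order = np.argsort(u)
        cum = np.cumsum(p[order])
        return np.interp(np.asarray(e_values), u[order], cum, left=0.0, right=1.0)

    def pmf_2d(self, T: float, x_edges: np.ndarray,
               y_edges: np.ndarray) -> np.ndarray:
        """Quadrature PMF (min-shifted) over the given (x, y) bins."""
        if self.dims != 2:
            raise ValueError("2-D PMF requires dims=2")
        x, y, _, p = self._boltzmann(T)
        xi = np.searchsorted(x_edges, x, side="right") - 1
        yi = np.searchsorted(y_edges, y, side="right") - 1
        nx, ny = len(x_edges) - 1, len(y_edges) - 1
        mass = np.zeros((nx, ny))
        ok_x = (xi >= 0) & (xi < nx)
        ok_y = (yi >= 0) & (yi < ny)
        for i in np.nonzero(ok_x)[0]:
            row = p[i, ok_y]
            np.add.at(mass[xi[i]], yi[ok_y], row)
        with np.errstate(divide="ignore"):
            pmf = -R_KCAL * T * np.log(mass)
        pmf[mass <= 0] = np.inf
        return pmf - pmf.min()


def make_double_well(barrier: float, asymmetry: float = 0.0,
                     dims: int = 1) -> tuple[ToySystem, DoubleWellOracle]:
    """Single-particle quartic double well (optionally with a harmonic y)."""
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    oracle = DoubleWellOracle(barrier, asymmetry, dims)
    coords = np.zeros((1, dims))
    coords[0, 0] = -1.0
    top = _bead_topology([("A", "ligand", 1, coords)], {"A": "ligand"})
    terms: list = [DoubleWell1D(0, 0, barrier, tilt=asymmetry)]
    if dims == 2:
        class _YWell(HarmonicWell):
            def energy(self, c):
                return 0.5 * self.kappa * c[..., self.particle, 1] ** 2

            def force(self, c):
                f = np.zeros_like(c)
                f[..., self.particle, 1] = -self.kappa * c[..., self.particle, 1]
                return f
        terms.append(_YWell(0, oracle.kappa_y))
    system = ToySystem(top, terms, x0=coords, step_size=0.35)
    return system, oracle


# ---------------------------------------------------------------------------
# Cryptic-pocket toy
# ---------------------------------------------------------------------------

SITE_SPACING = 3.0
SITE_NAMES = ("P1", "P2", "P3", "P4")


@dataclass
class CrypticOracle:
    """Enumeration oracle and planted truth thresholds for the cryptic toy."""

    system: ToySystem
    site_positions: np.ndarray
    gate_index: int
    ligand_indices: np.ndarray
    gate_bias: float
    coupling: float
    gate_open_y: float = 3.0
    gate_closed_y: float = 1.0
    bound_lambda: float = 10.0       # λ below this counts as bound
    folded_order: float = 0.8        # chain order above this counts as folded

    def _chain_coords(self, x_off: float, straight: bool) -> np.ndarray:
        n = len(self.ligand_indices)
        pts = [np.array([x_off, 1.0])]
        ang = np.deg2rad(35.0)
        for i in range(1, n):
            theta = 0.0 if straight else (ang if i % 2 else -ang)
            step = SITE_SPACING * np.array([np.cos(theta), np.sin(theta)])
            pts.append(pts[-1] + step)
        return np.asarray(pts)

    def enumerate_minimum(self) -> dict:
        """Exhaustive scan over a discretized configuration grid.

        Gate open/closed × ligand offset grid × straight/bent chain; returns
        the attributes of the global energy minimum.
        """
        best = None
        x0 = self.system.x0
        for x_off in np.linspace(-1.0, 14.0, 61):
            for gate_y in (self.gate_closed_y, self.gate_open_y):
                for straight in (True, False):
                    coords = x0.copy()
                    coords[self.ligand_indices] = self._chain_coords(x_off, straight)
                    coords[self.gate_index, 1] = gate_y
                    e = float(self.system.energy(coords))
                    if best is None or e < best[0]:
                        best = (e, x_off, gate_y, straight)
        e, x_off, gate_y, straight = best
        lam = x_off + SITE_SPACING * (len(self.ligand_indices) - 1) / 2.0
        return {"energy": e, "bound": lam < self.bound_lambda,
                "gate_open": gate_y > (self.gate_closed_y + self.gate_open_y) / 2,
                "folded": straight}

    # -- per-frame ground-truth labels -------------------------------------

    def gate_open_mask(self, ensemble: Ensemble) -> np.ndarray:
        mid = 0.5 * (self.gate_closed_y + self.gate_open_y)
        return ensemble.coords[:, self.gate_index, 1] > mid

    def bound_mask(self, ensemble: Ensemble) -> np.ndarray:
        lam = ensemble.coords[:, self.ligand_indices, 0].mean(axis=1)
        return lam < self.bound_lambda

    def chain_order(self, ensemble: Ensemble) -> np.ndarray:
        """Mean straightness of the ligand chain in [0, 1]; 1 = ordered."""
        c = ensemble.coords[:, self.ligand_indices, :]
        u = c[:, 1:-1] - c[:, :-2]
        v = c[:, 2:] - c[:, 1:-1]
        cos = np.sum(u * v, axis=-1) / (
            np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1))
        return np.mean((1.0 + cos) / 2.0, axis=-1)

    def folded_mask(self, ensemble: Ensemble) -> np.ndarray:
        return self.chain_order(ensemble) > self.folded_order


def make_cryptic_toy(n_ligand_beads: int = 5, gate_bias: float = 1.2,
                     coupling: float = 0.8, seed: int = 0,
                     site_depth: float = 2.5,
                     ) -> tuple[ToySystem, CrypticOracle]:
    """Two-dimensional coarse-grained cryptic-pocket system.

    A fixed receptor row carries four attraction sites P1–P4 along x (P1
    innermost, P4 at the groove mouth); a mobile gate bead sits over P1/P2
    with double-well energetics along y whose closed state is lower by
    ``gate_bias`` when unobstructed; ligand beads bind their native sites via
    Gaussian wells, and the chain's angle stiffness grows with site occupancy
    (``coupling``).  The ligand COM is confined to a box along the
    dissociation axis, the sampling analog of the restrained λ region.
    """
    if n_ligand_beads < 4:
        raise ValueError("need at least 4 ligand beads")
    if coupling <= 0:
        raise ValueError("coupling must be positive (degenerate system)")
    if gate_bias <= 0:
        raise ValueError("gate_bias must be positive (closed state favored)")
    del seed  # geometry is deterministic; kept for generator API symmetry

    site_pos = np.asarray([[i * SITE_SPACING, 0.0] for i in range(4)])
    gate_xy = np.array([[1.5, 3.0]])     # start open: the ligand starts bound
    lig = np.asarray([[i * SITE_SPACING, 1.0] for i in range(n_ligand_beads)])
    top = _bead_topology(
        [("R", "receptor", 4, site_pos),
         ("G", "receptor", 1, gate_xy),
         ("L", "ligand", n_ligand_beads, lig)],
        {"R": "receptor", "G": "receptor", "L": "ligand"},
    )
    gate_idx = 4
    lig_idx = np.arange(5, 5 + n_ligand_beads)

    sites = GaussianSite(beads=lig_idx[:4], sites=site_pos,
                         depth=site_depth, width=1.0)
    bonds = HarmonicBond(np.column_stack([lig_idx[:-1], lig_idx[1:]]),
                         r0=SITE_SPACING, k=10.0)
    triples = np.column_stack([lig_idx[:-2], lig_idx[1:-1], lig_idx[2:]])
    angles = ChainAngleTerm(triples, k0=0.15, coupling=coupling, sites=sites)
    gate_well = DoubleWell1D(gate_idx, axis=1, barrier=2.0, center=2.0,
                             half_width=1.0, tilt=gate_bias)
    gate_tether = Tether1D(gate_idx, axis=0, q0=1.5, k=50.0)
    gate_clash = SoftRepulsion(
        np.column_stack([np.full(len(lig_idx), gate_idx), lig_idx]),
        sigma=2.5, k=10.0)
    restraints = [
        RestraintSpec("com_axis_box", selection_a=lig_idx, lower=-1.0,
                      upper=18.0, k=10.0, axis=0),
        RestraintSpec("com_axis_box", selection_a=lig_idx, lower=-3.0,
                      upper=7.0, k=10.0, axis=1),
    ]
    mobile = np.zeros(top.n_atoms, dtype=bool)
    mobile[gate_idx] = True
    mobile[lig_idx] = True
    system = ToySystem(top, [sites, bonds, angles, gate_well, gate_tether,
                             gate_clash], restraints, mobile, step_size=0.3)
    oracle = CrypticOracle(system, site_pos, gate_idx, lig_idx,
                           gate_bias, coupling)
    return system, oracle


def first_contact_site(pathway, oracle: CrypticOracle,
                       cutoff: float = 4.5) -> str | None:
    """Name of the site first contacted when walking the path from unbound.

    Walks picks from the last (most-unbound) window toward the bound end and
    reports the attraction site nearest the first ligand bead that comes
    within ``cutoff`` of any site.  None when no pick makes site contact.
    """
    for snap in reversed(pathway.picks):
        lig = snap.coords[oracle.ligand_indices]
        d = np.linalg.norm(lig[:, None, :] - oracle.site_positions[None], axis=-1)
        if d.min() < cutoff:
            site = int(np.unravel_index(np.argmin(d), d.shape)[1])
            return SITE_NAMES[site]
    return None


def mechanism_report(production: Ensemble, weights, oracle: CrypticOracle) -> dict:
    """Mechanism signatures of a cryptic-toy multicanonical run.

    Using the canonical weights, computes per-trajectory (paired-seed)
    conditional probabilities: gate-closed occupancy given unbound,
    gate-open probability given bound vs unbound, and mean chain order
    given bound vs unbound.  Trajectories lacking bound or unbound frames
    are skipped in the paired statistics.
    """
    bound = oracle.bound_mask(production)
    open_ = oracle.gate_open_mask(production)
    order = oracle.chain_order(production)
    w = weights.weights
    per_traj = []
    for t in np.unique(production.traj_ids):
        sel = production.traj_ids == t
        wb = w[sel & bound].sum()
        wu = w[sel & ~bound].sum()
        if wb <= 0 or wu <= 0:
            continue
        per_traj.append({
            "traj": int(t),
            "closed_given_unbound": float(w[sel & ~bound & ~open_].sum() / wu),
            "open_given_bound": float(w[sel & bound & open_].sum() / wb),
            "open_given_unbound": float(w[sel & ~bound & open_].sum() / wu),
            "order_given_bound": float(np.sum(w[sel & bound] * order[sel & bound]) / wb),
            "order_given_unbound": float(np.sum(w[sel & ~bound] * order[sel & ~bound]) / wu),
        })
    pooled = {
        "closed_given_unbound": float(w[~bound & ~open_].sum() / max(w[~bound].sum(), 1e-300)),
        "open_given_bound": float(w[bound & open_].sum() / max(w[bound].sum(), 1e-300)),
        "open_given_unbound": float(w[~bound & open_].sum() / max(w[~bound].sum(), 1e-300)),
        "order_given_bound": float(np.sum(w[bound] * order[bound]) / max(w[bound].sum(), 1e-300)),
        "order_given_unbound": float(np.sum(w[~bound] * order[~bound]) / max(w[~bound].sum(), 1e-300)),
    }
    return {"per_traj": per_traj, "pooled": pooled}


def seeded_first_contacts(production: Ensemble, oracle: CrypticOracle,
                          window_width: float = 2.5,
                          min_unbound_lambda: float = 14.0) -> list:
    """First-contact site of a pathway extracted from each trajectory.

    Each trajectory (independent seed) yields its own binding pathway over
    its λ range; the returned list holds the name of the first contacted
    attraction site per trajectory (None when the trajectory never reaches
    the unbound region or a window is empty).
    """
    from .observables import lambda_coord_frames
    from .pathway import extract_pathway, make_windows

    lam = lambda_coord_frames(production)
    out = []
    for t in np.unique(production.traj_ids):
        idx = np.nonzero(production.traj_ids == t)[0]
        sub = production.subset(idx)
        lam_t = lam[idx]
        if lam_t.max() < min_unbound_lambda:
            out.append(None)
            continue
        windows = make_windows(float(lam_t.min()) - 1e-6,
                               float(lam_t.max()) + 1e-6, window_width)
        try:
            path = extract_pathway(sub, int(np.argmin(lam_t)), windows,
                                   lambdas=lam_t)
        except ValueError:
            out.append(None)
            continue
        out.append(first_contact_site(path, oracle))
    return out


# ---------------------------------------------------------------------------
# Planted multimodal ensembles
# ---------------------------------------------------------------------------


@dataclass
class PlantedMode:
    """One planted mode: ligand-bead → receptor-site map, offset and mass."""

    site_map: tuple[int, ...]     # receptor site index per ligand bead
    mass: float
    offset: tuple[float, float] = (0.0, 0.0)
    spread: float = 0.2


@dataclass
class PlantedTruth:
    """Ground truth of a planted ensemble."""

    labels: np.ndarray
    masses: np.ndarray
    templates: list[frozenset]    # planted contact sets (atom-index pairs)
    overlapping_pairs: list[tuple[int, int]]
    mode_energies: np.ndarray


def _planted_topology(n_sites: int, n_lig: int) -> StructureModel:
    site_pos = np.asarray([[i * SITE_SPACING, 0.0, 0.0] for i in range(n_sites)])
    lig = np.asarray([[i * SITE_SPACING, 1.5, 0.0] for i in range(n_lig)])
    return _bead_topology([("R", "receptor", n_sites, site_pos),
                           ("L", "ligand", n_lig, lig)],
                          {"R": "receptor", "L": "ligand"})


def _template_coords(top: StructureModel, mode: PlantedMode,
                     n_sites: int) -> np.ndarray:
    coords = top.coords.copy()
    lig = np.nonzero(top.role_mask("ligand"))[0]
    for b, s in enumerate(mode.site_map):
        coords[lig[b], 0] = s * SITE_SPACING + mode.offset[0]
        coords[lig[b], 1] = 1.5 + mode.offset[1]
        coords[lig[b], 2] = 0.0
    return coords


def _brute_contacts(coords: np.ndarray, rec: np.ndarray, lig: np.ndarray,
                    cutoff: float = 4.5) -> frozenset:
    """Independent O(n²) intermolecular contact scan (oracle-side)."""
    out = set()
    for a in rec:
        for b in lig:
            if np.linalg.norm(coords[a] - coords[b]) < cutoff:
                out.add((min(int(a), int(b)), max(int(a), int(b))))
    return frozenset(out)


def make_planted_ensemble(modes: list[PlantedMode], n: int, seed: int = 0,
                          t_mc: float = 700.0, t_target: float = 300.0,
                          n_sites: int = 6,
                          ) -> tuple[Ensemble, PlantedTruth]:
    """Multi-modal ensemble whose 300 K reweighting recovers planted masses.

    Frames are allocated evenly across modes (flat multicanonical occupancy
    analog); each mode carries a constant energy E_m chosen so the canonical
    weight at ``t_target`` reproduces the planted mass exactly:
    E_m = −ln(mass_m / n_m) / c with c = (1/T − 1/T_mc)/R under an identity
    bias.  Coordinates realize each mode's contact template with Gaussian
    jitter.
    """
    masses = np.asarray([m.mass for m in modes], dtype=float)
    if not np.isclose(masses.sum(), 1.0):
        raise ValueError("planted masses must sum to 1")
    if n < 10 * len(modes):
        raise ValueError("need at least 10 snapshots per mode")
    n_lig = len(modes[0].site_map)
    top = _planted_topology(n_sites, n_lig)
    rec = np.nonzero(top.role_mask("receptor"))[0]
    lig = np.nonzero(top.role_mask("ligand"))[0]

    n_m = np.full(len(modes), n // len(modes))
    n_m[: n - n_m.sum()] += 1
    c = (1.0 / t_target - 1.0 / t_mc) / R_KCAL
    e_m = -np.log(masses / n_m) / c
    e_m -= e_m.min()

    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    coords, energies, labels = [], [], []
    templates = []
    for k, mode in enumerate(modes):
        base = _template_coords(top, mode, n_sites)
        templates.append(_brute_contacts(base, rec, lig))
        for _ in range(n_m[k]):
            x = base.copy()
            x[lig, :] += rng.normal(0.0, mode.spread, size=(n_lig, 3))
            coords.append(x)
            energies.append(e_m[k])
            labels.append(k)
    order = rng.permutation(len(coords))
    coords = np.asarray(coords)[order]
    energies = np.asarray(energies)[order]
    labels = np.asarray(labels)[order]

    overlapping = []
    for i in range(len(modes)):
        for j in range(i + 1, len(modes)):
            inter = templates[i] & templates[j]
            if templates[j] and len(inter) / len(templates[j]) > 0.7:
                overlapping.append((i, j))
    ens = Ensemble(top, coords, energies,
                   metadata={"kind": "planted", "t_mc": t_mc, "seed": seed,
                             "bias_id": "identity"})
    truth = PlantedTruth(labels, masses, templates, overlapping, e_m)
    return ens, truth


def two_mode_ensemble(n: int = 600, seed: int = 0) -> tuple[Ensemble, PlantedTruth]:
    """Planted two-mode ensemble with a 2:1 mass split (ΔCFE = RT ln 2)."""
    modes = [PlantedMode(site_map=(0, 1, 2, 3), mass=2 / 3),
             PlantedMode(site_map=(2, 3, 4, 5), mass=1 / 3)]
    return make_planted_ensemble(modes, n, seed)


def five_mode_ensemble(n: int = 1500, seed: int = 0) -> tuple[Ensemble, PlantedTruth]:
    """Five planted modes, two of which share >70% of their contacts."""
    modes = [
        PlantedMode(site_map=(0, 1, 2, 3), mass=0.30),
        PlantedMode(site_map=(0, 1, 2, 3), mass=0.20, offset=(0.5, 0.1)),
        PlantedMode(site_map=(2, 3, 4, 5), mass=0.20),
        PlantedMode(site_map=(5, 4, 3, 2), mass=0.18),
        PlantedMode(site_map=(3, 2, 1, 0), mass=0.12),
    ]
    return make_planted_ensemble(modes, n, seed)


def make_funnel_ensemble(n_per_window: int = 40,
                         lambda_range: tuple[float, float] = (5.0, 20.0),
                         width: float = 2.5, noise: float = 0.12,
                         seed: int = 0) -> Ensemble:
    """Smooth dissociation funnel: the bound pose rigidly drawn outward.

    Frames are the cryptic toy's native ligand pose rigidly shifted along the
    dissociation axis, populating every λ window with jittered copies — a
    planted smooth pathway for window-picking oracles.
    """
    system, oracle = make_cryptic_toy()
    top = system.topology
    lig = oracle.ligand_indices
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    lam0 = top.coords[lig, 0].mean()
    lo, hi = lambda_range
    n_windows = int(np.ceil((hi - lo) / width))
    coords, energies = [], []
    for w in range(n_windows):
        for _ in range(n_per_window):
            lam = rng.uniform(lo + w * width, min(lo + (w + 1) * width, hi))
            x = top.coords.copy()
            x[lig, 0] += lam - lam0
            x[lig, :] += rng.normal(0.0, noise, size=(len(lig), 2))
            coords.append(x)
            energies.append(0.0)
    return Ensemble(top, np.asarray(coords), np.asarray(energies),
                    metadata={"kind": "funnel", "seed": seed,
                              "lambda_range": list(lambda_range)})


# ---------------------------------------------------------------------------
# Ideal-geometry peptide backbones (secondary-structure fixtures)
# ---------------------------------------------------------------------------

_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of atom d with internal coordinates w.r.t. a-b-c."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(angle),
                   bond * np.sin(angle) * np.cos(torsion),
                   bond * np.sin(angle) * np.sin(torsion)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_peptide(phi_psi: list[tuple[float, float]], chain: str = "A",
                  res_name: str = "ALA", omega: float = 180.0) -> StructureModel:
    """Ideal-geometry backbone (N, CA, C, O per residue) from (φ, ψ) angles.

    Standard bond lengths/angles; the carbonyl O lies in the peptide plane
    (torsion ψ + 180°).  Returns a single-chain structure suitable for
    secondary-structure assignment.
    """
    n_res = len(phi_psi)
    if n_res < 2:
        raise ValueError("need at least two residues")
    pos: list[dict] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    pos.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = pos[-1]
        phi, _ = phi_psi[i]
        _, psi_prev = phi_psi[i - 1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"],
                        _B_C_N, _A_CA_C_N, psi_prev)
        ca = _place_atom(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, omega)
        c = _place_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        pos.append({"N": n, "CA": ca, "C": c})
    # carbonyl O: in-plane, anti to the next N (torsion psi + 180)
    for i in range(n_res):
        psi = phi_psi[i][1]
        pos[i]["O"] = _place_atom(pos[i]["N"], pos[i]["CA"], pos[i]["C"],
                                  _B_C_O, _A_CA_C_O, psi + 180.0)
    names, elements, res_ids, coords = [], [], [], []
    for i, atoms in enumerate(pos):
        for nm in ("N", "CA", "C", "O"):
            names.append(nm)
            elements.append(nm[0])
            res_ids.append(i + 1)
            coords.append(atoms[nm])
    n_at = len(names)
    return StructureModel(
        atom_names=np.asarray(names, dtype=object),
        elements=np.asarray(elements, dtype=object),
        res_names=np.asarray([res_name] * n_at, dtype=object),
        res_ids=np.asarray(res_ids, dtype=int),
        chain_ids=np.asarray([chain] * n_at, dtype=object),
        coords=np.asarray(coords, dtype=float),
        chain_roles={chain: "ligand"},
    )


def make_helix(n_res: int = 16, **kw) -> StructureModel:
    """Ideal α-helix (φ = −57°, ψ = −47°)."""
    return build_peptide([(-57.0, -47.0)] * n_res, **kw)


def make_310_helix(n_res: int = 12, **kw) -> StructureModel:
    """Ideal 3₁₀ helix (φ = −49°, ψ = −26°)."""
    return build_peptide([(-49.0, -26.0)] * n_res, **kw)


def make_extended(n_res: int = 12, **kw) -> StructureModel:
    """Fully extended chain (φ = ψ = 180°): no hydrogen-bonded structure."""
    return build_peptide([(180.0, 180.0)] * n_res, **kw)


def make_beta_hairpin(strand_len: int = 5, **kw) -> StructureModel:
    """Antiparallel β-hairpin: two ideal strands (φ=−139°, ψ=135°) joined by
    a type-II'-like two-residue turn, producing ladder hydrogen bonds."""
    beta = (-139.0, 135.0)
    turn = [(60.0, -125.0), (-95.0, 5.0)]
    return build_peptide([beta] * strand_len + turn + [beta] * strand_len, **kw)


def make_coil(n_res: int = 14, seed: int = 0, **kw) -> StructureModel:
    """Irregular backbone from alternating extended/polyproline-like angles."""
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    pool = [(-75.0, 150.0), (-150.0, 100.0), (-100.0, 170.0), (140.0, 160.0)]
    angles = [pool[rng.integers(len(pool))] for _ in range(n_res)]
    return build_peptide(angles, **kw)
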