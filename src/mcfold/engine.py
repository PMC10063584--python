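"""Desk-scale canonical and multicanonical sampler over coarse-grained systems.

The engine samples a :class:`ToySystem` with Metropolis Monte Carlo (Gaussian
single-particle moves), either with the bare potential (canonical sampling at
temperature T) or with a modified potential E_mc(E) at sampling temperature
T_mc (multicanonical sampling).  The multicanonical bias is estimated from a
high-temperature canonical run and iteratively refined until the potential
energy histogram is flat over the target canonical range
[<E>(T_low), <E>(T_high)].

Energies are kcal/mol, lengths Å, temperatures K.  An optional overdamped
Langevin integrator is provided; every potential term carries analytic
forces, kept consistent with central finite differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

from .constants import R_KCAL
from .core import Ensemble, StructureModel


# ---------------------------------------------------------------------------
# Potential terms (energy in kcal/mol; coords (..., n_atoms, ndim))
# ---------------------------------------------------------------------------


class PotentialTerm:
    """Base class: vectorized energy over leading batch axes, analytic force."""

    def energy(self, coords: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def force(self, coords: np.ndarray) -> np.ndarray:
        """-dU/dx with the same shape as ``coords``."""
        raise NotImplementedError


def _dist(coords, i, j):
    rij = coords[..., i, :] - coords[..., j, :]
    return rij, np.sqrt(np.sum(rij * rij, axis=-1))


@dataclass
class HarmonicBond(PotentialTerm):
    """U = k (r_ij - r0)^2 summed over listed pairs."""

    pairs: np.ndarray  # (m, 2) int
    r0: float
    k: float

    def energy(self, coords):
        i, j = np.asarray(self.pairs).T
        _, r = _dist(coords, i, j)
        return self.k * np.sum((r - self.r0) ** 2, axis=-1)

    def force(self, coords):
        f = np.zeros_like(coords)
        for i, j in np.asarray(self.pairs):
            rij, r = _dist(coords, i, j)
            g = 2.0 * self.k * (r - self.r0)[..., None] * rij / r[..., None]
            f[..., i, :] -= g
            f[..., j, :] += g
        return f


@dataclass
class GaussianSite(PotentialTerm):
    """Attractive Gaussian well between a bead and a fixed site position.

    U = -depth * exp(-r^2 / (2 width^2)) for each (bead, site) pair.
    """

    beads: np.ndarray          # (m,) int
    sites: np.ndarray          # (m, ndim) fixed positions
    depth: float
    width: float

    def energy(self, coords):
        d = coords[..., np.asarray(self.beads), :] - np.asarray(self.sites)
        r2 = np.sum(d * d, axis=-1)
        return -self.depth * np.sum(np.exp(-r2 / (2 * self.width**2)), axis=-1)

    def force(self, coords):
        f = np.zeros_like(coords)
        w2 = self.width**2
        for b, s in zip(np.asarray(self.beads), np.asarray(self.sites)):
            d = coords[..., b, :] - s
            r2 = np.sum(d * d, axis=-1, keepdims=True)
            f[..., b, :] -= self.depth / w2 * np.exp(-r2 / (2 * w2)) * d
        return f

    def occupancy(self, coords):
        """Per-pair Gaussian occupancy in [0, 1], shape (..., m)."""
        d = coords[..., np.asarray(self.beads), :] - np.asarray(self.sites)
        r2 = np.sum(d * d, axis=-1)
        return np.exp(-r2 / (2 * self.width**2))


@dataclass
class SoftRepulsion(PotentialTerm):
    """U = k (sigma - r)^2 for r < sigma over listed pairs (soft core)."""

    pairs: np.ndarray
    sigma: float
    k: float

    def energy(self, coords):
        i, j = np.asarray(self.pairs).T
        _, r = _dist(coords, i, j)
        overlap = np.clip(self.sigma - r, 0.0, None)
        return self.k * np.sum(overlap * overlap, axis=-1)

    def force(self, coords):
        f = np.zeros_like(coords)
        for i, j in np.asarray(self.pairs):
            rij, r = _dist(coords, i, j)
            overlap = np.clip(self.sigma - r, 0.0, None)
            g = -2.0 * self.k * overlap[..., None] * rij / np.maximum(r, 1e-12)[..., None]
            f[..., i, :] -= g
            f[..., j, :] += g
        return f


@dataclass
class DoubleWell1D(PotentialTerm):
    """Quartic double well on one coordinate of one particle.

    With t = (q - center) / half_width:  U = barrier (t^2 - 1)^2 + tilt t / 2,
    giving minima near t = ±1 separated by ``barrier`` and offset by ``tilt``.
    """

    particle: int
    axis: int
    barrier: float
    center: float = 0.0
    half_width: float = 1.0
    tilt: float = 0.0

    def energy(self, coords):
        t = (coords[..., self.particle, self.axis] - self.center) / self.half_width
        return self.barrier * (t * t - 1.0) ** 2 + 0.5 * self.tilt * t

    def force(self, coords):
        f = np.zeros_like(coords)
        t = (coords[..., self.particle, self.axis] - self.center) / self.half_width
        dudq = (4.0 * self.barrier * t * (t * t - 1.0) + 0.5 * self.tilt) / self.half_width
        f[..., self.particle, self.axis] = -dudq
        return f


@dataclass
class Tether1D(PotentialTerm):
    """U = k (q - q0)^2 on one coordinate of one particle."""

    particle: int
    axis: int
    q0: float
    k: float

    def energy(self, coords):
        q = coords[..., self.particle, self.axis]
        return self.k * (q - self.q0) ** 2

    def force(self, coords):
        f = np.zeros_like(coords)
        q = coords[..., self.particle, self.axis]
        f[..., self.particle, self.axis] = -2.0 * self.k * (q - self.q0)
        return f


@dataclass
class HarmonicWell(PotentialTerm):
    """Isotropic well U = 0.5 kappa |x - x0|^2 on one particle (test system)."""

    particle: int
    kappa: float
    x0: np.ndarray | float = 0.0

    def energy(self, coords):
        d = coords[..., self.particle, :] - self.x0
        return 0.5 * self.kappa * np.sum(d * d, axis=-1)

    def force(self, coords):
        f = np.zeros_like(coords)
        f[..., self.particle, :] = -self.kappa * (coords[..., self.particle, :] - self.x0)
        return f


def _angle_cos_and_grads(coords, a, b, c):
    u = coords[..., a, :] - coords[..., b, :]
    v = coords[..., c, :] - coords[..., b, :]
    nu = np.sqrt(np.sum(u * u, axis=-1, keepdims=True))
    nv = np.sqrt(np.sum(v * v, axis=-1, keepdims=True))
    cos = np.sum(u * v, axis=-1, keepdims=True) / (nu * nv)
    ga = v / (nu * nv) - cos * u / (nu * nu)
    gc = u / (nu * nv) - cos * v / (nv * nv)
    return cos[..., 0], ga, gc


@dataclass
class ChainAngleTerm(PotentialTerm):
    """Helix-order term: U = k_eff * sum over triples of (1 + cos theta).

    Straight (theta = 180°) is the ordered, "helical" analog state.  When
    ``coupling`` and a :class:`GaussianSite` term are given, the effective
    constant is k0 + coupling * (summed site occupancy), so chain ordering is
    stabilized by binding-site occupancy (coupled folding and binding).
    """

    triples: np.ndarray  # (m, 3) int
    k0: float
    coupling: float = 0.0
    sites: GaussianSite | None = None

    def _order_sum(self, coords):
        a, b, c = np.asarray(self.triples).T
        total = 0.0
        for ai, bi, ci in zip(a, b, c):
            cos, _, _ = _angle_cos_and_grads(coords, ai, bi, ci)
            total = total + (1.0 + cos)
        return total

    def _k_eff(self, coords):
        if self.coupling == 0.0 or self.sites is None:
            return self.k0
        occ = np.sum(self.sites.occupancy(coords), axis=-1)
        return self.k0 + self.coupling * occ

    def energy(self, coords):
        return self._k_eff(coords) * self._order_sum(coords)

    def force(self, coords):
        k_eff = self._k_eff(coords)
        a_sum = self._order_sum(coords)
        f = np.zeros_like(coords)
        ke = np.asarray(k_eff)[..., None]
        for ai, bi, ci in np.asarray(self.triples):
            _, ga, gc = _angle_cos_and_grads(coords, ai, bi, ci)
            f[..., ai, :] -= ke * ga
            f[..., ci, :] -= ke * gc
            f[..., bi, :] += ke * (ga + gc)
        if self.coupling != 0.0 and self.sites is not None:
            w2 = self.sites.width**2
            amp = (self.coupling * np.asarray(a_sum))[..., None]
            for b, s in zip(np.asarray(self.sites.beads), np.asarray(self.sites.sites)):
                d = coords[..., b, :] - s
                r2 = np.sum(d * d, axis=-1, keepdims=True)
                f[..., b, :] += amp * np.exp(-r2 / (2 * w2)) * d / w2
        return f


# ---------------------------------------------------------------------------
# Restraints
# ---------------------------------------------------------------------------


@dataclass
class RestraintSpec:
    """Flat-bottom restraint: zero inside [lower, upper], k·Δ² beyond.

    ``kind`` is ``"flat_bottom_distance"`` (distance between the mass-weighted
    centers of two selections) or ``"com_axis_box"`` (center of mass of one
    selection along a named axis, as used to confine the ligand COM along the
    dissociation axis).  ``k`` is kcal/mol/Å².
    """

    kind: str
    selection_a: np.ndarray
    selection_b: np.ndarray | None = None
    lower: float = 0.0
    upper: float = 0.0
    k: float = 10.0
    axis: int = 0
    masses: np.ndarray | None = None

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower bound must not exceed upper bound")
        if self.k < 0:
            raise ValueError("force constant must be non-negative")
        if self.kind not in ("flat_bottom_distance", "com_axis_box"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if len(np.atleast_1d(self.selection_a)) == 0:
            raise ValueError("empty selection")
        if self.kind == "flat_bottom_distance" and (
            self.selection_b is None or len(np.atleast_1d(self.selection_b)) == 0
        ):
            raise ValueError("empty selection")


def _com(coords, sel, masses):
    sel = np.atleast_1d(sel)
    m = np.ones(len(sel)) if masses is None else np.asarray(masses)[sel]
    w = m / m.sum()
    return np.sum(coords[..., sel, :] * w[:, None], axis=-2), w


def _excess(value, lower, upper):
    """Signed distance outside [lower, upper]: 0 inside, >0 above, <0 below."""
    return np.clip(value - upper, 0.0, None) + np.clip(value - lower, None, 0.0)


def restraint_energy(coords: np.ndarray, spec: RestraintSpec,
                     masses: np.ndarray | None = None) -> np.ndarray:
    """Flat-bottom penalty energy of ``spec`` at ``coords`` (kcal/mol)."""
    masses = spec.masses if masses is None else masses
    if spec.kind == "flat_bottom_distance":
        ca, _ = _com(coords, spec.selection_a, masses)
        cb, _ = _com(coords, spec.selection_b, masses)
        d = np.sqrt(np.sum((ca - cb) ** 2, axis=-1))
        delta = _excess(d, spec.lower, spec.upper)
        return spec.k * delta * delta
    com, _ = _com(coords, spec.selection_a, masses)
    lam = com[..., spec.axis]
    delta = _excess(lam, spec.lower, spec.upper)
    return spec.k * delta * delta


class RestraintTerm(PotentialTerm):
    """Adapter exposing a :class:`RestraintSpec` as a potential term."""

    def __init__(self, spec: RestraintSpec, masses: np.ndarray | None = None):
        self.spec = spec
        self.masses = masses if masses is not None else spec.masses

    def energy(self, coords):
        return restraint_energy(coords, self.spec, self.masses)

    def force(self, coords):
        spec = self.spec
        f = np.zeros_like(coords)
        if spec.kind == "flat_bottom_distance":
            ca, wa = _com(coords, spec.selection_a, self.masses)
            cb, wb = _com(coords, spec.selection_b, self.masses)
            rij = ca - cb
            d = np.sqrt(np.sum(rij * rij, axis=-1))
            delta = _excess(d, spec.lower, spec.upper)
            g = 2.0 * spec.k * delta[..., None] * rij / np.maximum(d, 1e-12)[..., None]
            for idx, w in zip(np.atleast_1d(spec.selection_a), wa):
                f[..., idx, :] -= w * g
            for idx, w in zip(np.atleast_1d(spec.selection_b), wb):
                f[..., idx, :] += w * g
            return f
        com, w = _com(coords, spec.selection_a, self.masses)
        lam = com[..., spec.axis]
        delta = _excess(lam, spec.lower, spec.upper)
        g = 2.0 * spec.k * delta
        for idx, wi in zip(np.atleast_1d(spec.selection_a), w):
            f[..., idx, spec.axis] -= wi * g
        return f


# ---------------------------------------------------------------------------
# Toy system
# ---------------------------------------------------------------------------


@dataclass
class ToySystem:
    """Coarse-grained particle system: potential terms plus restraints.

    ``topology`` provides atom/residue/chain bookkeeping so ensemble-analysis
    operations (contacts, RMSD, SASA) apply unchanged; ``mobile_mask`` marks
    particles the sampler may move (the receptor scaffold is typically fixed).
    """

    topology: StructureModel
    terms: list[PotentialTerm]
    restraints: list[RestraintSpec] = field(default_factory=list)
    mobile_mask: np.ndarray | None = None
    x0: np.ndarray | None = None
    step_size: float = 0.25

    def __post_init__(self):
        if self.x0 is None:
            self.x0 = np.array(self.topology.coords, dtype=float)
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.mobile_mask is None:
            self.mobile_mask = np.ones(self.topology.n_atoms, dtype=bool)
        self._restraint_terms = [
            RestraintTerm(r, self.topology.atom_masses()) for r in self.restraints
        ]
        e0 = float(self.energy(self.x0))
        if not np.isfinite(e0):
            raise ValueError("potential not finite at the reference configuration")

    @property
    def ndim(self) -> int:
        return self.x0.shape[-1]

    def energy(self, coords: np.ndarray, include_restraints: bool = True) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        total = np.zeros(coords.shape[:-2])
        for term in self.terms:
            total = total + term.energy(coords)
        if include_restraints:
            for term in self._restraint_terms:
                total = total + term.energy(coords)
        return total

    def force(self, coords: np.ndarray, include_restraints: bool = True) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        f = np.zeros_like(coords)
        for term in self.terms:
            f = f + term.force(coords)
        if include_restraints:
            for term in self._restraint_terms:
                f = f + term.force(coords)
        return f

    def without_restraints(self) -> "ToySystem":
        return ToySystem(self.topology, self.terms, [], self.mobile_mask,
                         self.x0, self.step_size)


# ---------------------------------------------------------------------------
# Bias function
# ---------------------------------------------------------------------------


class BiasFunction:
    """Modified-energy mapping E -> E_mc for multicanonical sampling.

    Monotone non-decreasing piecewise-cubic (PCHIP) inside the fitted range
    [e_min, e_max], continued linearly outside with the boundary slopes, so
    the mapping is defined and differentiable everywhere.
    """

    def __init__(self, knots: np.ndarray, values: np.ndarray, t_mc: float,
                 bias_id: str = "bias"):
        knots = np.asarray(knots, dtype=float)
        values = np.asarray(values, dtype=float)
        order = np.argsort(knots)
        knots, values = knots[order], values[order]
        # drop duplicate knots, enforce monotone non-decreasing values
        keep = np.concatenate([[True], np.diff(knots) > 1e-12])
        knots, values = knots[keep], values[keep]
        if len(knots) < 2:
            raise ValueError("bias needs at least two distinct knots")
        values = np.maximum.accumulate(values)
        self.knots, self.values = knots, values
        self.t_mc = float(t_mc)
        self.bias_id = bias_id
        self.e_min, self.e_max = float(knots[0]), float(knots[-1])
        self._interp = PchipInterpolator(knots, values, extrapolate=False)
        d = self._interp.derivative()
        # linear tails never flatter than the identity: outside the fitted
        # range the effective temperature T_mc / slope stays <= T_mc, so the
        # sampler cannot run away up an unbounded potential
        self._slope_lo = max(float(d(self.e_min)), 1.0)
        self._slope_hi = max(float(d(self.e_max)), 1.0)
        self._v_lo = float(values[0])
        self._v_hi = float(values[-1])

    @classmethod
    def identity(cls, t_mc: float, e_range: tuple[float, float]) -> "BiasFunction":
        knots = np.linspace(e_range[0], e_range[1], 8)
        return cls(knots, knots.copy(), t_mc, bias_id="identity")

    def __call__(self, energy: np.ndarray) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        out = np.empty_like(e, dtype=float)
        lo = e < self.e_min
        hi = e > self.e_max
        mid = ~(lo | hi)
        out[mid] = self._interp(e[mid])
        out[lo] = self._v_lo + self._slope_lo * (e[lo] - self.e_min)
        out[hi] = self._v_hi + self._slope_hi * (e[hi] - self.e_max)
        return out if out.shape else float(out)

    def is_monotone(self) -> bool:
        grid = np.linspace(self.e_min, self.e_max, 512)
        return bool(np.all(np.diff(self.__call__(grid)) >= -1e-9))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class McMDConfig:
    """Multicanonical protocol settings (temperatures in K, energies kcal/mol)."""

    t_low: float = 280.0
    t_high: float = 700.0
    schedule: tuple[int, ...] = (2000, 2000, 3000, 3000, 4000, 4000, 6000, 6000, 8000)
    flatness_tol: float = 1.2
    bin_width: float = 0.5
    n_parallel: int = 16
    base_seed: int = 0
    save_interval: int = 5
    # optional Savitzky-Golay smoothing of binned bias values; 0 disables it
    # (the monotone piecewise-cubic fit already regularizes the curve)
    smooth_window: int = 0

    def __post_init__(self):
        if not self.t_low < self.t_high:
            raise ValueError("t_low must be below t_high")
        if any(s <= 0 for s in self.schedule):
            raise ValueError("all schedule lengths must be positive")


# ---------------------------------------------------------------------------
# Metropolis sampler
# ---------------------------------------------------------------------------


def _sample(system: ToySystem, mod_energy, T: float, n_sweeps: int, seed: int,
            n_walkers: int, save_interval: int, x0: np.ndarray | None,
            quench: bool, metadata: dict) -> Ensemble:
    if T <= 0 and not quench:
        raise ValueError("temperature must be positive")
    ndim = system.ndim
    mobile = np.nonzero(system.mobile_mask)[0]
    n_mob = len(mobile)
    if x0 is None:
        coords = np.broadcast_to(system.x0, (n_walkers,) + system.x0.shape).copy()
    else:
        x0 = np.asarray(x0, dtype=float)
        coords = (np.broadcast_to(x0, (n_walkers,) + system.x0.shape).copy()
                  if x0.ndim == 2 else x0.copy())

    # one generator per walker, seeded from (base seed, walker index); all
    # randomness drawn up front so runs are reproducible per trajectory
    children = np.random.SeedSequence(seed).spawn(n_walkers)
    gens = [np.random.Generator(np.random.Philox(s)) for s in children]
    normals = np.stack([g.standard_normal((n_sweeps, n_mob, ndim)) for g in gens])
    uniforms = np.stack([g.random((n_sweeps, n_mob)) for g in gens])
    normals *= system.step_size

    e_cur = system.energy(coords)
    m_cur = mod_energy(e_cur)
    beta = 0.0 if quench else 1.0 / (R_KCAL * T)

    frames, energies, tids, fids = [], [], [], []
    walkers = np.arange(n_walkers)
    for sweep in range(n_sweeps):
        for pi, p in enumerate(mobile):
            old = coords[:, p, :].copy()
            coords[:, p, :] = old + normals[:, sweep, pi, :]
            e_new = system.energy(coords)
            m_new = mod_energy(e_new)
            if not np.all(np.isfinite(e_new)):
                raise RuntimeError(
                    f"non-finite energy at sweep {sweep}, particle {p}: "
                    "the sampler diverged"
                )
            d_m = np.asarray(m_new - m_cur)
            if quench:
                accept = d_m <= 0.0
            else:
                accept = uniforms[:, sweep, pi] < np.exp(np.minimum(-beta * d_m, 0.0))
            reject = ~accept
            coords[reject, p, :] = old[reject]
            e_cur = np.where(accept, e_new, e_cur)
            m_cur = np.where(accept, m_new, m_cur)
        if (sweep + 1) % save_interval == 0:
            frames.append(coords.copy())
            energies.append(e_cur.copy())
            tids.append(walkers.copy())
            fids.append(np.full(n_walkers, sweep + 1))

    if not frames:
        raise ValueError("no frames saved: save_interval exceeds n_sweeps")
    # group frames by trajectory so each walker forms one contiguous block
    coords_arr = np.stack(frames)           # (n_saved, W, n, d)
    e_arr = np.stack(energies)
    n_saved = coords_arr.shape[0]
    coords_flat = np.transpose(coords_arr, (1, 0, 2, 3)).reshape(
        n_walkers * n_saved, system.topology.n_atoms, ndim)
    e_flat = np.transpose(e_arr, (1, 0)).reshape(-1)
    t_flat = np.repeat(walkers, n_saved)
    f_flat = np.tile(np.stack(fids)[:, 0], n_walkers)
    return Ensemble(system.topology, coords_flat, e_flat, t_flat, f_flat, metadata)


def run_canonical(system: ToySystem, T: float, n_steps: int, seed: int,
                  n_walkers: int = 1, save_interval: int = 5,
                  x0: np.ndarray | None = None, quench: bool = False) -> Ensemble:
    """Canonical Metropolis sampling at temperature ``T``.

    ``n_steps`` counts sweeps (one proposed move per mobile particle each).
    Identical ``seed`` gives bitwise-identical output.  ``quench=True`` runs
    greedy descent (the zero-temperature limit).
    """
    if T <= 0 and not quench:
        raise ValueError("temperature must be positive")
    meta = {"kind": "canonical", "T": T, "seed": seed,
            "save_interval": save_interval, "quench": quench}
    return _sample(system, lambda e: e, T, n_steps, seed, n_walkers,
                   save_interval, x0, quench, meta)


def run_mcmd(system: ToySystem, bias: BiasFunction, n_steps: int, seed: int,
             n_walkers: int = 1, save_interval: int = 5,
             x0: np.ndarray | None = None) -> Ensemble:
    """Multicanonical sampling with modified energy ``bias`` at ``bias.t_mc``."""
    meta = {"kind": "mcmd", "t_mc": bias.t_mc, "bias_id": bias.bias_id,
            "seed": seed, "save_interval": save_interval}
    return _sample(system, bias, bias.t_mc, n_steps, seed, n_walkers,
                   save_interval, x0, False, meta)


def run_langevin(system: ToySystem, T: float, n_steps: int, seed: int,
                 dt: float = 1e-3, gamma: float = 1.0,
                 n_walkers: int = 1, save_interval: int = 5,
                 x0: np.ndarray | None = None) -> Ensemble:
    """Overdamped Langevin integration (Euler–Maruyama) at temperature ``T``."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    coords = np.broadcast_to(
        system.x0 if x0 is None else np.asarray(x0, dtype=float),
        (n_walkers,) + system.x0.shape).copy()
    mobile = system.mobile_mask
    sigma = np.sqrt(2.0 * R_KCAL * T * dt / gamma)
    frames, energies = [], []
    for step in range(n_steps):
        f = system.force(coords)
        noise = rng.standard_normal(coords.shape)
        coords[:, mobile, :] += (f[:, mobile, :] / gamma) * dt + sigma * noise[:, mobile, :]
        if (step + 1) % save_interval == 0:
            e = system.energy(coords)
            if not np.all(np.isfinite(e)):
                raise RuntimeError(f"non-finite energy at step {step}")
            frames.append(coords.copy())
            energies.append(e)
    coords_arr = np.concatenate(frames)
    e_arr = np.concatenate(energies)
    meta = {"kind": "langevin", "T": T, "seed": seed, "dt": dt}
    n_saved = len(frames)
    tids = np.tile(np.arange(n_walkers), n_saved)
    return Ensemble(system.topology, coords_arr, e_arr, tids, metadata=meta)


# ---------------------------------------------------------------------------
# Bias estimation and iteration
# ---------------------------------------------------------------------------


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if len(values) < 5 or window < 5:
        return values
    window = min(window if window % 2 == 1 else window - 1, len(values) - (1 - len(values) % 2))
    if window < 5:
        return values
    return savgol_filter(values, window, 3)


def estimate_initial_bias(canonical_run: Ensemble, cfg: McMDConfig) -> BiasFunction:
    """Initial multicanonical bias from a canonical run at T_high.

    The density of states along energy is estimated from the high-temperature
    canonical histogram, ln n(E) = ln P(E, T_high) + E / (R T_high); the
    modified energy E_mc(E) = R T_high ln n(E) then targets a flat energy
    histogram when sampled at T_mc = T_high.  The fitted curve is smoothed and
    continued linearly outside the sampled range.
    """
    energies = canonical_run.energies
    lo, hi = energies.min(), energies.max()
    n_bins = int(np.clip(np.ceil((hi - lo) / cfg.bin_width), 1, 4000))
    counts, edges = np.histogram(energies, bins=n_bins, range=(lo, hi + 1e-9))
    centers = 0.5 * (edges[:-1] + edges[1:])
    nonzero = counts > 0
    if np.count_nonzero(nonzero) < 5:
        raise ValueError(
            "too few distinct energy bins to estimate a bias; "
            "run a longer high-temperature seed simulation"
        )
    centers, counts = centers[nonzero], counts[nonzero]
    ln_n = np.log(counts) + centers / (R_KCAL * cfg.t_high)
    e_mc = R_KCAL * cfg.t_high * ln_n
    e_mc = _smooth(e_mc, cfg.smooth_window)
    return BiasFunction(centers, e_mc, cfg.t_high, bias_id="initial")


def update_bias(bias: BiasFunction, production: Ensemble, cfg: McMDConfig) -> BiasFunction:
    """Flattening update: add R T_mc ln P_obs(E) to the modified energy.

    Over-sampled energies are penalized; a flat observed histogram is a fixed
    point (the update is then a constant shift).  Empty bins inside the
    sampled range are bridged by linear interpolation of ln P with a warning.
    """
    energies = production.energies
    lo = min(bias.e_min, energies.min())
    hi = max(bias.e_max, energies.max())
    n_bins = int(np.clip(np.ceil((hi - lo) / cfg.bin_width), 2, 4000))
    counts, edges = np.histogram(energies, bins=n_bins, range=(lo, hi + 1e-9))
    centers = 0.5 * (edges[:-1] + edges[1:])
    nonzero = counts > 0
    first, last = np.argmax(nonzero), len(counts) - 1 - np.argmax(nonzero[::-1])
    inside = np.arange(first, last + 1)
    ln_p = np.full(len(counts), np.nan)
    ln_p[nonzero] = np.log(counts[nonzero] / counts.sum())
    holes = inside[~nonzero[inside]]
    if len(holes):
        warnings.warn(f"{len(holes)} empty energy bins bridged by interpolation")
        ln_p[holes] = np.interp(centers[holes], centers[nonzero], ln_p[nonzero])
    centers, ln_p = centers[inside], ln_p[inside]
    new_values = bias(centers) + R_KCAL * bias.t_mc * ln_p
    new_values = _smooth(new_values, cfg.smooth_window)
    try:
        n_prev = int(bias.bias_id.rsplit("-", 1)[1])
    except (IndexError, ValueError):
        n_prev = 0
    return BiasFunction(centers, new_values, bias.t_mc, bias_id=f"update-{n_prev + 1}")


def target_energy_range(production: Ensemble, bias: BiasFunction,
                        cfg: McMDConfig) -> tuple[float, float]:
    """Canonical mean energies [<E>(T_low), <E>(T_high)] from reweighting."""
    from .reweight import canonical_weights

    e = production.energies
    out = []
    for T in (cfg.t_low, cfg.t_high):
        w = canonical_weights(production, bias, T)
        out.append(float(np.sum(w.weights * e)))
    return out[0], out[1]


def flatness_ratio(production: Ensemble, bias: BiasFunction, cfg: McMDConfig,
                   e_range: tuple[float, float] | None = None) -> float:
    """Max/min energy-histogram count ratio over the target canonical range."""
    if e_range is None:
        e_range = target_energy_range(production, bias, cfg)
    lo, hi = e_range
    if hi <= lo:
        return np.inf
    n_bins = max(int(np.ceil((hi - lo) / cfg.bin_width)), 2)
    counts, _ = np.histogram(production.energies, bins=n_bins, range=(lo, hi))
    if counts.min() == 0:
        return np.inf
    return float(counts.max() / counts.min())


def calibrate_bias(system: ToySystem, cfg: McMDConfig,
                   x0: np.ndarray | None = None) -> tuple[BiasFunction, Ensemble, dict]:
    """Run the full bias-flattening iteration.

    A canonical randomization run at T_high seeds the initial bias; each
    subsequent iteration samples under the current bias, measures flatness
    over [<E>(T_low), <E>(T_high)], and updates the bias until the tolerance
    or the schedule is exhausted.  Returns the final bias, the last
    multicanonical ensemble, and per-iteration diagnostics.
    """
    seed_run = run_canonical(system, cfg.t_high, cfg.schedule[0], cfg.base_seed,
                             n_walkers=cfg.n_parallel,
                             save_interval=cfg.save_interval, x0=x0)
    bias = estimate_initial_bias(seed_run, cfg)
    history: list[dict] = []
    production = None
    for it, length in enumerate(cfg.schedule[1:], start=1):
        production = run_mcmd(system, bias, length, cfg.base_seed + it,
                              n_walkers=cfg.n_parallel,
                              save_interval=cfg.save_interval, x0=x0)
        e_range = target_energy_range(production, bias, cfg)
        ratio = flatness_ratio(production, bias, cfg, e_range)
        history.append({"iteration": it, "flatness": ratio,
                        "e_range": e_range, "n_frames": len(production)})
        if ratio <= cfg.flatness_tol:
            break
        bias = update_bias(bias, production, cfg)
    diagnostics = {"history": history,
                   "converged": bool(history and history[-1]["flatness"] <= cfg.flatness_tol)}
    return bias, production, diagnostics
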