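"""Structural observables: secondary structure, solvent accessibility,
pocket distances and the dissociation coordinate λ.

Secondary structure follows the Kabsch–Sander construction: an electrostatic
backbone hydrogen-bond energy
    E = 0.084 (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · 332   kcal/mol,
a bond where E < −0.5 kcal/mol, α-helix (H) from two consecutive i→i+4
turns, 3₁₀ (G) from i→i+3 turns, and strand (E) from parallel/antiparallel
bridges, with priority H > E > G.  The amide H is placed geometrically from
the preceding carbonyl when absent.  Helicity counts class H only.

Solvent accessibility uses the Shrake–Rupley sphere-point method with a
deterministic golden-spiral point set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import PROBE_RADIUS, VDW_RADII
from .core import Snapshot, StructureModel, pad3d
from .reweight import WeightVector

Structure = StructureModel | Snapshot


def _as_structure(s: Structure) -> StructureModel:
    return s.as_structure() if isinstance(s, Snapshot) else s


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch–Sander)
# ---------------------------------------------------------------------------

#: Kabsch–Sander H-bond constants: partial charges factor and Coulomb constant.
_KS_Q = 0.084
_KS_F = 332.0
_HBOND_CUT = -0.5


@dataclass
class SSLabels:
    """Per-residue secondary-structure class: H (α), G (3₁₀), E (strand), C."""

    labels: np.ndarray            # unicode chars, one per residue
    res_ids: np.ndarray
    chain_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)

    def helix_mask(self) -> np.ndarray:
        return self.labels == "H"


def _backbone_table(s: StructureModel):
    """Ordered residue list with N/CA/C/O atom indices (None when missing)."""
    residues = []
    seen = {}
    for i in range(s.n_atoms):
        key = (str(s.chain_ids[i]), int(s.res_ids[i]))
        if key not in seen:
            seen[key] = {"chain": key[0], "res_id": key[1],
                         "N": None, "CA": None, "C": None, "O": None, "H": None}
            residues.append(seen[key])
        name = str(s.atom_names[i])
        if name in ("N", "CA", "C", "O"):
            seen[key][name] = i
        elif name in ("H", "HN"):
            seen[key]["H"] = i
    return residues


def assign_ss(structure: Structure) -> SSLabels:
    """Kabsch–Sander secondary-structure assignment.

    Residues missing a backbone atom are labeled C with a warning; chain
    termini can never be H by the i→i+4 rule.
    """
    s = _as_structure(structure)
    coords = pad3d(s.coords)
    residues = _backbone_table(s)
    n = len(residues)
    complete = np.zeros(n, dtype=bool)
    for k, r in enumerate(residues):
        complete[k] = all(r[a] is not None for a in ("N", "CA", "C", "O"))
        if not complete[k]:
            warnings.warn(
                f"residue {r['chain']}:{r['res_id']} missing backbone atoms; labeled C"
            )

    # H positions: 1 Å from N opposite the preceding carbonyl (C_prev - O_prev)
    h_pos = np.full((n, 3), np.nan)
    for k, r in enumerate(residues):
        if not complete[k]:
            continue
        if r["H"] is not None:
            h_pos[k] = coords[r["H"]]
        elif k > 0 and residues[k - 1]["chain"] == r["chain"] and complete[k - 1]:
            prev = residues[k - 1]
            co = coords[prev["C"]] - coords[prev["O"]]
            h_pos[k] = coords[r["N"]] + co / np.linalg.norm(co)

    def hbond(acc: int, don: int) -> bool:
        """H-bond with acceptor CO of residue ``acc`` and donor NH of ``don``."""
        if acc == don or not (complete[acc] and complete[don]):
            return False
        if np.any(np.isnan(h_pos[don])):
            return False
        c = coords[residues[acc]["C"]]
        o = coords[residues[acc]["O"]]
        nn = coords[residues[don]["N"]]
        h = h_pos[don]
        r_on = np.linalg.norm(o - nn)
        r_ch = np.linalg.norm(c - h)
        r_oh = np.linalg.norm(o - h)
        r_cn = np.linalg.norm(c - nn)
        if min(r_on, r_ch, r_oh, r_cn) < 0.5:
            return False
        e = _KS_Q * _KS_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
        return e < _HBOND_CUT

    def same_chain(i, j):
        return residues[i]["chain"] == residues[j]["chain"]

    # exclude donor = acceptor's successor (covalent neighbour) explicitly
    def hb(acc, don):
        if same_chain(acc, don) and don == acc + 1:
            return False
        return hbond(acc, don)

    turn3 = np.zeros(n, dtype=bool)
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n):
        if i + 3 < n and same_chain(i, i + 3):
            turn3[i] = hb(i, i + 3)
        if i + 4 < n and same_chain(i, i + 4):
            turn4[i] = hb(i, i + 4)

    labels = np.full(n, "C", dtype="<U1")
    for i in range(1, n):
        if turn4[i - 1] and turn4[i] and i + 3 < n:
            labels[i:i + 4] = "H"

    # bridges (strand): Kabsch–Sander parallel / antiparallel definitions
    bridge = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            par = (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))
            anti = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if par or anti:
                bridge[i] = bridge[j] = True
    strand = bridge & (labels != "H")
    labels[strand] = "E"

    for i in range(1, n):
        if turn3[i - 1] and turn3[i] and i + 2 < n:
            seg = slice(i, i + 3)
            free = labels[seg] == "C"
            idx = np.arange(i, i + 3)[free]
            labels[idx] = "G"

    labels[~complete] = "C"
    return SSLabels(labels,
                    np.asarray([r["res_id"] for r in residues]),
                    np.asarray([r["chain"] for r in residues], dtype=object))


def helicity_profile(ensemble, weights: WeightVector,
                     chain: str | None = None) -> "tuple[np.ndarray, np.ndarray]":
    """Reweighted per-residue α-helix probability over an ensemble.

    Returns ``(res_ids, probability)`` for the selected chain (default: the
    ligand chain).  Only class H counts as helix.
    """
    top = ensemble.topology
    if chain is None:
        lig_chains = [c for c, r in top.chain_roles.items() if r == "ligand"]
        chain = lig_chains[0] if lig_chains else str(top.chain_ids[0])
    prob = None
    res_ids = None
    for k, snap in enumerate(ensemble):
        ss = assign_ss(snap)
        mask = ss.chain_ids == chain
        if prob is None:
            res_ids = ss.res_ids[mask]
            prob = np.zeros(mask.sum())
        prob += weights.weights[k] * (ss.labels[mask] == "H")
    total = weights.weights.sum()
    return res_ids, prob / total if total > 0 else prob


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake–Rupley)
# ---------------------------------------------------------------------------


@dataclass
class SASAResult:
    """Per-atom and total solvent-accessible surface area (Å²)."""

    per_atom: np.ndarray
    probe: float

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def atom_radii(s: StructureModel) -> np.ndarray:
    if s.radii is not None:
        return np.asarray(s.radii, dtype=float)
    out = []
    for e in s.elements:
        key = str(e).upper()[:1] if str(e).upper() not in VDW_RADII else str(e).upper()
        if key not in VDW_RADII:
            raise KeyError(f"no van der Waals radius for element {e!r}")
        out.append(VDW_RADII[key])
    return np.asarray(out)


def sasa(structure: Structure, selection: np.ndarray | None = None,
         probe: float = PROBE_RADIUS, n_points: int = 960,
         context: np.ndarray | None = None) -> SASAResult:
    """Shrake–Rupley accessible surface area of ``selection`` atoms.

    ``context`` atoms (default: all atoms) occlude but are not reported.
    Deterministic given ``n_points``.
    """
    s = _as_structure(structure)
    coords = pad3d(s.coords)
    radii = atom_radii(s)
    if selection is None:
        selection = np.arange(s.n_atoms)
    selection = np.asarray(selection)
    if context is None:
        context = np.arange(s.n_atoms)
    context = np.asarray(context)
    pts = _sphere_points(n_points)
    areas = np.zeros(len(selection))
    for k, i in enumerate(selection):
        ri = radii[i] + probe
        sphere = coords[i] + ri * pts
        buried = np.zeros(n_points, dtype=bool)
        for j in context:
            if j == i:
                continue
            rj = radii[j] + probe
            d = coords[j] - coords[i]
            if d @ d > (ri + rj) ** 2:
                continue
            buried |= np.sum((sphere - coords[j]) ** 2, axis=1) < rj * rj
        areas[k] = 4.0 * np.pi * ri * ri * (1.0 - buried.mean())
    return SASAResult(areas, probe)


def rasa(complex_snapshot: Structure, ligand_role: str = "ligand",
         probe: float = PROBE_RADIUS, n_points: int = 960) -> float:
    """Relative accessible surface area of the ligand in the complex.

    SASA of the ligand atoms within the complex divided by the SASA of the
    same conformation extracted alone; 1 when fully exposed, → 0 when buried.
    """
    s = _as_structure(complex_snapshot)
    lig = np.nonzero(s.role_mask(ligand_role))[0]
    in_complex = sasa(s, selection=lig, probe=probe, n_points=n_points).total
    alone = sasa(s, selection=lig, probe=probe, n_points=n_points,
                 context=lig).total
    if alone <= 0:
        raise ValueError("isolated ligand SASA is zero")
    return in_complex / alone


# ---------------------------------------------------------------------------
# Pocket distances and λ
# ---------------------------------------------------------------------------

#: Cα pairs of the cryptic-groove width profile d0–d4 (receptor residue ids).
DEFAULT_POCKET_PAIRS = ((112, 122), (108, 126), (105, 130), (101, 139), (96, 136))


@dataclass
class PocketProfile:
    """Named pocket-width distances (Å) per snapshot."""

    names: list[str]
    distances: np.ndarray
    pairs: tuple


def pocket_distances(structure: Structure,
                     pairs: tuple = DEFAULT_POCKET_PAIRS,
                     chain: str | None = None,
                     atom_name: str = "CA") -> PocketProfile:
    """Cα–Cα distances for a list of residue pairs, in listed order."""
    s = _as_structure(structure)
    coords = pad3d(s.coords)
    dists = []
    for a, b in pairs:
        ia = s.select(chain_id=chain, res_id=a, atom_name=atom_name)
        ib = s.select(chain_id=chain, res_id=b, atom_name=atom_name)
        if len(ia) == 0 or len(ib) == 0:
            raise ValueError(f"cannot resolve {atom_name} of residue pair {a}-{b}")
        dists.append(float(np.linalg.norm(coords[ia[0]] - coords[ib[0]])))
    names = [f"d{i}" for i in range(len(pairs))]
    return PocketProfile(names, np.asarray(dists), tuple(pairs))


def lambda_coord(structure: Structure, ligand_role: str = "ligand",
                 axis: int = 0) -> float:
    """Mass-weighted ligand center-of-mass coordinate along ``axis`` (Å)."""
    s = _as_structure(structure)
    lig = s.role_mask(ligand_role)
    m = s.atom_masses()[lig]
    return float(np.sum(s.coords[lig, axis] * m) / m.sum())


def lambda_coord_frames(ensemble, ligand_role: str = "ligand",
                        axis: int = 0) -> np.ndarray:
    """λ per frame of an ensemble (vectorized)."""
    top = ensemble.topology
    lig = top.role_mask(ligand_role)
    m = top.atom_masses()[lig]
    return np.asarray(ensemble.coords[:, lig, axis] @ m / m.sum())
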