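"""Contact-preservation similarity (R-value), per-residue decomposition, RMSD.

The R-value of a query structure against a reference is the fraction of the
reference's contacts that are preserved in the query,
R = |C(query) ∩ C(ref)| / |C(ref)|, over a chosen scope (intermolecular,
intramolecular, or both).  A contact is a heavy-atom pair within a cutoff
(default 4.5 Å); intramolecular pairs exclude same-residue and sequence
neighbours |Δres| ≤ 2.  R is asymmetric: the reference fixes the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import CONTACT_CUTOFF
from .core import Snapshot, StructureModel, pad3d


Structure = StructureModel | Snapshot


def _as_structure(s: Structure) -> StructureModel:
    return s.as_structure() if isinstance(s, Snapshot) else s


@dataclass
class ContactSet:
    """Atom-index pairs in contact, with the scope and cutoff that built them."""

    pairs: frozenset
    scope: str
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)


def contact_set(structure: Structure, scope: str = "inter",
                cutoff: float = CONTACT_CUTOFF) -> ContactSet:
    """Heavy-atom contact pairs of a structure within ``cutoff``.

    ``scope``: ``"inter"`` keeps only pairs spanning different molecules
    (chain roles when declared, chain ids otherwise), ``"intra"`` only
    within-chain pairs (excluding same-residue and |Δres| ≤ 2 neighbours),
    ``"both"`` keeps the union.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if scope not in ("inter", "intra", "both"):
        raise ValueError(f"unknown scope {scope!r}")
    s = _as_structure(structure)
    heavy = np.nonzero(s.heavy_mask())[0]
    if len(heavy) == 0:
        raise ValueError("structure has no heavy atoms")
    coords = pad3d(s.coords)[heavy]
    tree = cKDTree(coords)
    out = set()
    chains, res = s.chain_ids, s.res_ids
    roles = s.chain_roles

    def molecule(chain: str) -> str:
        return roles.get(chain, chain)

    for a_loc, b_loc in tree.query_pairs(cutoff):
        a, b = int(heavy[a_loc]), int(heavy[b_loc])
        ca, cb = str(chains[a]), str(chains[b])
        is_inter = molecule(ca) != molecule(cb)
        is_intra = ca == cb and abs(int(res[a]) - int(res[b])) > 2
        if scope == "inter" and not is_inter:
            continue
        if scope == "intra" and not is_intra:
            continue
        if scope == "both" and not (is_inter or is_intra):
            continue
        out.add((min(a, b), max(a, b)))
    return ContactSet(frozenset(out), scope, cutoff)


def r_value(structure: Structure, reference: Structure, scope: str = "inter",
            cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of the reference's contacts preserved in ``structure``.

    Raises ``ValueError`` when the reference has no contacts in scope (the
    R-value is undefined there).
    """
    ref = contact_set(reference, scope, cutoff)
    if len(ref) == 0:
        raise ValueError("reference has no contacts in scope; R-value undefined")
    query = contact_set(structure, scope, cutoff)
    return len(ref.pairs & query.pairs) / len(ref.pairs)


@dataclass
class RValueReport:
    """Global and per-residue contact preservation against a reference."""

    global_r: float
    residue_ids: np.ndarray
    residue_r: np.ndarray        # NaN where a residue has no reference contacts
    residue_n_ref: np.ndarray    # reference contacts involving each residue
    scope: str
    cutoff: float


def per_residue_r_value(structure: Structure, reference: Structure,
                        scope: str = "inter",
                        cutoff: float = CONTACT_CUTOFF,
                        chain: str | None = None) -> RValueReport:
    """Per-residue preserved fraction of reference contacts.

    Residue i's value is the preserved fraction of reference contacts that
    involve any atom of residue i; residues without reference contacts are
    NaN.  The contact-weighted mean of the per-residue values (each contact
    counted once per participating residue) equals the global R exactly.
    """
    ref_struct = _as_structure(reference)
    ref = contact_set(reference, scope, cutoff)
    if len(ref) == 0:
        raise ValueError("reference has no contacts in scope; R-value undefined")
    query = contact_set(structure, scope, cutoff)
    preserved = ref.pairs & query.pairs

    res_of = ref_struct.res_ids
    chain_of = ref_struct.chain_ids
    if chain is None:
        keys = sorted({(str(chain_of[a]), int(res_of[a]))
                       for pair in ref.pairs for a in pair})
    else:
        keys = sorted({(str(chain_of[a]), int(res_of[a]))
                       for pair in ref.pairs for a in pair
                       if chain_of[a] == chain})
    index = {key: k for k, key in enumerate(keys)}
    n_ref = np.zeros(len(keys))
    n_pres = np.zeros(len(keys))
    for pair in ref.pairs:
        hit = pair in preserved
        for a in pair:
            key = (str(chain_of[a]), int(res_of[a]))
            if key in index:
                n_ref[index[key]] += 1
                if hit:
                    n_pres[index[key]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = np.where(n_ref > 0, n_pres / np.maximum(n_ref, 1), np.nan)
    return RValueReport(
        global_r=len(preserved) / len(ref.pairs),
        residue_ids=np.asarray([r for _, r in keys]),
        residue_r=rr,
        residue_n_ref=n_ref,
        scope=scope,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal least-squares rotation (Kabsch, via SVD) mapping mobile→target.

    Both inputs must already be centered.
    """
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0] * (h.shape[0] - 1) + [d])
    return vt.T @ corr @ u.T


def rmsd(structure: Structure, reference: Structure,
         selection: np.ndarray | None = None, superpose: bool = True) -> float:
    """Root-mean-square deviation in Å over ``selection`` (default: heavy atoms).

    With ``superpose`` the optimal rigid rotation+translation is removed
    first; otherwise the raw deviation in the current frame is returned.
    """
    s = _as_structure(structure)
    r = _as_structure(reference)
    if selection is None:
        selection = np.nonzero(r.heavy_mask())[0]
    selection = np.asarray(selection)
    if s.n_atoms != r.n_atoms:
        raise ValueError("structure and reference must share a topology")
    x = pad3d(s.coords)[selection]
    y = pad3d(r.coords)[selection]
    if x.shape != y.shape:
        raise ValueError("mismatched selections")
    if superpose:
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        rot = kabsch_rotation(xc, yc)
        x = xc @ rot.T
        y = yc
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=-1))))


def ligand_rmsd_receptor_frame(structure: Structure, reference: Structure,
                               heavy_only: bool = True) -> float:
    """Ligand RMSD after superposing on the receptor (complex-frame RMSD).

    The rigid fit uses receptor atoms only, then the deviation is measured
    over ligand (heavy) atoms — the receptor-fixed frame used for the λ
    coordinate and the representative tables.
    """
    s = _as_structure(structure)
    r = _as_structure(reference)
    rec = np.nonzero(r.role_mask("receptor"))[0]
    lig = np.nonzero(r.role_mask("ligand"))[0]
    if heavy_only:
        heavy = r.heavy_mask()
        rec = rec[heavy[rec]]
        lig = lig[heavy[lig]]
    x = pad3d(s.coords)
    y = pad3d(r.coords)
    mx = x[rec].mean(axis=0)
    my = y[rec].mean(axis=0)
    rot = kabsch_rotation(x[rec] - mx, y[rec] - my)
    x_fit = (x - mx) @ rot.T + my
    return float(np.sqrt(np.mean(np.sum((x_fit[lig] - y[lig]) ** 2, axis=-1))))
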