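"""Domain types, structure / ensemble I/O and bookkeeping arithmetic.

The central containers are :class:`StructureModel` (a topology with one set of
coordinates), :class:`Snapshot` (one frame of an ensemble) and
:class:`Ensemble` (frames stored as a dense coordinate array plus a potential
energy per frame).  Structures are read and written in a narrow PDB dialect
(ATOM/HETATM/TER/END records only); ensembles have an HDF5 container format
and a plain-text JSON exchange form used for small fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be interpreted."""


# ---------------------------------------------------------------------------
# Residue templates
# ---------------------------------------------------------------------------

#: Atom counts (hydrogens included) of the Amber-style all-hydrogen residue
#: templates at neutral pH (His as the Nε2-protonated HIE tautomer), plus the
#: ACE / NHE terminal caps.
AMBER_ATOM_COUNTS = {
    "ALA": 10, "ARG": 24, "ASN": 14, "ASP": 12, "CYS": 11,
    "GLN": 17, "GLU": 15, "GLY": 7, "HIS": 17, "ILE": 19,
    "LEU": 19, "LYS": 22, "MET": 17, "PHE": 20, "PRO": 14,
    "SER": 11, "THR": 14, "TRP": 24, "TYR": 21, "VAL": 16,
    "ACE": 6, "NHE": 3,
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class ResidueTemplateTable:
    """Mapping residue code -> atom count (hydrogens included)."""

    counts: Mapping[str, int] = field(default_factory=lambda: dict(AMBER_ATOM_COUNTS))

    def __post_init__(self) -> None:
        for code, n in self.counts.items():
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ValueError(f"atom count for {code!r} must be a positive integer")

    def __getitem__(self, code: str) -> int:
        try:
            return self.counts[code]
        except KeyError:
            raise KeyError(f"unknown residue code {code!r}") from None


def count_atoms(
    sequence: str,
    n_cap: str = "ACE",
    c_cap: str = "NHE",
    table: ResidueTemplateTable | None = None,
) -> int:
    """Atom count of a capped peptide built from residue templates.

    ``sequence`` is a one-letter amino-acid string; ``n_cap`` / ``c_cap`` are
    three-letter cap codes.  The count is the sum of the per-residue template
    atom counts plus both caps.
    """
    if table is None:
        table = ResidueTemplateTable()
    if not sequence:
        raise ValueError("empty sequence")
    total = table[n_cap] + table[c_cap]
    for letter in sequence:
        three = ONE_TO_THREE.get(letter.upper())
        if three is None:
            raise KeyError(f"unknown residue code {letter!r}")
        total += table[three]
    return total


def plan_snapshots(n_traj: int, traj_length: float, save_interval: float) -> int:
    """Number of frames produced by ``n_traj`` runs saved every ``save_interval``.

    ``traj_length`` must be an integer multiple of ``save_interval`` (same
    time unit for both); no silent rounding is performed.
    """
    if n_traj <= 0 or traj_length <= 0 or save_interval <= 0:
        raise ValueError("all inputs must be positive")
    ratio = traj_length / save_interval
    n_per_traj = round(ratio)
    if abs(ratio - n_per_traj) > 1e-9 * max(1.0, abs(ratio)):
        raise ValueError(
            f"trajectory length {traj_length} is not an integer multiple of "
            f"save interval {save_interval}"
        )
    return int(n_traj) * int(n_per_traj)


# ---------------------------------------------------------------------------
# Structure model
# ---------------------------------------------------------------------------


@dataclass
class StructureModel:
    """A molecular topology with one set of coordinates.

    Atom attributes are parallel arrays of length ``n_atoms``; ``chain_roles``
    maps each chain id to ``"receptor"`` or ``"ligand"``.  Coordinates are Å.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    chain_roles: dict[str, str] = field(default_factory=dict)
    masses: np.ndarray | None = None
    radii: np.ndarray | None = None
    box: np.ndarray | None = None  # orthorhombic box lengths, optional

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be (n_atoms, ndim)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.atom_names)
        for name in ("elements", "res_names", "res_ids", "chain_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if self.coords.shape[0] != n:
            raise ValueError("coords length mismatch")
        for cid in np.unique(self.chain_ids):
            rid = self.res_ids[self.chain_ids == cid]
            if np.any(np.diff(np.unique(rid, return_index=True)[1]) < 0):
                raise ValueError(f"residue ids not grouped within chain {cid}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def ndim(self) -> int:
        return self.coords.shape[1]

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_ids == chain_id

    def role_mask(self, role: str) -> np.ndarray:
        chains = [c for c, r in self.chain_roles.items() if r == role]
        if not chains:
            raise ValueError(f"no chain with role {role!r}")
        return np.isin(self.chain_ids, chains)

    def heavy_mask(self) -> np.ndarray:
        return np.asarray([e.upper() != "H" for e in self.elements])

    def atom_masses(self) -> np.ndarray:
        if self.masses is not None:
            return np.asarray(self.masses, dtype=float)
        return np.ones(self.n_atoms)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        out = StructureModel(
            atom_names=self.atom_names, elements=self.elements,
            res_names=self.res_names, res_ids=self.res_ids,
            chain_ids=self.chain_ids, coords=np.asarray(coords, dtype=float),
            chain_roles=dict(self.chain_roles), masses=self.masses,
            radii=self.radii, box=self.box,
        )
        return out

    def coords3d(self) -> np.ndarray:
        """Coordinates padded with zeros to three dimensions."""
        return pad3d(self.coords)

    def select(self, chain_id: str | None = None, res_id: int | None = None,
               atom_name: str | None = None) -> np.ndarray:
        """Indices of atoms matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        if res_id is not None:
            mask &= self.res_ids == res_id
        if atom_name is not None:
            mask &= self.atom_names == atom_name
        return np.nonzero(mask)[0]


def pad3d(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-1] == 3:
        return coords
    pad = [(0, 0)] * (coords.ndim - 1) + [(0, 3 - coords.shape[-1])]
    return np.pad(coords, pad)


# ---------------------------------------------------------------------------
# Snapshots and ensembles
# ---------------------------------------------------------------------------


@dataclass
class Snapshot:
    """One frame: coordinates on a parent topology plus its potential energy."""

    topology: StructureModel
    coords: np.ndarray
    energy: float
    traj_id: int = 0
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.energy):
            raise ValueError("snapshot energy must be finite")
        if self.coords.shape[0] != self.topology.n_atoms:
            raise ValueError("coordinate / topology atom count mismatch")

    def as_structure(self) -> StructureModel:
        return self.topology.with_coords(self.coords)


class Ensemble:
    """An ordered set of snapshots sharing one topology.

    Frames are stored densely: ``coords`` has shape ``(n_frames, n_atoms,
    ndim)`` and ``energies`` shape ``(n_frames,)``.  ``metadata`` records
    sampling provenance (sampling temperature ``t_mc``, bias id, save
    interval, seeds).
    """

    def __init__(
        self,
        topology: StructureModel,
        coords: np.ndarray,
        energies: np.ndarray,
        traj_ids: np.ndarray | None = None,
        frame_indices: np.ndarray | None = None,
        metadata: dict | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        energies = np.asarray(energies, dtype=float)
        if coords.ndim != 3:
            raise ValueError("coords must be (n_frames, n_atoms, ndim)")
        if len(coords) == 0:
            raise ValueError("ensemble must be non-empty")
        if coords.shape[1] != topology.n_atoms:
            raise ValueError("topology atom count mismatch")
        if len(energies) != len(coords):
            raise ValueError("one energy per frame required")
        if not np.all(np.isfinite(energies)):
            raise ValueError("energies must be finite")
        self.topology = topology
        self.coords = coords
        self.energies = energies
        self.traj_ids = (np.zeros(len(coords), dtype=int)
                         if traj_ids is None else np.asarray(traj_ids, dtype=int))
        self.frame_indices = (np.arange(len(coords))
                              if frame_indices is None
                              else np.asarray(frame_indices, dtype=int))
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.coords)

    def __getitem__(self, i: int) -> Snapshot:
        return Snapshot(self.topology, self.coords[i], float(self.energies[i]),
                        int(self.traj_ids[i]), int(self.frame_indices[i]))

    def __iter__(self) -> Iterator[Snapshot]:
        for i in range(len(self)):
            yield self[i]

    def subset(self, idx: np.ndarray) -> "Ensemble":
        idx = np.asarray(idx)
        return Ensemble(self.topology, self.coords[idx], self.energies[idx],
                        self.traj_ids[idx], self.frame_indices[idx],
                        dict(self.metadata))

    # -- persistence --------------------------------------------------------

    def to_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("coords", data=self.coords)
            f.create_dataset("energies", data=self.energies)
            f.create_dataset("traj_ids", data=self.traj_ids)
            f.create_dataset("frame_indices", data=self.frame_indices)
            f.attrs["metadata"] = json.dumps(self.metadata)
            top = f.create_group("topology")
            top.attrs["json"] = json.dumps(_topology_to_dict(self.topology))

    @classmethod
    def from_hdf5(cls, path: str) -> "Ensemble":
        import h5py

        with h5py.File(path, "r") as f:
            topology = _topology_from_dict(json.loads(f["topology"].attrs["json"]))
            return cls(topology, f["coords"][...], f["energies"][...],
                       f["traj_ids"][...], f["frame_indices"][...],
                       json.loads(f.attrs["metadata"]))

    def to_json(self) -> str:
        """Plain-text exchange form (fixtures and small ensembles only)."""
        payload = {
            "topology": _topology_to_dict(self.topology),
            "coords": self.coords.tolist(),
            "energies": self.energies.tolist(),
            "traj_ids": self.traj_ids.tolist(),
            "frame_indices": self.frame_indices.tolist(),
            "metadata": self.metadata,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "Ensemble":
        d = json.loads(text)
        return cls(_topology_from_dict(d["topology"]), np.asarray(d["coords"]),
                   np.asarray(d["energies"]), np.asarray(d["traj_ids"]),
                   np.asarray(d["frame_indices"]), d["metadata"])


def _topology_to_dict(t: StructureModel) -> dict:
    return {
        "atom_names": list(map(str, t.atom_names)),
        "elements": list(map(str, t.elements)),
        "res_names": list(map(str, t.res_names)),
        "res_ids": [int(r) for r in t.res_ids],
        "chain_ids": list(map(str, t.chain_ids)),
        "coords": np.asarray(t.coords).tolist(),
        "chain_roles": dict(t.chain_roles),
        "masses": None if t.masses is None else np.asarray(t.masses).tolist(),
    }


def _topology_from_dict(d: dict) -> StructureModel:
    return StructureModel(
        atom_names=np.asarray(d["atom_names"], dtype=object),
        elements=np.asarray(d["elements"], dtype=object),
        res_names=np.asarray(d["res_names"], dtype=object),
        res_ids=np.asarray(d["res_ids"], dtype=int),
        chain_ids=np.asarray(d["chain_ids"], dtype=object),
        coords=np.asarray(d["coords"], dtype=float),
        chain_roles=d.get("chain_roles", {}),
        masses=None if d.get("masses") is None else np.asarray(d["masses"]),
    )


# ---------------------------------------------------------------------------
# PDB I/O (narrow dialect: ATOM/HETATM/TER/END, no insertion codes)
# ---------------------------------------------------------------------------


def read_structure(pdb_text: str, chain_roles: Mapping[str, str] | None = None) -> StructureModel:
    """Parse ATOM/HETATM records of a PDB file into a :class:`StructureModel`.

    Alternate locations other than blank/'A' are dropped; insertion codes are
    rejected.  Malformed coordinate fields raise :class:`PDBParseError`
    naming the offending line.
    """
    names, elements, res_names, res_ids, chain_ids, xyz = [], [], [], [], [], []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated {rec} record")
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        icode = line[26]
        if icode != " ":
            raise PDBParseError(f"line {lineno}: insertion codes are not supported")
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            res_id = int(line[22:26])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed numeric field ({exc})") from None
        name = line[12:16].strip()
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _element_from_name(name)
        names.append(name)
        elements.append(element)
        res_names.append(line[17:20].strip())
        res_ids.append(res_id)
        chain_ids.append(line[21] if line[21] != " " else "A")
        xyz.append((x, y, z))
    if not names:
        raise PDBParseError("no atoms: input contains no ATOM/HETATM records")
    return StructureModel(
        atom_names=np.asarray(names, dtype=object),
        elements=np.asarray(elements, dtype=object),
        res_names=np.asarray(res_names, dtype=object),
        res_ids=np.asarray(res_ids, dtype=int),
        chain_ids=np.asarray(chain_ids, dtype=object),
        coords=np.asarray(xyz, dtype=float),
        chain_roles=dict(chain_roles or {}),
    )


def _element_from_name(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "X"


def write_structure(model: StructureModel, multi: Sequence[np.ndarray] | None = None) -> str:
    """Serialize a structure (or several coordinate sets as MODELs) to PDB text."""
    frames = [model.coords] if multi is None else list(multi)
    out: list[str] = []
    use_models = len(frames) > 1
    coords_list = [pad3d(c) for c in frames]
    for m, coords in enumerate(coords_list, start=1):
        if use_models:
            out.append(f"MODEL     {m:4d}")
        serial = 1
        prev_chain = None
        for i in range(model.n_atoms):
            chain = str(model.chain_ids[i])
            if prev_chain is not None and chain != prev_chain:
                out.append("TER")
            prev_chain = chain
            name = str(model.atom_names[i])
            pdb_name = f" {name:<3s}" if len(name) < 4 else name[:4]
            x, y, z = coords[i]
            out.append(
                f"ATOM  {serial:5d} {pdb_name}{'':1s}{str(model.res_names[i]):>3s} "
                f"{chain:1s}{int(model.res_ids[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{str(model.elements[i]):>2s}"
            )
            serial += 1
        out.append("TER")
        if use_models:
            out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"
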