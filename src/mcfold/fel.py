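"""Distance-array features, PCA and reweighted free-energy landscapes.

Features are Euclidean distances over named atom-pair groups (intermolecular
receptor-anchor × ligand pairs, intramolecular pairs with a sequence-exclusion
window).  PCA is computed on the unweighted multicanonical ensemble;
reweighting enters only through the per-bin probability on the landscape,
PMF_i = −RT ln P_i with the minimum shifted to zero and a display cutoff
(default 5 kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import R_KCAL
from .core import Ensemble, StructureModel
from .reweight import WeightVector


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------


@dataclass
class SelectionSpec:
    """Named atom-pair groups defining the distance array.

    ``pairs`` is an (n_pairs, 2) integer array of atom indices; ``labels``
    names each pair.  Use :meth:`build` to assemble the paper-style groups:
    all receptor-anchor × ligand intermolecular pairs plus intramolecular
    ligand pairs excluding residues within ±``exclusion`` in sequence.
    """

    pairs: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be (n, 2)")
        if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise ValueError("self-pairs are not allowed")
        if not self.labels:
            self.labels = [f"{i}-{j}" for i, j in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def build(cls, topology: StructureModel,
              receptor_anchors: np.ndarray | None = None,
              ligand_atoms: np.ndarray | None = None,
              intra_ligand: bool = True,
              exclusion: int = 3,
              receptor_pairs: np.ndarray | None = None) -> "SelectionSpec":
        """Assemble intermolecular + intramolecular pair groups from roles."""
        if receptor_anchors is None:
            receptor_anchors = np.nonzero(topology.role_mask("receptor"))[0]
        if ligand_atoms is None:
            ligand_atoms = np.nonzero(topology.role_mask("ligand"))[0]
        pairs, labels = [], []
        for a in receptor_anchors:
            for b in ligand_atoms:
                pairs.append((a, b))
                labels.append(f"inter:{a}-{b}")
        if intra_ligand:
            res = topology.res_ids
            for ii, a in enumerate(ligand_atoms):
                for b in ligand_atoms[ii + 1:]:
                    if abs(int(res[a]) - int(res[b])) <= exclusion:
                        continue
                    pairs.append((a, b))
                    labels.append(f"intra:{a}-{b}")
        if receptor_pairs is not None:
            for a, b in np.asarray(receptor_pairs):
                pairs.append((int(a), int(b)))
                labels.append(f"receptor:{a}-{b}")
        if not pairs:
            raise ValueError("selection produced no pairs")
        return cls(np.asarray(pairs), labels)


def intra_chain_pairs(topology: StructureModel, chain_atoms: np.ndarray,
                      exclusion: int) -> np.ndarray:
    """All within-chain pairs with |Δresidue| > exclusion (brute enumeration)."""
    res = topology.res_ids
    out = []
    for ii, a in enumerate(chain_atoms):
        for b in chain_atoms[ii + 1:]:
            if abs(int(res[a]) - int(res[b])) > exclusion:
                out.append((int(a), int(b)))
    return np.asarray(out, dtype=int).reshape(-1, 2)


@dataclass
class FeatureMatrix:
    """n_snapshots × n_pairs distance matrix (Å) with pair labels."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("distances must be positive and finite")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label / column count mismatch")


def build_distance_features(ensemble: Ensemble, spec: SelectionSpec) -> FeatureMatrix:
    """Per-frame Euclidean distances for every pair in ``spec`` order.

    When the topology declares an orthorhombic box, the minimum-image
    convention is applied per axis.
    """
    n_atoms = ensemble.topology.n_atoms
    bad = spec.pairs[(spec.pairs < 0).any(axis=1) | (spec.pairs >= n_atoms).any(axis=1)]
    if len(bad):
        raise ValueError(f"selection atoms missing from topology: {bad.tolist()}")
    i, j = spec.pairs.T
    d = ensemble.coords[:, i, :] - ensemble.coords[:, j, :]
    box = ensemble.topology.box
    if box is not None:
        box = np.asarray(box, dtype=float)[: d.shape[-1]]
        d = d - box * np.round(d / box)
    return FeatureMatrix(np.sqrt(np.sum(d * d, axis=-1)), list(spec.labels))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class Projection:
    """PCA components, per-component variance contributions (%), and scores."""

    components: np.ndarray        # (n_components, n_features)
    contributions: np.ndarray     # percent, non-increasing
    scores: np.ndarray            # (n_snapshots, n_components)
    mean: np.ndarray | None = None

    def __post_init__(self):
        self.contributions = np.asarray(self.contributions, dtype=float)
        if np.any(np.diff(self.contributions) > 1e-9):
            raise ValueError("contributions must be non-increasing")
        if self.contributions.sum() > 100.0 + 1e-6:
            raise ValueError("contributions must sum to at most 100%")

    @classmethod
    def from_scores(cls, scores: np.ndarray) -> "Projection":
        """Wrap raw low-dimensional coordinates as an identity projection.

        Column order is preserved; the stored contributions are the sorted
        variance shares and do not map onto columns for this constructor.
        """
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        var = scores.var(axis=0)
        total = var.sum()
        contrib = (100.0 * np.sort(var)[::-1] / total if total > 0
                   else np.zeros(scores.shape[1]))
        return cls(np.eye(scores.shape[1]), contrib, scores)

    def n_components_for(self, threshold_pct: float = 90.0) -> int:
        """Smallest m whose cumulative variance contribution exceeds threshold."""
        cum = np.cumsum(self.contributions)
        idx = np.searchsorted(cum, threshold_pct, side="left")
        return int(min(idx + 1, len(cum)))


def pca_fit_project(features: FeatureMatrix,
                    weights: WeightVector | None = None) -> Projection:
    """PCA of the (optionally weighted) covariance of centered distance columns.

    Deterministic sign convention: within each component the loading of
    largest magnitude is made positive, so scores and landscapes are stable
    across reruns.
    """
    x = features.values
    if x.shape[0] < 2:
        raise ValueError("need at least two snapshots")
    if weights is None:
        mean = x.mean(axis=0)
        xc = x - mean
        cov = xc.T @ xc / (x.shape[0] - 1)
    else:
        w = weights.weights
        mean = np.sum(x * w[:, None], axis=0)
        xc = x - mean
        cov = (xc * w[:, None]).T @ xc
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise ValueError("rank-0 feature matrix: no variance to decompose")
    comps = evecs.T
    for c in comps:  # sign convention
        k = np.argmax(np.abs(c))
        if c[k] < 0:
            c *= -1.0
    scores = (x - mean) @ comps.T
    return Projection(comps, 100.0 * evals / total, scores, mean)


# ---------------------------------------------------------------------------
# Free-energy landscape
# ---------------------------------------------------------------------------


@dataclass
class FELGrid:
    """2-D free-energy landscape: PMF per (PC1, PC2) bin in kcal/mol."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    pmf: np.ndarray               # (nx, ny); NaN where empty
    temperature: float
    cutoff: float = 5.0

    @property
    def above_cutoff(self) -> np.ndarray:
        """Mask of bins that are empty or above the display cutoff."""
        return ~np.isfinite(self.pmf) | (self.pmf > self.cutoff)

    def to_table(self) -> "object":
        import pandas as pd

        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame({
            "pc1": xx.ravel(), "pc2": yy.ravel(), "pmf": self.pmf.ravel(),
            "flagged": self.above_cutoff.ravel(),
        })


def default_grid(scores: np.ndarray, n_bins: int = 100,
                 pad_fraction: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """100×100 bins spanning the score range padded by 2% on each side."""
    lo = scores[:, :2].min(axis=0)
    hi = scores[:, :2].max(axis=0)
    pad = (hi - lo) * pad_fraction
    return (np.linspace(lo[0] - pad[0], hi[0] + pad[0], n_bins + 1),
            np.linspace(lo[1] - pad[1], hi[1] + pad[1], n_bins + 1))


def compute_fel(projection: Projection, weights: WeightVector,
                grid: tuple[np.ndarray, np.ndarray] | None = None,
                T: float = 300.0, cutoff: float = 5.0) -> FELGrid:
    """Reweighted 2-D free-energy landscape over (PC1, PC2).

    P_i is the summed snapshot weight in bin i; PMF_i = −R T ln P_i, shifted
    so the occupied minimum is zero.  Empty bins are NaN; bins above
    ``cutoff`` are flagged.
    """
    scores = projection.scores
    if grid is None:
        grid = default_grid(scores)
    x_edges, y_edges = grid
    x, y = scores[:, 0], scores[:, 1]
    if (x.min() < x_edges[0] or x.max() > x_edges[-1]
            or y.min() < y_edges[0] or y.max() > y_edges[-1]):
        raise ValueError(
            "grid does not cover the score range; suggested bounds "
            f"x [{x.min():.3g}, {x.max():.3g}], y [{y.min():.3g}, {y.max():.3g}]"
        )
    mass, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges),
                                weights=weights.weights)
    with np.errstate(divide="ignore"):
        pmf = -R_KCAL * T * np.log(mass)
    pmf[mass <= 0] = np.nan
    pmf -= np.nanmin(pmf)
    return FELGrid(x_edges, y_edges, pmf, T, cutoff)


def fel_value_at(fel: FELGrid, pc1: float, pc2: float) -> float:
    """Landscape PMF of the bin containing (pc1, pc2); NaN outside/empty."""
    i = np.searchsorted(fel.x_edges, pc1, side="right") - 1
    j = np.searchsorted(fel.y_edges, pc2, side="right") - 1
    if not (0 <= i < fel.pmf.shape[0] and 0 <= j < fel.pmf.shape[1]):
        return float("nan")
    return float(fel.pmf[i, j])
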