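"""Cluster the projected ensemble, rank by cluster free energy, pick and
merge representatives.

Clusters come from K-means on the leading PC scores (enough components to
pass a variance-contribution threshold, default 90%).  Each cluster's free
energy is CFE = −RT ln P, with P the summed canonical weight of its members;
clusters are ranked ascending.  One representative snapshot per cluster (the
member nearest the centroid) is kept, and representatives that preserve more
than a threshold fraction of a retained representative's intermolecular
contacts (R-value > 0.7) are merged into it, masses added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .constants import R_KCAL
from .core import Ensemble
from .fel import Projection
from .reweight import WeightVector
from . import rvalue as rv


@dataclass
class ClusterSet:
    """Per-snapshot K-means labels with centroids in the clustered PC subspace."""

    labels: np.ndarray
    centroids: np.ndarray
    dims: int
    seed: int

    def __post_init__(self):
        if self.labels.min() < 0:
            raise ValueError("every snapshot must be labeled")

    @property
    def k(self) -> int:
        return len(self.centroids)


def cluster_pc(projection: Projection, k_prime: int, dims: int | None = None,
               seed: int = 0, n_init: int = 10,
               variance_threshold: float = 90.0) -> ClusterSet:
    """K-means on the first ``dims`` PC score columns (k-means++ init).

    When ``dims`` is omitted it is the smallest component count whose
    cumulative variance contribution exceeds ``variance_threshold`` percent.
    Deterministic given ``seed``; best of ``n_init`` restarts kept.
    """
    scores = projection.scores
    n = scores.shape[0]
    if k_prime > n:
        raise ValueError(f"k'={k_prime} exceeds the {n} snapshots")
    if dims is None:
        dims = projection.n_components_for(variance_threshold)
    if dims > scores.shape[1]:
        raise ValueError("dims exceeds available components")
    km = KMeans(n_clusters=k_prime, init="k-means++", n_init=n_init,
                random_state=seed)
    labels = km.fit_predict(scores[:, :dims])
    return ClusterSet(labels, km.cluster_centers_, dims, seed)


def default_k_prime(n_snapshots: int, k_max: int = 1000) -> int:
    """Desk-scale default k' = min(1000, n/10); the printed k'=1000 assumes
    millions of snapshots."""
    return max(1, min(k_max, n_snapshots // 10))


def cluster_free_energy(clusters: ClusterSet, weights: WeightVector,
                        T: float = 300.0) -> pd.DataFrame:
    """Per-cluster probability mass and CFE = −RT ln P, minimum shifted to 0.

    Empty clusters are excluded and flagged.  Rows are ranked ascending by
    CFE.
    """
    k = clusters.k
    mass = np.bincount(clusters.labels, weights=weights.weights, minlength=k)
    occupied = np.bincount(clusters.labels, minlength=k) > 0
    with np.errstate(divide="ignore"):
        cfe = -R_KCAL * T * np.log(np.where(mass > 0, mass, np.nan))
    table = pd.DataFrame({
        "cluster": np.arange(k),
        "mass": mass,
        "cfe": cfe,
        "empty": ~occupied,
    })
    table = table[~table["empty"]].copy()
    table["cfe"] -= table["cfe"].min()
    return table.sort_values("cfe", kind="stable").reset_index(drop=True)


def pick_representatives(clusters: ClusterSet, projection: Projection) -> np.ndarray:
    """Per cluster, the snapshot nearest its centroid in the clustered subspace.

    Ties break to the lowest snapshot index.  Returns an array indexed by
    cluster id (−1 for empty clusters).
    """
    scores = projection.scores[:, :clusters.dims]
    reps = np.full(clusters.k, -1, dtype=int)
    for c in range(clusters.k):
        members = np.nonzero(clusters.labels == c)[0]
        if len(members) == 0:
            continue
        d2 = np.sum((scores[members] - clusters.centroids[c]) ** 2, axis=1)
        reps[c] = members[np.argmin(d2)]  # argmin takes the first minimum
    return reps


@dataclass
class RepresentativeSet:
    """Ranked, merged representatives with CFE, mass and merge lineage."""

    table: pd.DataFrame          # rank, snapshot, mass, cfe, stable
    lineage: dict = field(default_factory=dict)  # retained cluster -> merged clusters
    temperature: float = 300.0
    cfe_cutoff: float = 2.5

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snapshots(self) -> np.ndarray:
        return self.table["snapshot"].to_numpy()


def merge_by_rvalue(rep_indices: np.ndarray, cfe_table: pd.DataFrame,
                    ensemble: Ensemble, threshold: float = 0.7,
                    cfe_cutoff: float = 2.5, T: float = 300.0,
                    scope: str = "inter",
                    cutoff: float = rv.CONTACT_CUTOFF) -> RepresentativeSet:
    """Greedy rank-order merge of near-duplicate representatives.

    Walking the CFE-ranked clusters from most stable down, a candidate whose
    R-value against any already-retained representative exceeds ``threshold``
    is merged into the first such match (probability masses added).  CFEs are
    recomputed from merged masses and re-shifted; representatives with CFE
    below ``cfe_cutoff`` form the stable set.  Candidates without contacts in
    scope never merge (R undefined ⇒ treated as dissimilar).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    retained: list[dict] = []
    lineage: dict[int, list[int]] = {}
    for row in cfe_table.itertuples(index=False):
        cluster = int(row.cluster)
        snap_idx = int(rep_indices[cluster])
        snap = ensemble[snap_idx]
        merged = False
        for kept in retained:
            try:
                r = rv.r_value(snap, kept["snapshot_obj"], scope, cutoff)
            except ValueError:
                continue  # retained rep has no contacts in scope
            if r > threshold:
                kept["mass"] += float(row.mass)
                lineage[kept["cluster"]].append(cluster)
                merged = True
                break
        if not merged:
            retained.append({"cluster": cluster, "snapshot": snap_idx,
                             "snapshot_obj": snap, "mass": float(row.mass)})
            lineage[cluster] = [cluster]
    mass = np.asarray([k["mass"] for k in retained])
    cfe = -R_KCAL * T * np.log(mass / mass.sum())
    cfe -= cfe.min()
    order = np.argsort(cfe, kind="stable")
    table = pd.DataFrame({
        "rank": np.arange(1, len(retained) + 1),
        "cluster": [retained[i]["cluster"] for i in order],
        "snapshot": [retained[i]["snapshot"] for i in order],
        "mass": mass[order],
        "cfe": cfe[order],
    })
    table["stable"] = table["cfe"] < cfe_cutoff
    return RepresentativeSet(table, lineage, T, cfe_cutoff)
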