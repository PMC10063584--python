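"""Canonical reweighting of multicanonical samples.

A multicanonical run sampled with modified energy E_mc at temperature T_mc is
converted to a canonical ensemble at arbitrary temperature T by per-snapshot
weights  w_j ∝ exp[ E_mc(E_j) / (R T_mc)  −  E_j / (R T) ],  normalized with a
log-sum-exp.  Weights are per snapshot (not per energy bin), so downstream
landscape and cluster probabilities are simple weight sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import R_KCAL
from .core import Ensemble
from .engine import BiasFunction


@dataclass
class WeightVector:
    """Normalized per-snapshot canonical weights at temperature ``T``."""

    weights: np.ndarray
    temperature: float
    normalized: bool = True

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite and non-negative")
        if self.normalized and len(self.weights):
            s = self.weights.sum()
            if not np.isclose(s, 1.0, atol=1e-8):
                raise ValueError("normalized weights must sum to 1")

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def ess(self) -> float:
        """Kish effective sample size 1 / Σ w²."""
        return float(1.0 / np.sum(self.weights**2))

    @classmethod
    def uniform(cls, n: int, temperature: float = 300.0) -> "WeightVector":
        return cls(np.full(n, 1.0 / n), temperature)


@dataclass
class Distribution:
    """A reweighted, binned probability distribution of one observable."""

    edges: np.ndarray
    masses: np.ndarray
    temperature: float
    label: str = ""
    overflow: float = 0.0

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses < -1e-12):
            raise ValueError("bin masses must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def entropy(self) -> float:
        p = self.masses[self.masses > 0]
        return float(-np.sum(p * np.log(p)))


def canonical_weights(ensemble: Ensemble, bias: BiasFunction, T: float,
                      ess_warn: float = 100.0) -> WeightVector:
    """Per-snapshot canonical weights at temperature ``T``.

    ``bias`` must be the modified-energy mapping the ensemble was sampled
    under (pass an identity bias for a canonical run).  Warns when the
    effective sample size drops below ``ess_warn``.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    e = ensemble.energies
    log_w = np.asarray(bias(e)) / (R_KCAL * bias.t_mc) - e / (R_KCAL * T)
    log_w -= logsumexp(log_w)
    w = np.exp(log_w)
    wv = WeightVector(w / w.sum(), T)
    if wv.ess < ess_warn:
        warnings.warn(
            f"effective sample size {wv.ess:.1f} below {ess_warn:g} at T={T:g} K"
        )
    return wv


def reweighted_histogram(values: np.ndarray, weights: WeightVector,
                         edges: np.ndarray, label: str = "") -> Distribution:
    """Weighted histogram of a per-snapshot observable (right-open bins).

    Values outside the bin range are excluded from the mass and accumulated
    in the distribution's ``overflow`` counter.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if len(values) != len(weights):
        raise ValueError("one value per snapshot required")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    inside = (values >= edges[0]) & (values < edges[-1])
    overflow = float(np.sum(weights.weights[~inside]))
    if overflow > 0:
        warnings.warn(f"{overflow:.3g} probability mass outside histogram range")
    masses, _ = np.histogram(values[inside], bins=edges,
                             weights=weights.weights[inside])
    total = masses.sum()
    if total > 0:
        masses = masses / total
    return Distribution(edges, masses, weights.temperature, label, overflow)


def weighted_mean(values: np.ndarray, weights: WeightVector) -> float:
    return float(np.sum(np.asarray(values) * weights.weights))


def weighted_var(values: np.ndarray, weights: WeightVector) -> float:
    m = weighted_mean(values, weights)
    return float(np.sum(weights.weights * (np.asarray(values) - m) ** 2))
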