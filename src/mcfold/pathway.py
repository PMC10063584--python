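"""Binding/unbinding pathway extraction along the dissociation coordinate λ.

The λ range is split into contiguous windows; starting from a bound reference
structure in the first window, one snapshot per window is picked from the
multicanonical ensemble, maximizing contact similarity (R-value) to the pick
of the previous window.  Consecutive-pick similarities flag putative barriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Ensemble, Snapshot
from .observables import lambda_coord_frames
from . import rvalue as rv


@dataclass
class WindowSpec:
    """Contiguous, non-overlapping λ windows covering [lambda_min, lambda_max]."""

    lambda_min: float
    lambda_max: float
    width: float
    edges: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")
        if self.lambda_max <= self.lambda_min:
            raise ValueError("empty λ range")
        n = int(np.ceil((self.lambda_max - self.lambda_min) / self.width - 1e-12))
        edges = self.lambda_min + self.width * np.arange(n + 1)
        edges[-1] = self.lambda_max  # last window truncated to the range end
        self.edges = edges

    @property
    def n_windows(self) -> int:
        return len(self.edges) - 1

    def window_of(self, lam: np.ndarray) -> np.ndarray:
        """Window index per λ (−1 outside the covered range)."""
        lam = np.asarray(lam, dtype=float)
        idx = np.searchsorted(self.edges, lam, side="right") - 1
        idx[lam == self.lambda_max] = self.n_windows - 1
        idx[(lam < self.lambda_min) | (lam > self.lambda_max)] = -1
        return idx


def make_windows(lambda_min: float, lambda_max: float, width: float = 2.5) -> WindowSpec:
    """⌈(max−min)/width⌉ contiguous windows; the default width of 2.5 Å over
    the restrained λ range −2.5–40.0 Å gives 17 windows."""
    return WindowSpec(lambda_min, lambda_max, width)


@dataclass
class Pathway:
    """Ordered per-window picks with per-step similarity to the previous pick."""

    picks: list[Snapshot]
    pick_indices: np.ndarray
    lambdas: np.ndarray
    step_r: np.ndarray        # NaN for the first window and undefined steps
    step_rmsd: np.ndarray
    windows: WindowSpec
    start_index: int

    def __len__(self) -> int:
        return len(self.picks)


def extract_pathway(ensemble: Ensemble, start: int, windows: WindowSpec,
                    axis: int = 0, scope: str = "inter",
                    cutoff: float = rv.CONTACT_CUTOFF,
                    lambdas: np.ndarray | None = None) -> Pathway:
    """Pick a connected chain of snapshots, one per λ window.

    ``start`` indexes the bound reference snapshot, which must lie in the
    first window.  Iterating windows outward, the pick maximizes the R-value
    against the previous pick among that window's snapshots; ties break by
    lower ligand RMSD (receptor frame), then by lower frame index.  When the
    previous pick has no contacts in scope (unbound region) the R criterion
    is undefined and picks fall through to the RMSD/tie rules.
    """
    if lambdas is None:
        lambdas = lambda_coord_frames(ensemble, axis=axis)
    widx = windows.window_of(lambdas)
    if widx[start] != 0:
        raise ValueError(
            f"start snapshot λ={lambdas[start]:.3g} is not in the first window "
            f"[{windows.edges[0]:.3g}, {windows.edges[1]:.3g})"
        )
    picks = [start]
    step_r = [np.nan]
    step_rmsd = [np.nan]
    prev = ensemble[start]
    for w in range(1, windows.n_windows):
        members = np.nonzero(widx == w)[0]
        if len(members) == 0:
            lo, hi = windows.edges[w], windows.edges[w + 1]
            raise ValueError(
                f"no snapshots in window {w} ([{lo:.3g}, {hi:.3g}) Å); "
                "consider wider windows"
            )
        try:
            ref_contacts = rv.contact_set(prev, scope, cutoff)
        except ValueError:
            ref_contacts = None
        best = None
        for idx in members:
            snap = ensemble[idx]
            if ref_contacts is not None and len(ref_contacts) > 0:
                own = rv.contact_set(snap, scope, cutoff)
                r = len(ref_contacts.pairs & own.pairs) / len(ref_contacts.pairs)
            else:
                r = np.nan
            d = rv.ligand_rmsd_receptor_frame(snap, prev)
            key = (-(r if np.isfinite(r) else -1.0), d, idx)
            if best is None or key < best[0]:
                best = (key, idx, r, d)
        _, idx, r, d = best
        picks.append(int(idx))
        step_r.append(r)
        step_rmsd.append(d)
        prev = ensemble[int(idx)]
    return Pathway(
        picks=[ensemble[i] for i in picks],
        pick_indices=np.asarray(picks),
        lambdas=lambdas[np.asarray(picks)],
        step_r=np.asarray(step_r),
        step_rmsd=np.asarray(step_rmsd),
        windows=windows,
        start_index=start,
    )


def window_similarity(path: Pathway, flag_threshold: float = 0.6) -> pd.DataFrame:
    """Neighbor-similarity table: per consecutive pair, R (later pick against
    the earlier as reference) and ligand RMSD in the receptor frame.

    Steps with R below ``flag_threshold`` are marked as putative barriers.
    """
    if len(path) < 2:
        raise ValueError("pathway needs at least two picks")
    rows = []
    for w in range(1, len(path)):
        r, d = path.step_r[w], path.step_rmsd[w]
        rows.append({
            "window": w,
            "lambda": path.lambdas[w],
            "r_value": r,
            "rmsd": d,
            "barrier_flag": bool(np.isnan(r) or r < flag_threshold),
        })
    return pd.DataFrame(rows)
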