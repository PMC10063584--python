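"""End-to-end orchestration: sample → reweight → FEL → pick → refine → path.

A :class:`PipelineConfig` (YAML-loadable) fixes the system, the
multicanonical protocol and every analysis threshold; ``run_docking_analysis``
executes the stages in order and returns a :class:`ReportBundle` with the
representative table, stability table, landscape, pathway table and
observable profiles, plus provenance (config hash and seeds).  Identical
config and seeds give identical reports; the expensive sampling stage is
cached on disk keyed by the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Ensemble
from .engine import BiasFunction, McMDConfig, calibrate_bias, run_mcmd
from .fel import SelectionSpec, build_distance_features, compute_fel, fel_value_at, pca_fit_project
from .observables import lambda_coord_frames
from .pathway import extract_pathway, make_windows, window_similarity
from .refine import stability_table
from .represent import (cluster_free_energy, cluster_pc, default_k_prime,
                        merge_by_rvalue, pick_representatives)
from .reweight import canonical_weights
from . import synth

log = logging.getLogger("mcfold")


@dataclass
class PipelineConfig:
    """Every knob of the analysis, with the standard protocol defaults."""

    system: str = "cryptic"              # cryptic | doublewell | store:<path>
    system_params: dict = field(default_factory=dict)
    mcmd: dict = field(default_factory=dict)        # McMDConfig overrides
    production_sweeps: int = 20000
    n_walkers: int = 16
    seed: int = 0
    temperature: float = 300.0
    stability_temps: tuple = (300.0, 400.0)
    exclusion: int = 3
    variance_threshold: float = 90.0
    k_prime: int | None = None           # default min(1000, n/10)
    merge_threshold: float = 0.7
    cfe_cutoff: float = 2.5
    fel_cutoff: float = 5.0
    window_width: float = 2.5
    refine_sweeps: int = 1500
    refine_n_traj: int = 10
    max_refined: int = 3

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All stage outputs plus provenance."""

    representatives: pd.DataFrame
    stability: pd.DataFrame | None
    fel_table: pd.DataFrame
    pathway_table: pd.DataFrame | None
    diagnostics: dict
    provenance: dict

    def save(self, out_dir: str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.representatives.to_csv(out / "representatives.csv", index=False)
        if self.stability is not None:
            self.stability.to_csv(out / "stability.csv", index=False)
        self.fel_table.to_csv(out / "fel.csv", index=False)
        if self.pathway_table is not None:
            self.pathway_table.to_csv(out / "pathway.csv", index=False)
        with open(out / "report.json", "w") as f:
            json.dump({"diagnostics": self.diagnostics,
                       "provenance": self.provenance}, f, indent=2, default=str)


def _build_system(cfg: PipelineConfig):
    if cfg.system == "cryptic":
        return synth.make_cryptic_toy(**cfg.system_params)
    if cfg.system == "doublewell":
        return synth.make_double_well(**(cfg.system_params or {"barrier": 3.0}))
    if cfg.system.startswith("store:"):
        return Ensemble.from_hdf5(cfg.system.split(":", 1)[1]), None
    raise ValueError(f"unknown system {cfg.system!r}")


def _sampling_stage(cfg: PipelineConfig, system, cache_dir: Path | None):
    """Calibrate the bias and run production, with on-disk caching."""
    if cache_dir is not None:
        tag = cache_dir / f"production-{cfg.config_hash()}.h5"
        bias_tag = cache_dir / f"bias-{cfg.config_hash()}.json"
        if tag.exists() and bias_tag.exists():
            log.info("sampling stage: cache hit (%s)", tag.name)
            with open(bias_tag) as f:
                bd = json.load(f)
            bias = BiasFunction(np.asarray(bd["knots"]), np.asarray(bd["values"]),
                                bd["t_mc"], bd["bias_id"])
            return bias, Ensemble.from_hdf5(str(tag)), {"cached": True}
    mc = McMDConfig(base_seed=cfg.seed, n_parallel=cfg.n_walkers, **cfg.mcmd)
    bias, _, diag = calibrate_bias(system, mc)
    production = run_mcmd(system, bias, cfg.production_sweeps,
                          seed=cfg.seed + 1000, n_walkers=cfg.n_walkers,
                          save_interval=mc.save_interval)
    log.info("sampling stage: %d frames, flatness history %s",
             len(production), [h["flatness"] for h in diag["history"]])
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        production.to_hdf5(str(tag))
        with open(bias_tag, "w") as f:
            json.dump({"knots": bias.knots.tolist(),
                       "values": bias.values.tolist(),
                       "t_mc": bias.t_mc, "bias_id": bias.bias_id}, f)
    return bias, production, diag


def run_docking_analysis(config: PipelineConfig,
                         out_dir: str | None = None) -> ReportBundle:
    """Execute the full analysis; see the module docstring for the stages."""
    t0 = time.time()
    diagnostics: dict = {}
    system, oracle = _build_system(config)
    cache = Path(out_dir) / "cache" if out_dir else None

    bias, production, samp_diag = _sampling_stage(config, system, cache)
    diagnostics["sampling"] = {k: v for k, v in samp_diag.items() if k != "history"}
    diagnostics["n_frames"] = len(production)

    weights = canonical_weights(production, bias, config.temperature)
    diagnostics["ess"] = weights.ess

    spec = SelectionSpec.build(production.topology, exclusion=config.exclusion)
    features = build_distance_features(production, spec)
    projection = pca_fit_project(features)
    fel = compute_fel(projection, weights, T=config.temperature,
                      cutoff=config.fel_cutoff)

    k_prime = config.k_prime or default_k_prime(len(production))
    clusters = cluster_pc(projection, k_prime, seed=config.seed,
                          variance_threshold=config.variance_threshold)
    diagnostics["k_prime"] = k_prime
    diagnostics["pc_dims"] = clusters.dims
    cfe = cluster_free_energy(clusters, weights, config.temperature)
    rep_idx = pick_representatives(clusters, projection)
    reps = merge_by_rvalue(rep_idx, cfe, production,
                           threshold=config.merge_threshold,
                           cfe_cutoff=config.cfe_cutoff, T=config.temperature)
    lam = lambda_coord_frames(production)
    rep_table = reps.table.copy()
    rep_table["pc1"] = projection.scores[rep_table["snapshot"], 0]
    rep_table["pc2"] = projection.scores[rep_table["snapshot"], 1]
    rep_table["pca_fe"] = [fel_value_at(fel, r.pc1, r.pc2)
                           for r in rep_table.itertuples()]
    rep_table["lambda"] = lam[rep_table["snapshot"]]
    diagnostics["n_representatives"] = len(rep_table)
    diagnostics["n_stable"] = int(rep_table["stable"].sum())

    stability = None
    if oracle is not None and hasattr(system, "terms"):
        stable = rep_table[rep_table["stable"]].head(config.max_refined)
        snaps = [production[int(i)] for i in stable["snapshot"]]
        if snaps:
            stability = stability_table(
                snaps, system, temperatures=tuple(config.stability_temps),
                n_traj=config.refine_n_traj, n_sweeps=config.refine_sweeps,
                seed=config.seed + 7)

    pathway_table = None
    try:
        start = int(rep_table.iloc[0]["snapshot"])
        lam_lo = float(lam[start])
        windows = make_windows(lam_lo - 1e-9, float(lam.max()),
                               config.window_width)
        path = extract_pathway(production, start, windows, lambdas=lam)
        pathway_table = window_similarity(path)
    except ValueError as exc:
        diagnostics["pathway_error"] = str(exc)

    provenance = {"config_hash": config.config_hash(), "seed": config.seed,
                  "config": asdict(config), "runtime_s": round(time.time() - t0, 2)}
    bundle = ReportBundle(rep_table.drop(columns=[], errors="ignore"),
                          stability, fel.to_table(), pathway_table,
                          diagnostics, provenance)
    if out_dir:
        bundle.save(out_dir)
    return bundle
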