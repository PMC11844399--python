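"""Readers/writers for labeled matrices and traces, plus the pipeline runner.

Matrices travel as comma-separated text with a header row and index column
of region labels, full float precision, alongside an optional YAML sidecar
(``<stem>.meta.yaml``) carrying hemisphere tags, weight kind / metric name
and provenance parameters.  Spin traces round-trip through ``.npz``
bundles.  ``run_pipeline`` chains generate → metrics → Ising FC → compare
and writes a manifest with seeds and content hashes so identical configs
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .graph_core import Connectome, validate_connectome
from .ising import IsingConfig, SpinTrace, find_near_critical_coupling, simulate_fc
from .metrics import (
    PairwiseMatrix,
    commute_time,
    communicability_matrix,
    hitting_time,
    mfpt_commute_matrix,
    search_information_matrix,
)
from .structure_function import hemisphere_mask, spearman_compare
from .synthetic import ConnectomeRecipe, generate_connectome

logger = logging.getLogger(__name__)

METRIC_BUILDERS = {
    "commute": commute_time,
    "mfpt": mfpt_commute_matrix,
    "communicability": communicability_matrix,
    "search-info": search_information_matrix,
}


def _sidecar(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.yaml")


def matrix_hash(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()[:16]


def write_connectome(path, c: Connectome) -> None:
    """Connectome to CSV (labels as header/index) with a YAML sidecar."""
    path = Path(path)
    pd.DataFrame(c.weights, index=list(c.labels),
                 columns=list(c.labels)).to_csv(path, float_format="%.17g")
    meta = {"kind": "connectome", "labels": list(c.labels),
            "hemisphere": list(c.hemisphere), "weight_kind": c.weight_kind,
            "hash": matrix_hash(c.weights)}
    _sidecar(path).write_text(yaml.safe_dump(meta))


def write_pairwise(path, m: PairwiseMatrix, extra_meta: dict | None = None) -> None:
    """Metric matrix to CSV with a sidecar recording metric name and parameters."""
    path = Path(path)
    pd.DataFrame(m.values, index=list(m.labels),
                 columns=list(m.labels)).to_csv(path, float_format="%.17g")
    meta = {"kind": "pairwise", "metric_name": m.metric_name,
            "diagonal_policy": m.diagonal_policy, "hash": matrix_hash(m.values)}
    meta.update({k: v for k, v in m.meta.items()
                 if isinstance(v, (int, float, str, bool))})
    if extra_meta:
        meta.update(extra_meta)
    _sidecar(path).write_text(yaml.safe_dump(meta))


def _read_labeled_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"{path}: matrix is {df.shape[0]}×{df.shape[1]}, expected square "
            "(ragged rows or mismatched header)")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row labels do not match column labels")
    return df


def read_matrix(path, expected_kind: str = "connectome"):
    """Read a labeled matrix; validation depends on ``expected_kind``.

    ``connectome`` → full connectome validation (uses the sidecar's
    hemisphere/weight_kind when present); ``fc`` → entries must be
    correlations in [−1, 1]; ``pairwise`` → any symmetric metric matrix.
    """
    path = Path(path)
    df = _read_labeled_csv(path)
    values = df.to_numpy(dtype=float)
    labels = [str(x) for x in df.columns]
    meta = {}
    side = _sidecar(path)
    if side.exists():
        meta = yaml.safe_load(side.read_text()) or {}
    if expected_kind == "connectome":
        return validate_connectome(values, labels=labels,
                                   hemisphere=meta.get("hemisphere"),
                                   weight_kind=meta.get("weight_kind", "count"))
    if expected_kind == "fc":
        if np.abs(values).max() > 1.0 + 1e-9:
            bad = float(np.abs(values).max())
            raise ValueError(f"{path}: FC entry magnitude {bad} exceeds 1 "
                             "(not a correlation matrix)")
        return PairwiseMatrix(values=np.clip(values, -1, 1), metric_name="fc",
                              labels=tuple(labels), diagonal_policy="defined")
    if expected_kind == "pairwise":
        if np.abs(values - values.T).max() > 1e-8:
            raise ValueError(f"{path}: pairwise matrix is not symmetric")
        return PairwiseMatrix(values=(values + values.T) / 2.0,
                              metric_name=str(meta.get("metric_name", "unknown")),
                              labels=tuple(labels),
                              diagonal_policy=str(meta.get("diagonal_policy", "zero")))
    raise ValueError(f"unknown expected_kind {expected_kind!r}")


def write_trace(path, trace: SpinTrace) -> None:
    """Spin trace + config to a compressed array bundle (runtime artifact)."""
    cfg = dataclasses.asdict(trace.config)
    np.savez_compressed(
        path, spins=trace.spins,
        bold=trace.bold if trace.bold is not None else np.empty((0, 0)),
        accepted=trace.accepted, dt=trace.dt, burn_in=trace.burn_in,
        config_json=json.dumps(cfg), labels=np.array(trace.labels, dtype=object))


def read_trace(path) -> SpinTrace:
    with np.load(path, allow_pickle=True) as z:
        cfg = IsingConfig(**json.loads(str(z["config_json"])))
        bold = z["bold"]
        return SpinTrace(spins=z["spins"],
                         bold=None if bold.size == 0 else bold,
                         dt=float(z["dt"]), accepted=z["accepted"],
                         burn_in=int(z["burn_in"]), config=cfg,
                         labels=tuple(z["labels"].tolist()))


@dataclass
class RunConfig:
    """Configuration of the end-to-end synthetic pipeline.

    Either ``connectome_path`` points at an existing matrix, or a synthetic
    one is generated from the recipe fields.  Every stochastic stage has
    its own explicit seed.
    """

    outdir: str = "commutefc_run"
    connectome_path: str | None = None
    n_regions: int = 84
    intra_density: float = 0.35
    inter_density: float = 0.08
    weight_log_mean: float = 2.0
    weight_log_sd: float = 1.0
    homotopic_weight: float = 0.0
    generate_seed: int = 0
    metrics: tuple = ("commute",)
    coupling: float | None = None  # None → locate near-critical λ by sweep
    n_steps: int = 5000
    flip_fraction: float = 0.15
    proposal_mode: str = "block"
    ising_seed: int = 0
    sweep_seed: int = 0
    mask: str = "all_offdiag"
    modes_x: int = 0
    modes_y: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["metrics"] = list(self.metrics)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "metrics" in d:
            d["metrics"] = tuple(d["metrics"])
        return cls(**d)


def run_pipeline(cfg: RunConfig) -> dict:
    """Generate/load → metrics → Ising FC → compare; returns the manifest.

    All intermediates are written under ``cfg.outdir``; the manifest
    records seeds, parameters and content hashes so a rerun with the same
    config is byte-identical.
    """
    if cfg.connectome_path is not None and not Path(cfg.connectome_path).exists():
        raise FileNotFoundError(f"connectome_path {cfg.connectome_path} does not exist")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}}

    if cfg.connectome_path is not None:
        c = read_matrix(cfg.connectome_path, "connectome")
        manifest["stages"]["input"] = {"path": str(cfg.connectome_path),
                                       "hash": matrix_hash(c.weights)}
    else:
        recipe = ConnectomeRecipe(
            n_regions=cfg.n_regions, intra_density=cfg.intra_density,
            inter_density=cfg.inter_density, weight_log_mean=cfg.weight_log_mean,
            weight_log_sd=cfg.weight_log_sd, homotopic_weight=cfg.homotopic_weight,
            seed=cfg.generate_seed)
        c = generate_connectome(recipe)
        write_connectome(outdir / "connectome.csv", c)
        manifest["stages"]["generate"] = {"seed": cfg.generate_seed,
                                          "hash": matrix_hash(c.weights)}

    metric_matrices = {}
    for name in cfg.metrics:
        if name not in METRIC_BUILDERS:
            raise ValueError(f"unknown metric {name!r}; choose from "
                             f"{sorted(METRIC_BUILDERS)}")
        m = METRIC_BUILDERS[name](c)
        metric_matrices[name] = m
        write_pairwise(outdir / f"{name}.csv", m)
        manifest["stages"][f"metric_{name}"] = {"hash": matrix_hash(m.values)}

    lam = cfg.coupling
    if lam is None:
        lam = find_near_critical_coupling(c, seed=cfg.sweep_seed)
        manifest["stages"]["coupling_sweep"] = {"seed": cfg.sweep_seed,
                                                "critical_coupling": lam}
    ising_cfg = IsingConfig(coupling=float(lam), n_steps=cfg.n_steps,
                            flip_fraction=cfg.flip_fraction,
                            proposal_mode=cfg.proposal_mode, seed=cfg.ising_seed)
    fc = simulate_fc(c, ising_cfg)
    write_pairwise(outdir / "fc.csv", fc,
                   extra_meta={"coupling": float(lam), "seed": cfg.ising_seed})
    manifest["stages"]["ising"] = {"seed": cfg.ising_seed, "coupling": float(lam),
                                   "hash": matrix_hash(fc.values)}

    mask = hemisphere_mask(c, cfg.mask)
    comparisons = {}
    for name, m in metric_matrices.items():
        res = spearman_compare(m, fc, mask=mask,
                               modes_x=cfg.modes_x, modes_y=cfg.modes_y)
        comparisons[name] = res.as_dict()
    (outdir / "comparison.json").write_text(json.dumps(comparisons, indent=2))
    manifest["stages"]["compare"] = comparisons
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
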