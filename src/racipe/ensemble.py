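"""Full ensemble runs: sample N models, solve each, assemble tables.

The product is the in-silico gene expression dataset: one row per stable
steady state (a model with m coexisting states contributes m rows,
unweighted) with the genes as columns, plus a parameter table with one row
per model.  Per-model random substreams are derived from the master seed,
so results are reproducible and independent of execution order.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .model import KineticParameters
from .sampling import (SamplingConfig, ThresholdMedians,
                       estimate_gene_medians, sample_model_parameters)
from .steady_state import SimulationError, SolverSettings, solve_model
from .topology import CircuitTopology, parse_topology, write_topology

__all__ = ["PerturbationMode", "Perturbation", "EnsembleConfig",
           "EnsembleResult", "run_ensemble", "apply_perturbation",
           "export_tables", "read_tables", "save_run_config",
           "load_run_config"]

_META_COLUMNS = ["model_id", "state_id", "n_states"]


class PerturbationMode(enum.Enum):
    KNOCKDOWN = "knockdown"
    OVEREXPRESS = "overexpress"


@dataclass(frozen=True)
class Perturbation:
    """A production-rate treatment of one gene across the whole ensemble."""

    gene: str
    mode: PerturbationMode
    factor: float = 10.0

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("perturbation factor must be positive")


@dataclass
class EnsembleConfig:
    """Everything needed to reproduce one ensemble run."""

    topology: CircuitTopology
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    solver: SolverSettings = field(default_factory=SolverSettings)
    n_models: int = 10_000
    master_seed: int = 0
    perturbation: Optional[Perturbation] = None

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


def apply_perturbation(params: KineticParameters, gene: str,
                       mode: Union[PerturbationMode, str],
                       factor: float) -> KineticParameters:
    """Knock down (divide) or overexpress (multiply) a gene's production.

    Only the maximum production rate G and the derived basal rate g of the
    targeted gene change; fold changes and thresholds are untouched.
    """
    if isinstance(mode, str):
        mode = PerturbationMode(mode.lower())
    if factor <= 0:
        raise ValueError("perturbation factor must be positive")
    scale = 1.0 / factor if mode is PerturbationMode.KNOCKDOWN else factor
    return params.with_production_scaled(gene, scale)


@dataclass
class EnsembleResult:
    """Stacked expression/parameter tables plus run metadata."""

    topology: CircuitTopology
    expression: pd.DataFrame      # model_id, state_id, n_states, <genes...>
    parameters: pd.DataFrame      # model_id, per-gene and per-edge params
    medians: ThresholdMedians
    config: EnsembleConfig
    metadata: dict

    @property
    def gene_names(self) -> list[str]:
        return self.topology.gene_names

    def levels(self) -> pd.DataFrame:
        """Just the per-gene expression columns of the stacked table."""
        return self.expression[self.gene_names]

    def states_per_model(self) -> pd.Series:
        return self.expression.groupby("model_id")["n_states"].first()


def _param_columns(topology: CircuitTopology) -> list[str]:
    cols = []
    for gname in topology.gene_names:
        cols += [f"G[{gname}]", f"k[{gname}]", f"g[{gname}]"]
    for e in topology.edges:
        tag = f"{e.source}->{e.target}"
        cols += [f"n[{tag}]", f"lam[{tag}]", f"x0[{tag}]"]
    return cols


def _param_row(params: KineticParameters) -> list[float]:
    row = []
    for i in range(len(params.gene_names)):
        row += [params.G[i], params.k[i], params.g[i]]
    for e in range(len(params.edge_pairs)):
        row += [float(params.n[e]), params.lam[e], params.x0[e]]
    return row


def run_ensemble(config: EnsembleConfig, progress: bool = False) -> EnsembleResult:
    """Run the full pipeline: medians, N random models, state enumeration.

    Deterministic for a given ``master_seed``: the threshold-median
    estimation uses one child stream of the seed, and model i draws its
    parameters and initial conditions from child stream i+1, so the result
    does not depend on execution order.
    """
    topo = config.topology
    children = np.random.SeedSequence(config.master_seed).spawn(
        config.n_models + 1)
    med_rng = np.random.default_rng(children[0])
    medians = estimate_gene_medians(topo, config.sampling, med_rng)

    expr_rows: list[list] = []
    param_rows: list[list] = []
    n_flagged = 0
    n_oscillating = 0
    n_failed = 0
    iterator = range(config.n_models)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic only
        iterator = tqdm(iterator, desc="models")
    for m in iterator:
        rng = np.random.default_rng(children[m + 1])
        params = sample_model_parameters(topo, config.sampling, medians, rng)
        if config.perturbation is not None:
            p = config.perturbation
            params = apply_perturbation(params, p.gene, p.mode, p.factor)
        try:
            sol = solve_model(topo, params, config.solver, rng)
        except SimulationError:
            n_failed += 1
            continue
        param_rows.append([m] + _param_row(params))
        if sol.oscillation_found:
            n_oscillating += 1
        if sol.n_states == 0:
            n_flagged += 1
            continue
        for s, state in enumerate(sol.states):
            expr_rows.append([m, s, sol.n_states] + list(state.levels))

    expression = pd.DataFrame(
        expr_rows, columns=_META_COLUMNS + topo.gene_names)
    expression[_META_COLUMNS] = expression[_META_COLUMNS].astype(np.int64)
    parameters = pd.DataFrame(
        param_rows, columns=["model_id"] + _param_columns(topo))
    parameters["model_id"] = parameters["model_id"].astype(np.int64)

    counts = expression.groupby("model_id")["n_states"].first()
    dist = (counts.value_counts(normalize=True).sort_index()
            if len(counts) else pd.Series(dtype=float))
    metadata = {
        "version": __version__,
        "master_seed": config.master_seed,
        "n_models": config.n_models,
        "n_models_with_states": int(counts.shape[0]),
        "n_models_flagged": n_flagged,
        "n_models_oscillating": n_oscillating,
        "n_models_failed": n_failed,
        "state_count_distribution": {int(k): float(v)
                                     for k, v in dist.items()},
        "isolated_median_M0": medians.M0,
        "gene_medians": {g: float(v) for g, v in
                         zip(topo.gene_names, medians.M)},
    }
    return EnsembleResult(topo, expression, parameters, medians, config,
                          metadata)


# ---------------------------------------------------------------------------
# run configuration files
# ---------------------------------------------------------------------------

def save_run_config(path: Union[str, Path], sampling: SamplingConfig,
                    solver: Optional[SolverSettings] = None) -> None:
    """Write sampling and solver settings to one plain-text key: value file."""
    import enum as _enum

    import yaml

    data = {}
    for obj in (sampling, solver):
        if obj is None:
            continue
        for k, v in vars(obj).items():
            if isinstance(v, _enum.Enum):
                v = v.value
            if isinstance(v, tuple):
                v = list(v)
            data[k] = v
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, default_flow_style=True, sort_keys=False)


def load_run_config(path: Union[str, Path]
                    ) -> tuple[SamplingConfig, SolverSettings]:
    """Read a combined config file; keys are routed to SamplingConfig or
    SolverSettings by field name, unknown keys are an error."""
    import dataclasses

    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    samp_fields = {f.name for f in dataclasses.fields(SamplingConfig)}
    solv_fields = {f.name for f in dataclasses.fields(SolverSettings)}
    samp_kw, solv_kw = {}, {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        if k in samp_fields:
            samp_kw[k] = v
        elif k in solv_fields:
            solv_kw[k] = v
        else:
            raise ValueError(f"unknown configuration key {k!r}")
    return SamplingConfig(**samp_kw), SolverSettings(**solv_kw)


# ---------------------------------------------------------------------------
# on-disk tables
# ---------------------------------------------------------------------------

def export_tables(result: EnsembleResult, out_dir: Union[str, Path]) -> dict:
    """Write expression.tsv, parameters.tsv, topology.topo and manifest.json.

    Floats are written with repr-exact precision, so reading the tables
    back reproduces the in-memory matrices bit for bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "parameters": out / "parameters.tsv",
        "topology": out / "topology.topo",
        "manifest": out / "manifest.json",
    }
    result.expression.to_csv(paths["expression"], sep="\t", index=False,
                             float_format=None)
    result.parameters.to_csv(paths["parameters"], sep="\t", index=False)
    write_topology(result.topology, paths["topology"])
    cfg = result.config
    manifest = {
        "metadata": result.metadata,
        "sampling": {k: (v.value if isinstance(v, enum.Enum) else v)
                     for k, v in vars(cfg.sampling).items()},
        "solver": vars(cfg.solver),
        "perturbation": (None if cfg.perturbation is None else {
            "gene": cfg.perturbation.gene,
            "mode": cfg.perturbation.mode.value,
            "factor": cfg.perturbation.factor}),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
        fh.write("\n")
    return paths


def read_tables(out_dir: Union[str, Path]) -> tuple[CircuitTopology,
                                                    pd.DataFrame,
                                                    pd.DataFrame]:
    """Read back an exported run: (topology, expression, parameters)."""
    out = Path(out_dir)
    topo = parse_topology(out / "topology.topo")
    expression = pd.read_csv(out / "expression.tsv", sep="\t")
    parameters = pd.read_csv(out / "parameters.tsv", sep="\t")
    return topo, expression, parameters
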