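"""Randomization of kinetic parameters, including the half-functional rule.

Five parameter classes are randomized per model: maximum production rates G
(the basal rate g is derived), degradation rates k, Hill coefficients n,
fold changes lambda and regulation thresholds X0.  Fold changes of
inhibitory links are sampled through their inverse (1/lambda- uniform on
[1, 100] by default), which concentrates lambda- near strong inhibition.

Thresholds are sampled so that each regulatory link has roughly a 50%
chance of being above or below threshold across the ensemble's stable
states (the half-functional rule).  This is achieved by a single-pass
mean-field estimate of each gene's median steady-state level: regulator
levels are approximated by the unregulated steady-state distribution G/k,
and the gene's own level distribution is then computed in closed form as
g * prod(HS) / k.  Thresholds of a gene's outgoing links are drawn from
[0.02, 1.98] times that gene's estimated median.

Alternative sampling distributions (Gaussian, exponential) and shrunk
ranges reproduce the robustness variants: Gaussian draws are centred on the
interval midpoint with sd = width/4, truncated to the interval; exponential
draws are anchored at the interval minimum with mean = width/4, truncated
at the maximum.  ``range_shrink`` (1, 1/2 or 1/4) narrows the uniform
interval about its midpoint, halves the Gaussian sd, or halves the
exponential mean per step.  Hill coefficients are always uniform integers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .model import KineticParameters, shifted_hill
from .topology import CircuitTopology, Sign

__all__ = ["Distribution", "SamplingConfig", "ThresholdMedians",
           "draw_value", "draw_values", "isolated_gene_median",
           "estimate_gene_medians", "sample_model_parameters",
           "unregulated_level_bounds"]


class Distribution(enum.Enum):
    UNIFORM = "uniform"
    GAUSSIAN = "gaussian"
    EXPONENTIAL = "exponential"


Interval = tuple[float, float]


@dataclass
class SamplingConfig:
    """Parameter ranges and sampling protocol for one ensemble.

    Defaults are the method's standard ranges: G in [1, 100], k in
    [0.1, 1], integer n in [1, 6], lambda+ in [1, 100], 1/lambda- in
    [1, 100] (so lambda- in [0.01, 1]) and thresholds in [0.02, 1.98]
    times the gene's estimated median level.
    """

    G_range: Interval = (1.0, 100.0)
    k_range: Interval = (0.1, 1.0)
    n_range: tuple[int, int] = (1, 6)
    lambda_act_range: Interval = (1.0, 100.0)
    lambda_inh_inverse_range: Interval = (1.0, 100.0)
    threshold_scaling: Interval = (0.02, 1.98)
    distribution: Distribution = Distribution.UNIFORM
    range_shrink: float = 1.0
    median_estimation_samples: int = 10_000
    seed: Optional[int] = None

    def __post_init__(self):
        if isinstance(self.distribution, str):
            self.distribution = Distribution(self.distribution.lower())
        for name in ("G_range", "k_range", "lambda_act_range",
                     "lambda_inh_inverse_range", "threshold_scaling"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lower <= upper, "
                                 f"got ({lo}, {hi})")
            setattr(self, name, (float(lo), float(hi)))
        n_lo, n_hi = self.n_range
        if not (1 <= n_lo <= n_hi):
            raise ValueError(f"n_range must satisfy 1 <= lower <= upper")
        self.n_range = (int(n_lo), int(n_hi))
        if self.range_shrink not in (1.0, 0.5, 0.25):
            raise ValueError("range_shrink must be one of 1, 1/2, 1/4")
        if self.median_estimation_samples < 1:
            raise ValueError("median_estimation_samples must be >= 1")

    # -- plain-text serialization (key: value) ---------------------------
    def to_file(self, path: Union[str, Path]) -> None:
        data = asdict(self)
        data["distribution"] = self.distribution.value
        data = {k: list(v) if isinstance(v, tuple) else v
                for k, v in data.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, default_flow_style=True, sort_keys=False)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SamplingConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data = {k: tuple(v) if isinstance(v, list) else v
                for k, v in data.items()}
        return cls(**data)


@dataclass(frozen=True)
class ThresholdMedians:
    """Per-gene estimated median steady-state level M (used to scale the
    thresholds of that gene's outgoing links), plus the isolated-gene
    median M0."""

    gene_names: tuple[str, ...]
    M: np.ndarray
    M0: float

    def __post_init__(self):
        if np.any(np.asarray(self.M) <= 0):
            raise ValueError("medians must be positive")

    def of(self, gene: str) -> float:
        return float(self.M[self.gene_names.index(gene)])


# ---------------------------------------------------------------------------
# elementary draws
# ---------------------------------------------------------------------------

def draw_values(dist: Distribution, interval: Interval,
                rng: np.random.Generator, size: int,
                shrink: float = 1.0) -> np.ndarray:
    """Draw ``size`` values from ``dist`` on ``interval``.

    Truncation (Gaussian to the interval, exponential at the maximum) is by
    resampling, so the draw count consumed from ``rng`` is data-dependent
    but fully determined by the stream state.
    """
    lo, hi = float(interval[0]), float(interval[1])
    if hi < lo:
        raise ValueError(f"invalid interval ({lo}, {hi})")
    width = hi - lo
    if dist is Distribution.UNIFORM:
        half = 0.5 * width * shrink
        mid = 0.5 * (lo + hi)
        return rng.uniform(mid - half, mid + half, size)
    if dist is Distribution.GAUSSIAN:
        mu, sd = 0.5 * (lo + hi), 0.25 * width * shrink
        out = rng.normal(mu, sd, size)
        bad = (out < lo) | (out > hi)
        while np.any(bad):
            out[bad] = rng.normal(mu, sd, int(bad.sum()))
            bad = (out < lo) | (out > hi)
        return out
    if dist is Distribution.EXPONENTIAL:
        mean = 0.25 * width * shrink
        out = lo + rng.exponential(mean, size)
        bad = out > hi
        while np.any(bad):
            out[bad] = lo + rng.exponential(mean, int(bad.sum()))
            bad = out > hi
        return out
    raise ValueError(f"unknown distribution {dist!r}")


def draw_value(dist: Distribution, interval: Interval,
               rng: np.random.Generator, shrink: float = 1.0) -> float:
    return float(draw_values(dist, interval, rng, 1, shrink)[0])


def _draw_int_n(config: SamplingConfig, rng: np.random.Generator,
                size: int) -> np.ndarray:
    # Hill coefficients are discrete-uniform integers under every
    # distribution variant.
    return rng.integers(config.n_range[0], config.n_range[1] + 1, size)


def unregulated_level_bounds(config: SamplingConfig) -> tuple[float, float]:
    """Extreme achievable steady levels G/k of an unregulated gene across
    the configured ranges (default: 1 to 1000, a relative ratio of 1000)."""
    return (config.G_range[0] / config.k_range[1],
            config.G_range[1] / config.k_range[0])


# ---------------------------------------------------------------------------
# half-functional threshold estimation
# ---------------------------------------------------------------------------

def isolated_gene_median(config: SamplingConfig,
                         rng: np.random.Generator) -> float:
    """Monte-Carlo median M0 of the unregulated steady level G/k."""
    S = config.median_estimation_samples
    d, s = config.distribution, config.range_shrink
    G = draw_values(d, config.G_range, rng, S, s)
    k = draw_values(d, config.k_range, rng, S, s)
    return float(np.median(G / k))


def _draw_threshold_scaling(config: SamplingConfig, rng: np.random.Generator,
                            size: int) -> np.ndarray:
    # Threshold scalings stay uniform (symmetric about the regulator's
    # median) under every distribution variant: an asymmetric draw such as
    # a minimum-anchored exponential would push thresholds far below the
    # median and silently break the half-functional rule the scheme is
    # built around.  Range shrink still applies.
    return draw_values(Distribution.UNIFORM, config.threshold_scaling, rng,
                       size, config.range_shrink)


def _draw_edge_lambda(config: SamplingConfig, sign: Sign,
                      rng: np.random.Generator, size: int) -> np.ndarray:
    d, s = config.distribution, config.range_shrink
    if sign is Sign.ACTIVATION:
        return draw_values(d, config.lambda_act_range, rng, size, s)
    return 1.0 / draw_values(d, config.lambda_inh_inverse_range, rng, size, s)


def estimate_gene_medians(topology: CircuitTopology, config: SamplingConfig,
                          rng: np.random.Generator,
                          M0: Optional[float] = None) -> ThresholdMedians:
    """Single-pass mean-field estimate of every gene's median steady level.

    For each gene (topology order), a synthetic ensemble is drawn in which
    every inward regulator's level follows the isolated-gene distribution
    G/k, inward thresholds are drawn from [0.02, 1.98] * M0, and the gene's
    closed-form steady level g * prod(HS) / k is computed; M is the median
    of those levels.  Genes without regulators get M = M0.  Feedback loops
    are deliberately not iterated: the regulator approximation is always
    the isolated distribution.

    Draw order per gene: for each inward edge (file order) the regulator's
    G and k, the threshold scaling, n and lambda; then the gene's own G
    and k.
    """
    if M0 is None:
        M0 = isolated_gene_median(config, rng)
    S = config.median_estimation_samples
    d, s = config.distribution, config.range_shrink
    M = np.empty(topology.n_genes)
    for i, gene in enumerate(topology.gene_names):
        inward = topology.edges_into(gene)
        if not inward:
            M[i] = M0
            continue
        hs_prod = np.ones(S)
        act_lambda_prod = np.ones(S)
        for _, edge in inward:
            reg_G = draw_values(d, config.G_range, rng, S, s)
            reg_k = draw_values(d, config.k_range, rng, S, s)
            x_reg = reg_G / reg_k
            x0 = _draw_threshold_scaling(config, rng, S) * M0
            n = _draw_int_n(config, rng, S)
            lam = _draw_edge_lambda(config, edge.sign, rng, S)
            hs_prod *= shifted_hill(x_reg, x0, n, lam)
            if edge.sign is Sign.ACTIVATION:
                act_lambda_prod *= lam
        G_i = draw_values(d, config.G_range, rng, S, s)
        k_i = draw_values(d, config.k_range, rng, S, s)
        levels = (G_i / act_lambda_prod) * hs_prod / k_i
        M[i] = np.median(levels)
    return ThresholdMedians(tuple(topology.gene_names), M, float(M0))


# ---------------------------------------------------------------------------
# per-model parameter sampling
# ---------------------------------------------------------------------------

def sample_model_parameters(topology: CircuitTopology, config: SamplingConfig,
                            medians: ThresholdMedians,
                            rng: np.random.Generator) -> KineticParameters:
    """Draw one model's full kinetic parameter set.

    Fixed draw order (the reproducibility contract): genes in topology
    order (G then k each), then edges in file order (n, lambda, X0).  The
    threshold of edge j->i is drawn from threshold_scaling * M_j, i.e. it
    scales with the *regulator's* estimated median.  Finally the basal rate
    g_i = G_i / prod(lambda+ of i's activators) is derived.
    """
    if tuple(topology.gene_names) != medians.gene_names:
        raise ValueError("medians are not aligned with this topology")
    d, s = config.distribution, config.range_shrink
    ng, ne = topology.n_genes, topology.n_edges
    G = np.empty(ng)
    k = np.empty(ng)
    for i in range(ng):
        G[i] = draw_value(d, config.G_range, rng, s)
        k[i] = draw_value(d, config.k_range, rng, s)
    lam = np.empty(ne)
    n = np.empty(ne, dtype=np.int64)
    x0 = np.empty(ne)
    for e, edge in enumerate(topology.edges):
        n[e] = _draw_int_n(config, rng, 1)[0]
        lam[e] = _draw_edge_lambda(config, edge.sign, rng, 1)[0]
        x0[e] = float(_draw_threshold_scaling(config, rng, 1)[0]) \
            * medians.of(edge.source)
    return KineticParameters(
        gene_names=tuple(topology.gene_names),
        edge_pairs=tuple((e.source, e.target) for e in topology.edges),
        edge_signs=tuple(e.sign for e in topology.edges),
        G=G, k=k, lam=lam, n=n, x0=x0)
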