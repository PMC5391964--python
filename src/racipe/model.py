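"""Deterministic rate equations for a circuit and one kinetic parameter set.

Each gene level x_i obeys

    dx_i/dt = g_i * prod_{edges j->i} HS(x_j; X0_ji, n_ji, lambda_ji) - k_i x_i

where HS is the shifted Hill function

    HS(x; x0, n, lam) = lam + (1 - lam) / (1 + (x/x0)^n),

equal to 1 when the regulator is absent and to lam at saturation: lam > 1
models activation, 0 < lam < 1 inhibition.  Multiple regulators combine
multiplicatively; the basal rate g_i = G_i / prod(lambda+ over activators)
makes the maximum production rate of gene i exactly G_i.

Levels and rates are in arbitrary (dimensionless) expression units; only
ratios are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .topology import CircuitTopology, Sign

__all__ = ["KineticParameters", "shifted_hill", "derivative", "jacobian",
           "steady_state_bounds"]


def shifted_hill(x, x0, n, lam):
    """Shifted Hill regulation factor lam + (1-lam)/(1+(x/x0)^n).

    Bounded between min(1, lam) and max(1, lam); monotone in ``x``
    (decreasing iff lam < 1).  Vectorized over all arguments.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("Hill threshold x0 must be positive")
    ratio = np.asarray(x, dtype=float) / x0
    return lam + (1.0 - lam) / (1.0 + ratio ** n)


def _shifted_hill_dx(x, x0, n, lam):
    """d(HS)/dx, analytic."""
    r = np.asarray(x, dtype=float) / x0
    rn = r ** n
    # d/dx [1/(1+r^n)] = -n r^(n-1) / (x0 (1+r^n)^2)
    return -(1.0 - lam) * n * r ** (n - 1) / (x0 * (1.0 + rn) ** 2)


@dataclass(frozen=True)
class KineticParameters:
    """One model's full parameter set, aligned with a topology.

    Per gene (topology order): maximum production rate ``G``, degradation
    rate ``k`` and the derived basal rate ``g = G / prod(lambda+)`` over the
    gene's activators.  Per edge (file order): fold change ``lam`` (>1 for
    activation, in (0,1) for inhibition), integer Hill coefficient ``n`` and
    regulator threshold ``x0``.
    """

    gene_names: tuple[str, ...]
    edge_pairs: tuple[tuple[str, str], ...]   # (source, target) per edge
    edge_signs: tuple[Sign, ...]
    G: np.ndarray
    k: np.ndarray
    lam: np.ndarray
    n: np.ndarray
    x0: np.ndarray
    g: np.ndarray = None  # derived; filled in __post_init__ if omitted

    def __post_init__(self):
        ng, ne = len(self.gene_names), len(self.edge_pairs)
        for arr_name, arr, size in (("G", self.G, ng), ("k", self.k, ng),
                                    ("lam", self.lam, ne), ("n", self.n, ne),
                                    ("x0", self.x0, ne)):
            arr = np.asarray(arr)
            if arr.shape != (size,):
                raise ValueError(f"{arr_name} must have shape ({size},)")
        if np.any(self.G <= 0) or np.any(self.k <= 0):
            raise ValueError("G and k must be positive")
        if ne and (np.any(self.x0 <= 0) or np.any(self.n < 1)
                   or np.any(self.lam <= 0)):
            raise ValueError("edge parameters must satisfy x0>0, n>=1, lam>0")
        if len(self.edge_signs) != ne:
            raise ValueError("edge_signs must match edge_pairs")
        for e, sign in enumerate(self.edge_signs):
            if sign is Sign.ACTIVATION and self.lam[e] <= 1.0:
                raise ValueError(f"activation edge {self.edge_pairs[e]} "
                                 f"requires lam > 1, got {self.lam[e]}")
            if sign is Sign.INHIBITION and not (0.0 < self.lam[e] < 1.0):
                raise ValueError(f"inhibition edge {self.edge_pairs[e]} "
                                 f"requires 0 < lam < 1, got {self.lam[e]}")
        if self.g is None:
            object.__setattr__(self, "g", self._derive_basal())

    def _derive_basal(self) -> np.ndarray:
        idx = {name: i for i, name in enumerate(self.gene_names)}
        g = np.array(self.G, dtype=float)
        for e, (src, tgt) in enumerate(self.edge_pairs):
            if self.edge_signs[e] is Sign.ACTIVATION:
                g[idx[tgt]] /= self.lam[e]
        return g

    def with_production_scaled(self, gene: str, factor: float) -> "KineticParameters":
        """Return a copy with gene's G (and derived g) multiplied by factor."""
        if gene not in self.gene_names:
            raise ValueError(f"unknown gene {gene!r}")
        i = self.gene_names.index(gene)
        G = np.array(self.G, dtype=float)
        g = np.array(self.g, dtype=float)
        G[i] *= factor
        g[i] *= factor
        return replace(self, G=G, g=g)


def _edge_arrays(topology: CircuitTopology):
    idx = {name: i for i, name in enumerate(topology.gene_names)}
    src = np.array([idx[e.source] for e in topology.edges], dtype=np.int64)
    tgt = np.array([idx[e.target] for e in topology.edges], dtype=np.int64)
    return src, tgt


def _check_alignment(topology: CircuitTopology, params: KineticParameters,
                     state) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (topology.n_genes,):
        raise ValueError(f"state must have shape ({topology.n_genes},), "
                         f"got {state.shape}")
    if tuple(topology.gene_names) != tuple(params.gene_names):
        raise ValueError("parameter set is not aligned with this topology")
    return state


def derivative(topology: CircuitTopology, params: KineticParameters,
               state) -> np.ndarray:
    """Rates dx/dt at ``state`` (one entry per gene, topology order)."""
    x = _check_alignment(topology, params, state)
    src, tgt = _edge_arrays(topology)
    prod = params.g.astype(float).copy()
    if len(src):
        hs = shifted_hill(x[src], params.x0, params.n, params.lam)
        np.multiply.at(prod, tgt, hs)
    return prod - params.k * x


def jacobian(topology: CircuitTopology, params: KineticParameters,
             state) -> np.ndarray:
    """Analytic Jacobian J[i, j] = d(rate_i)/dx_j; diagonal includes -k_i."""
    x = _check_alignment(topology, params, state)
    n = topology.n_genes
    src, tgt = _edge_arrays(topology)
    J = np.zeros((n, n))
    if len(src):
        hs = shifted_hill(x[src], params.x0, params.n, params.lam)
        dhs = _shifted_hill_dx(x[src], params.x0, params.n, params.lam)
        prod = params.g.astype(float).copy()
        np.multiply.at(prod, tgt, hs)
        # d(prod_i)/dx_j = prod_i / HS_e * HS'_e for the (unique) edge j->i
        for e in range(len(src)):
            J[tgt[e], src[e]] += prod[tgt[e]] / hs[e] * dhs[e]
    J[np.diag_indices(n)] -= params.k
    return J


def steady_state_bounds(topology: CircuitTopology,
                        params: KineticParameters) -> tuple[np.ndarray, np.ndarray]:
    """Analytic per-gene bounds [x_min, x_max] on reachable steady levels.

    x_max_i = G_i / k_i (all activators saturated, inhibitors absent);
    x_min_i = (G_i / k_i) * prod(lambda- of inhibitors) / prod(lambda+ of
    activators) (the reverse extreme).  The box is forward-invariant.
    """
    x_max = params.G / params.k
    x_min = x_max.copy()
    idx = {name: i for i, name in enumerate(topology.gene_names)}
    for e, (edge, lam) in enumerate(zip(topology.edges, params.lam)):
        i = idx[edge.target]
        if edge.sign is Sign.INHIBITION:
            x_min[i] *= lam
        else:
            x_min[i] /= lam
    return x_min, x_max
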