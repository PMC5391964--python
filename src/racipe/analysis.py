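"""Statistical post-processing of an ensemble: gene-state identification.

The stacked stable-state table is treated like an expression microarray:
levels are log10-transformed and z-scored per gene, clustered by
average-linkage hierarchical clustering on Euclidean distance, and each
cluster receives a per-gene LOW / INTERMEDIATE / HIGH call by comparing
the cluster median with the full-ensemble terciles.  PCA projections and
2-D density maps reproduce the standard visual summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .ensemble import EnsembleResult

__all__ = ["state_count_distribution", "half_functional_fractions",
           "normalize_expression", "hierarchical_clustering",
           "choose_n_clusters", "major_gene_states", "pca_projection",
           "assign_expression_levels",
           "density_map", "axis_silhouette", "GeneStateTable"]

LEVEL_CALLS = ("LOW", "INTERMEDIATE", "HIGH")


def state_count_distribution(result: EnsembleResult) -> pd.Series:
    """P(number of stable states) across models, tallied once per model.

    Models flagged as having no stable state (non-convergent or
    oscillatory) are excluded; the probabilities sum to 1 over the models
    that contributed rows.
    """
    counts = result.states_per_model()
    if counts.empty:
        raise ValueError("ensemble has no solved models")
    return counts.value_counts(normalize=True).sort_index()


def half_functional_fractions(result: EnsembleResult) -> pd.Series:
    """Per-edge fraction of stable-state rows with regulator above threshold.

    For each edge j->i the sampled threshold x0 varies per model; a row
    counts as "above" when the regulator's level at that stable state
    exceeds its own model's threshold.  Under the half-functional rule
    every fraction should sit near 0.5.
    """
    expr = result.expression
    params = result.parameters.set_index("model_id")
    out = {}
    for e in result.topology.edges:
        tag = f"{e.source}->{e.target}"
        thr = params[f"x0[{tag}]"].reindex(expr["model_id"]).to_numpy()
        lvl = expr[e.source].to_numpy()
        out[tag] = float(np.mean(lvl > thr))
    return pd.Series(out, name="fraction_above_threshold")


def normalize_expression(levels: Union[pd.DataFrame, np.ndarray],
                         ) -> pd.DataFrame:
    """log10 transform then per-gene z-score (columns = genes).

    Zero-variance columns map to all-zero z-scores.  Raises on
    non-positive levels, which the model cannot produce.
    """
    df = pd.DataFrame(levels).astype(float)
    if (df <= 0).any().any():
        raise ValueError("expression levels must be strictly positive")
    logs = np.log10(df)
    sd = logs.std(axis=0, ddof=0)
    sd = sd.replace(0.0, 1.0)
    return (logs - logs.mean(axis=0)) / sd


def hierarchical_clustering(normalized: Union[pd.DataFrame, np.ndarray],
                            n_clusters: int) -> np.ndarray:
    """Average-linkage / Euclidean agglomerative clustering, cut at
    ``n_clusters``; labels 0..n_clusters-1 ordered by descending occupancy."""
    X = np.asarray(normalized, dtype=float)
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > X.shape[0]:
        raise ValueError(f"n_clusters={n_clusters} exceeds row count "
                         f"{X.shape[0]}")
    if n_clusters == 1:
        return np.zeros(X.shape[0], dtype=np.int64)
    Z = linkage(X, method="average", metric="euclidean")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    return _relabel_by_occupancy(raw)


def _relabel_by_occupancy(raw: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(raw, return_counts=True)
    # stable tie-break: larger cluster first, then smaller original id
    order = ids[np.lexsort((ids, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[v] for v in raw], dtype=np.int64)


def _z_pattern(median_z: np.ndarray, band: float) -> tuple:
    """Discrete H/I/L signature of a cluster from its median z-scores."""
    return tuple("H" if v > band else ("L" if v < -band else "I")
                 for v in median_z)


def _pattern_occupancy_at_cut(X: np.ndarray, Z: np.ndarray, cut: int,
                              min_occupancy: float, band: float):
    """Distinct H/I/L state signatures among clusters holding at least
    ``min_occupancy`` of rows at dendrogram cut ``cut``, with per-pattern
    occupancies and per-row pattern labels (-1 for rows outside major
    clusters)."""
    labels = fcluster(Z, t=cut, criterion="maxclust")
    ids, counts = np.unique(labels, return_counts=True)
    major = ids[counts / X.shape[0] >= min_occupancy]
    patterns: dict[tuple, float] = {}
    row_pattern = {}
    for c in major:
        mask = labels == c
        pat = _z_pattern(np.median(X[mask], axis=0), band)
        patterns[pat] = patterns.get(pat, 0.0) + mask.mean()
        row_pattern[c] = pat
    return patterns, labels, row_pattern


def choose_n_clusters(normalized: Union[pd.DataFrame, np.ndarray],
                      min_occupancy: float = 0.05,
                      max_scan: int = 40,
                      z_band: float = 0.3) -> int:
    """Occupancy-plateau heuristic for the number of major gene states.

    Dendrogram cuts from 2 to ``max_scan`` clusters are scanned; at each
    cut the clusters holding at least ``min_occupancy`` of the rows are
    reduced to discrete H/I/L signatures (cluster median z-score against
    a +-``z_band`` band), so sub-clusters of one state collapse onto one
    signature while states differing by a flipped switch stay distinct.
    The returned value is the signature count sustained over the longest
    range of cuts (the plateau).  Average linkage splits isolated outlier
    rows off first, which is why naive all-clusters-above-threshold rules
    underestimate; counting major signatures per cut is insensitive to
    those early singleton splits.
    """
    X = np.asarray(normalized, dtype=float)
    Z = linkage(X, method="average", metric="euclidean")
    vals = []
    for k in range(2, min(max_scan, X.shape[0]) + 1):
        patterns, _, _ = _pattern_occupancy_at_cut(X, Z, k, min_occupancy,
                                                   z_band)
        vals.append(len(patterns))
    if not vals:
        return 1
    uniq, counts = np.unique(vals, return_counts=True)
    return int(uniq[np.argmax(counts)])


def major_gene_states(normalized: Union[pd.DataFrame, np.ndarray],
                      min_occupancy: float = 0.05,
                      max_scan: int = 40,
                      z_band: float = 0.3
                      ) -> tuple[int, pd.DataFrame, np.ndarray]:
    """Major gene states via the occupancy-plateau heuristic.

    Returns ``(n_states, states, row_labels)`` where ``states`` has one
    row per state (H/I/L signature per gene plus occupancy, sorted by
    descending occupancy) evaluated at the shallowest cut realizing the
    plateau count, and ``row_labels`` maps each expression row to a state
    index (-1 for rows outside the major clusters).
    """
    X = np.asarray(normalized, dtype=float)
    cols = (list(normalized.columns)
            if isinstance(normalized, pd.DataFrame)
            else list(range(X.shape[1])))
    Z = linkage(X, method="average", metric="euclidean")
    per_cut = {}
    vals = []
    for k in range(2, min(max_scan, X.shape[0]) + 1):
        res = _pattern_occupancy_at_cut(X, Z, k, min_occupancy, z_band)
        per_cut[k] = res
        vals.append(len(res[0]))
    if not vals:
        raise ValueError("too few rows to identify gene states")
    uniq, counts = np.unique(vals, return_counts=True)
    n_states = int(uniq[np.argmax(counts)])
    cut = next(k for k in sorted(per_cut) if len(per_cut[k][0]) == n_states)
    patterns, labels, row_pattern = per_cut[cut]
    order = sorted(patterns, key=lambda p: -patterns[p])
    index = {p: i for i, p in enumerate(order)}
    states = pd.DataFrame([list(p) for p in order], columns=cols)
    states["occupancy"] = [patterns[p] for p in order]
    row_labels = np.array([index.get(row_pattern.get(l, None), -1)
                           for l in labels], dtype=np.int64)
    return n_states, states, row_labels


def pca_projection(normalized: Union[pd.DataFrame, np.ndarray],
                   n_components: int = 2
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the normalized matrix: (coordinates, explained-variance
    shares, loadings).  Sign convention: the largest-magnitude loading of
    each component is positive, so projections are deterministic."""
    X = np.asarray(normalized, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 genes")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("matrix has no variance")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    comps = pca.components_.copy()
    for c in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[c]))
        if comps[c, j] < 0:
            comps[c] = -comps[c]
            coords[:, c] = -coords[:, c]
    return coords, pca.explained_variance_ratio_, comps


@dataclass
class GeneStateTable:
    """Cluster labels, occupancy fractions and per-(cluster, gene) calls."""

    labels: np.ndarray
    occupancy: pd.Series              # cluster -> fraction of rows
    calls: pd.DataFrame               # rows = clusters, cols = genes
    cluster_medians: pd.DataFrame


def assign_expression_levels(levels: Union[pd.DataFrame, np.ndarray],
                             labels: Sequence[int]) -> GeneStateTable:
    """Call each (cluster, gene) LOW / INTERMEDIATE / HIGH.

    The cluster's per-gene median is compared against the full-ensemble
    terciles of that gene: below the 1st tercile is LOW, above the 2nd is
    HIGH, otherwise INTERMEDIATE.  Quantile-based, hence invariant under
    any monotone rescaling applied uniformly to a gene's column.
    """
    df = pd.DataFrame(levels).astype(float).reset_index(drop=True)
    labels = np.asarray(labels)
    if len(labels) != len(df):
        raise ValueError("labels must cover every expression row")
    t1 = df.quantile(1.0 / 3.0)
    t2 = df.quantile(2.0 / 3.0)
    clusters = np.unique(labels)
    medians = {}
    for c in clusters:
        sub = df[labels == c]
        if sub.empty:
            raise ValueError(f"cluster {c} is empty")
        medians[c] = sub.median()
    med = pd.DataFrame(medians).T
    calls = pd.DataFrame("INTERMEDIATE", index=med.index, columns=df.columns)
    # boundary ties go to the extreme call, except for degenerate genes
    # whose terciles coincide (those stay INTERMEDIATE)
    calls = calls.mask(med.le(t1, axis=1) & med.lt(t2, axis=1), "LOW")
    calls = calls.mask(med.ge(t2, axis=1) & med.gt(t1, axis=1), "HIGH")
    occupancy = (pd.Series(labels).value_counts(normalize=True)
                 .reindex(clusters).sort_index())
    return GeneStateTable(labels, occupancy, calls, med)


def density_map(values: Union[pd.DataFrame, np.ndarray],
                axes: tuple = (0, 1), bins: int = 50,
                log: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized 2-D histogram (sums to 1) over a gene or PC pair.

    ``axes`` selects two columns by name or position; with ``log=True``
    the histogram is taken on log10 coordinates (for raw levels).
    """
    df = pd.DataFrame(values)
    cols = []
    for a in axes:
        if isinstance(a, str):
            if a not in df.columns:
                raise ValueError(f"unknown gene/axis {a!r}")
            cols.append(df[a].to_numpy(dtype=float))
        else:
            cols.append(df.iloc[:, a].to_numpy(dtype=float))
    x, y = cols
    if log:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-scaled axes require positive values")
        x, y = np.log10(x), np.log10(y)
    hist, xe, ye = np.histogram2d(x, y, bins=bins)
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return hist, xe, ye


def axis_silhouette(values: Union[pd.DataFrame, np.ndarray],
                    labels: Sequence[int], axes: tuple,
                    log: bool = True) -> float:
    """Silhouette score of the cluster labels using only a 2-gene (or
    2-axis) projection — how well that marker pair separates the states."""
    from sklearn.metrics import silhouette_score

    df = pd.DataFrame(values)
    cols = [df[a] if isinstance(a, str) else df.iloc[:, a] for a in axes]
    X = np.column_stack([c.to_numpy(dtype=float) for c in cols])
    if log:
        X = np.log10(np.maximum(X, 1e-12))
    return float(silhouette_score(X, np.asarray(labels)))
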