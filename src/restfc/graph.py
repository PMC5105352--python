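"""Binary brain graphs over a density grid and their small-world metrics.

Each subject's Fisher-z FC matrix is thresholded proportionally: at
density d the k = round(d * R(R-1)/2) strongest edges are kept, so every
subject's graph has the same wiring cost and metrics are comparable
across subjects.  On the binary graph we compute nodal clustering and
local efficiency, the network clustering coefficient C (mean of nodal
values over all nodes), the characteristic path length L as the harmonic
mean of geodesic distances (finite for disconnected graphs; the
reciprocal of global efficiency), and the size of the largest connected
component.

Small-worldness is sigma = (C/C_rand) / (L/L_rand) where C_rand, L_rand
average over an ensemble of degree-preserving random graphs produced by
Maslov–Sneppen double-edge swaps (default 30 nulls, 10 successful swaps
per edge).  sigma > 1 indicates small-world organisation.

Graphs are plain boolean adjacency matrices; all-pairs unweighted
distances go through scipy.sparse.csgraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

logger = logging.getLogger(__name__)


@dataclass
class NullEnsembleSpec:
    """Size and intensity of the degree-preserving null ensemble."""

    n_nulls: int = 30
    swaps_per_edge: int = 10
    count_attempts: bool = False  # count attempted instead of successful swaps

    def __post_init__(self) -> None:
        if self.n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


def default_density_grid() -> list[float]:
    """Density levels 0.05 to 0.95 in steps of 0.05 (19 levels)."""
    return [round(0.05 * k, 2) for k in range(1, 20)]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def proportional_threshold(
    z: np.ndarray, density: float, use_abs: bool = False
) -> np.ndarray:
    """Keep the top fraction ``density`` of edges as a boolean adjacency.

    Edges are ranked by signed z-value (or |z| with ``use_abs``); ties at
    the cutoff break by ascending (i, j) order so results are
    deterministic.  Exactly k = round(density * R(R-1)/2) edges are kept.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    z = np.asarray(z, dtype=float)
    r = z.shape[0]
    iu, ju = np.triu_indices(r, k=1)
    w = z[iu, ju]
    if use_abs:
        w = np.abs(w)
    m = w.size
    k = _round_half_away(density * m)
    # lexsort: last key primary -> strongest first, ties by ascending (i, j)
    order = np.lexsort((ju, iu, -w))
    keep = order[:k]
    adj = np.zeros((r, r), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    return adj | adj.T


def graph_n_edges(adj: np.ndarray) -> int:
    return int(adj.sum()) // 2


def nodal_clustering(adj: np.ndarray) -> np.ndarray:
    """c_i = 2 t_i / (k_i (k_i - 1)), zero for degree < 2."""
    a = np.asarray(adj, dtype=float)
    deg = a.sum(axis=0)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return c


def _pairwise_distances(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)


def _efficiency_from_distances(d: np.ndarray) -> float:
    """Mean of 1/d over ordered pairs, with 1/inf = 0."""
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(adj: np.ndarray) -> float:
    return _efficiency_from_distances(_pairwise_distances(adj))


def nodal_local_efficiency(adj: np.ndarray) -> np.ndarray:
    """Efficiency of each node's neighbour-induced subgraph (0 for degree < 2)."""
    adj = np.asarray(adj, dtype=bool)
    r = adj.shape[0]
    out = np.zeros(r)
    for node in range(r):
        nbrs = np.flatnonzero(adj[node])
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[node] = global_efficiency(sub)
    return out


def network_clustering(adj: np.ndarray) -> float:
    """C: mean nodal clustering over all R nodes (zero-degree nodes count as 0)."""
    return float(nodal_clustering(adj).mean())


def characteristic_path_length(adj: np.ndarray) -> float:
    """Harmonic mean of geodesic distances over ordered pairs.

    L = P / sum(1/d) with P = R(R-1) and 1/d = 0 for disconnected pairs;
    equivalently the reciprocal of global efficiency.  Finite for any
    graph with at least one edge; an edgeless graph raises.
    """
    adj = np.asarray(adj, dtype=bool)
    if graph_n_edges(adj) == 0:
        raise ValueError("characteristic path length undefined for an edgeless graph")
    eff = global_efficiency(adj)
    return 1.0 / eff


def largest_component_size(adj: np.ndarray) -> int:
    adj = np.asarray(adj, dtype=bool)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    return int(np.bincount(labels, minlength=n_comp).max())


def double_edge_swap(
    adj: np.ndarray,
    n_swaps: int,
    rng: np.random.Generator,
    max_attempt_factor: int = 100,
    count_attempts: bool = False,
) -> tuple[np.ndarray, int]:
    """Degree-preserving rewiring by repeated double-edge swaps.

    Picks two edges (a,b), (c,d), rewires to (a,d), (c,b); rejects swaps
    that would create a self-loop or duplicate edge (all four endpoints
    must be distinct and the new edges absent).  Runs until ``n_swaps``
    successful swaps (or attempts, with ``count_attempts``), capping
    attempts at ``max_attempt_factor * n_swaps`` with a logged shortfall.
    Returns the rewired adjacency and the number of successful swaps.
    """
    a_mat = np.array(adj, dtype=bool)
    iu, ju = np.nonzero(np.triu(a_mat, k=1))
    m = iu.size
    if m < 2:
        logger.warning("graph too small to rewire; returning a copy")
        return a_mat, 0
    eu = iu.copy()
    ev = ju.copy()
    successes = 0
    attempts = 0
    cap = max_attempt_factor * n_swaps
    block = max(256, min(n_swaps * 4, 1 << 16))
    while attempts < cap:
        if count_attempts:
            if attempts >= n_swaps:
                break
        elif successes >= n_swaps:
            break
        e1 = rng.integers(0, m, size=block)
        e2 = rng.integers(0, m, size=block)
        flips = rng.integers(0, 2, size=block)
        for i1, i2, flip in zip(e1, e2, flips):
            if count_attempts:
                if attempts >= n_swaps:
                    break
            elif successes >= n_swaps:
                break
            attempts += 1
            if attempts > cap:
                break
            if i1 == i2:
                continue
            a, b = eu[i1], ev[i1]
            c, d = (ev[i2], eu[i2]) if flip else (eu[i2], ev[i2])
            if a == c or a == d or b == c or b == d:
                continue
            if a_mat[a, d] or a_mat[c, b]:
                continue
            a_mat[a, b] = a_mat[b, a] = False
            a_mat[c, d] = a_mat[d, c] = False
            a_mat[a, d] = a_mat[d, a] = True
            a_mat[c, b] = a_mat[b, c] = True
            eu[i1], ev[i1] = (a, d) if a < d else (d, a)
            eu[i2], ev[i2] = (c, b) if c < b else (b, c)
            successes += 1
    if not count_attempts and successes < n_swaps:
        logger.warning(
            "rewiring fell short: %d of %d swaps after %d attempts",
            successes,
            n_swaps,
            attempts,
        )
    return a_mat, successes


def maslov_sneppen_ensemble(
    adj: np.ndarray, spec: NullEnsembleSpec, rng: np.random.Generator
) -> list[np.ndarray]:
    """Ensemble of degree-preserving nulls for one graph."""
    m = graph_n_edges(adj)
    target = spec.swaps_per_edge * m
    return [
        double_edge_swap(adj, target, rng, count_attempts=spec.count_attempts)[0]
        for _ in range(spec.n_nulls)
    ]


@dataclass
class SmallWorldResult:
    clustering: float
    path_length: float
    clustering_rand: float
    path_length_rand: float
    clustering_norm: float
    path_length_norm: float
    sigma: float


def small_worldness(
    adj: np.ndarray,
    spec: NullEnsembleSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> SmallWorldResult:
    """sigma = (C/C_rand) / (L/L_rand) against the rewired-null ensemble.

    If the nulls are triangle-free (C_rand = 0) sigma is reported as NaN
    rather than infinite.
    """
    spec = spec or NullEnsembleSpec()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    c = network_clustering(adj)
    length = characteristic_path_length(adj)
    nulls = maslov_sneppen_ensemble(adj, spec, rng)
    c_rand = float(np.mean([network_clustering(g) for g in nulls]))
    l_rand = float(np.mean([characteristic_path_length(g) for g in nulls]))
    if c_rand > 0 and l_rand > 0:
        c_norm = c / c_rand
        l_norm = length / l_rand
        sigma = c_norm / l_norm
    else:
        logger.warning("null ensemble has zero clustering or path length; sigma undefined")
        c_norm = c / c_rand if c_rand > 0 else np.nan
        l_norm = length / l_rand if l_rand > 0 else np.nan
        sigma = np.nan
    return SmallWorldResult(
        clustering=c,
        path_length=length,
        clustering_rand=c_rand,
        path_length_rand=l_rand,
        clustering_norm=c_norm,
        path_length_norm=l_norm,
        sigma=sigma,
    )


@dataclass
class GraphMetricsResult:
    """Nodal and global graph metrics per subject x density."""

    nodal: pd.DataFrame  # subject_id, density, node, clustering, local_efficiency
    global_: pd.DataFrame  # subject_id, density, C, L, ..., sigma, largest_component
    spec: NullEnsembleSpec = field(default_factory=NullEnsembleSpec)

    def to_long_frame(self) -> pd.DataFrame:
        nodal_long = self.nodal.melt(
            id_vars=["subject_id", "density", "node"], var_name="metric", value_name="value"
        )
        glob = self.global_.melt(
            id_vars=["subject_id", "density"], var_name="metric", value_name="value"
        )
        glob.insert(2, "node", "global")
        return pd.concat([nodal_long, glob], ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def _substream(master_seed: int, subject_idx: int, density_idx: int) -> np.random.Generator:
    # counter-based derivation: execution order cannot change results
    ss = np.random.SeedSequence([int(master_seed) % (2**31), subject_idx, density_idx])
    return np.random.default_rng(ss)


def run_density_grid(
    matrices: dict[str, np.ndarray],
    grid: list[float] | None = None,
    spec: NullEnsembleSpec | None = None,
    seed: int = 0,
    use_abs: bool = False,
) -> GraphMetricsResult:
    """All metrics for every subject at every density level.

    ``matrices`` maps subject_id to a symmetric Fisher-z FC matrix.  The
    null-ensemble stream for each (subject, density) cell is derived from
    the master seed by counter, so the result is independent of iteration
    order and bit-reproducible.
    """
    grid = sorted(grid if grid is not None else default_density_grid())
    for d in grid:
        if not 0 < d <= 1:
            raise ValueError(f"density {d} outside (0, 1]")
    spec = spec or NullEnsembleSpec()
    nodal_rows = []
    global_rows = []
    for s_idx, (subject_id, z) in enumerate(matrices.items()):
        r = z.shape[0]
        for d_idx, density in enumerate(grid):
            adj = proportional_threshold(z, density, use_abs=use_abs)
            c_nodes = nodal_clustering(adj)
            e_nodes = nodal_local_efficiency(adj)
            rng = _substream(seed, s_idx, d_idx)
            sw = small_worldness(adj, spec, rng)
            nodal_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_id,
                        "density": density,
                        "node": np.arange(1, r + 1),
                        "clustering": c_nodes,
                        "local_efficiency": e_nodes,
                    }
                )
            )
            global_rows.append(
                {
                    "subject_id": subject_id,
                    "density": density,
                    "n_edges": graph_n_edges(adj),
                    "C": sw.clustering,
                    "L": sw.path_length,
                    "C_rand": sw.clustering_rand,
                    "L_rand": sw.path_length_rand,
                    "C_norm": sw.clustering_norm,
                    "L_norm": sw.path_length_norm,
                    "sigma": sw.sigma,
                    "largest_component": largest_component_size(adj),
                }
            )
    return GraphMetricsResult(
        nodal=pd.concat(nodal_rows, ignore_index=True),
        global_=pd.DataFrame(global_rows),
        spec=spec,
    )
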