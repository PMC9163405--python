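"""Graph-theoretic metrics of binarized windowed FC over a sparsity grid.

Each windowed Fisher-z matrix is binarized by keeping the strongest positive
edges at a series of sparsity thresholds (default 0.2-0.3, step 0.01, so 11
grid points).  On every binarized graph seven global metrics are computed:
global efficiency (integration), local efficiency and clustering coefficient
(segregation), characteristic path length, and the normalized small-world
metrics gamma, lambda and sigma = gamma/lambda against degree-preserving
rewired null graphs.  Each metric is integrated over the sparsity grid
(AUC), and the across-window variance of the AUC quantifies how much
network topology fluctuates over the scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .windows import WindowedFCStack, vec_to_matrix

METRIC_NAMES = ("E_glob", "E_loc", "C_p", "L_p", "gamma", "lambda", "sigma")


@dataclass(frozen=True)
class SparsityGrid:
    """Sparsity thresholds for binarization (fraction of strongest edges kept)."""

    s_min: float = 0.2
    s_max: float = 0.3
    s_step: float = 0.01

    def __post_init__(self):
        if not (0 < self.s_min <= self.s_max < 1):
            raise ValueError("need 0 < s_min <= s_max < 1")
        n = (self.s_max - self.s_min) / self.s_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step must divide the sparsity range")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.s_step)) + 1
        return self.s_min + self.s_step * np.arange(n)


def binarize_sparsity(z_matrix: np.ndarray, sparsity: float) -> np.ndarray:
    """Keep the round(S*E) largest positive edges as an unweighted adjacency.

    E = N(N-1)/2 is the number of possible edges; round is banker's rounding.
    If fewer positive edges exist than requested, all positive edges are
    kept.  Ties break toward the lower fixed edge index.  Self-loops never.
    """
    m = np.asarray(z_matrix, dtype=float)
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    if not (0 < sparsity < 1):
        raise ValueError("sparsity must lie in (0, 1)")
    n = m.shape[0]
    iu = np.triu_indices(n, 1)
    vals = m[iu]
    n_possible = vals.size
    n_keep = int(np.rint(sparsity * n_possible))
    pos = vals > 0
    n_keep = min(n_keep, int(pos.sum()))
    adj = np.zeros((n, n), dtype=int)
    if n_keep > 0:
        order = np.argsort(-vals, kind="stable")  # lowest index first on ties
        keep = order[:n_keep]
        adj[(iu[0][keep], iu[1][keep])] = 1
        adj += adj.T
    return adj


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths of an unweighted undirected graph.

    Dense matrix-power BFS: (A^k)_{ij} > 0 iff a walk of length k exists, so
    the first k at which a pair becomes reachable is its distance.  For the
    small dense graphs used here this avoids sparse-matrix overhead.
    """
    a = (np.asarray(adj) > 0).astype(float)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    cur = a.copy()
    for d in range(1, n):
        new = (cur > 0) & np.isinf(dist)
        if not new.any():
            break
        dist[new] = d
        cur = cur @ a
    return dist


def _efficiency(adj: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_metrics(adj: np.ndarray) -> dict[str, float]:
    """E_glob, E_loc, C_p and L_p of a binary undirected graph.

    Global efficiency averages inverse shortest-path lengths over all node
    pairs (0 for disconnected pairs); local efficiency averages each node's
    neighborhood-subgraph efficiency; C_p is the mean binary clustering
    coefficient (0 for degree < 2 nodes); L_p averages shortest-path lengths
    over connected pairs only (disconnected pairs are excluded rather than
    set to infinity).
    """
    a = np.asarray(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    dist = _distances(a)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(dist > 0, dist, np.inf), 0.0)
    e_glob = float(inv[off].sum() / (n * (n - 1)))
    l_p = float(dist[finite].mean()) if finite.any() else 0.0
    deg = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1) / 2.0
    c_nodes = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)
    c_p = float(c_nodes.mean())
    e_loc_nodes = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size >= 2:
            e_loc_nodes[i] = _efficiency(a[np.ix_(nb, nb)])
    return {"E_glob": e_glob, "E_loc": float(e_loc_nodes.mean()),
            "C_p": c_p, "L_p": l_p}


def _rewired_null(g: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    null = g.copy()
    m = null.number_of_edges()
    if m < 2:
        return null
    nswap = 10 * m
    # Maslov-Sneppen double-edge swaps; falls back to the graph itself when
    # no swap is possible (e.g., stars)
    try:
        nx.double_edge_swap(null, nswap=nswap, max_tries=20 * nswap,
                            seed=int(rng.integers(2 ** 31)))
    except nx.NetworkXError:
        pass
    except nx.NetworkXAlgorithmError:
        pass
    return null


def normalized_metrics(adj: np.ndarray, n_null: int = 100, seed: int = 0
                       ) -> dict[str, float]:
    """gamma, lambda and sigma against degree-preserving rewired nulls.

    gamma = C_p / <C_p of nulls>, lambda = L_p / <L_p of nulls>, sigma =
    gamma / lambda.  Nulls are Maslov-Sneppen double-edge-swap graphs (10*|E|
    attempted swaps each); the ensemble is deterministic given the seed.
    Graphs whose null mean C_p or L_p is zero get gamma/lambda of 1.
    """
    if adj.sum() == 0:
        raise ValueError("graph has no edges")
    g = nx.from_numpy_array(adj)
    base = global_metrics(adj)
    rng = np.random.default_rng(seed)
    c_null, l_null = [], []
    for _ in range(n_null):
        null = _rewired_null(g, rng)
        null_adj = nx.to_numpy_array(null, nodelist=range(adj.shape[0])).astype(int)
        nm = global_metrics(null_adj)
        c_null.append(nm["C_p"])
        l_null.append(nm["L_p"])
    c_bar, l_bar = float(np.mean(c_null)), float(np.mean(l_null))
    gamma = base["C_p"] / c_bar if c_bar > 0 else 1.0
    lam = base["L_p"] / l_bar if l_bar > 0 else 1.0
    return {"gamma": gamma, "lambda": lam, "sigma": gamma / lam}


def all_metrics(adj: np.ndarray, n_null: int = 100, seed: int = 0,
                compute_normalized: bool = True) -> dict[str, float]:
    rec = global_metrics(adj)
    if compute_normalized and adj.sum() > 0:
        rec.update(normalized_metrics(adj, n_null=n_null, seed=seed))
    else:
        rec.update({"gamma": np.nan, "lambda": np.nan, "sigma": np.nan})
    return rec


def auc_over_grid(values: np.ndarray, grid: SparsityGrid) -> float:
    """Composite-trapezoid integral of a metric over the sparsity grid."""
    v = np.asarray(values, dtype=float)
    s = grid.values
    if v.shape != s.shape:
        raise ValueError("one value per grid point required")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite metric value")
    return float(np.trapezoid(v, s))


def dynamic_metric_variance(stack: WindowedFCStack,
                            grid: SparsityGrid | None = None,
                            n_null: int = 100, seed: int = 0,
                            compute_normalized: bool = True
                            ) -> dict[str, object]:
    """Per-window metric AUCs over the sparsity grid and their variance.

    For each window the symmetric z-matrix is rebuilt, binarized at every
    grid sparsity, the seven global metrics computed and integrated over the
    grid; the across-window variance (unbiased, n-1 denominator) of each
    metric's AUC summarizes topological fluctuation over the scan.
    """
    grid = grid or SparsityGrid()
    if stack.n_windows < 2:
        raise ValueError("need at least 2 windows")
    n = len(stack.network_labels)
    names = METRIC_NAMES if compute_normalized else METRIC_NAMES[:4]
    ss = np.random.SeedSequence(seed)
    win_seeds = [int(c.generate_state(1)[0] % (2 ** 31))
                 for c in ss.spawn(stack.n_windows)]
    aucs = {m: np.empty(stack.n_windows) for m in names}
    for wi in range(stack.n_windows):
        zmat = vec_to_matrix(stack.edge_values[wi], n)
        per_s = {m: np.empty(len(grid.values)) for m in names}
        for si, s in enumerate(grid.values):
            adj = binarize_sparsity(zmat, s)
            rec = all_metrics(adj, n_null=n_null,
                              seed=win_seeds[wi] + si,
                              compute_normalized=compute_normalized and adj.sum() > 0)
            for m in names:
                per_s[m][si] = rec[m]
        for m in names:
            vals = per_s[m]
            aucs[m][wi] = auc_over_grid(np.nan_to_num(vals, nan=1.0), grid) \
                if np.any(np.isnan(vals)) else auc_over_grid(vals, grid)
    variance = {m: float(np.var(aucs[m], ddof=1)) for m in names}
    return {"auc": aucs, "variance": variance, "grid": grid}
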