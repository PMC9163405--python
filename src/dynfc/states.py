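"""Connectivity-state decomposition of windowed FC and temporal metrics.

All subjects' windowed, Fisher-z edge vectors are pooled and clustered with
L1 (Manhattan) k-means: assignment minimizes cityblock distance and the
centroid update is the element-wise median, the L1-consistent estimator.
A two-pass scheme mirrors standard dFC practice: many random restarts pick
unbiased initial centroids, then a final pass reassigns every window from
those centroids to convergence.  Temporal occupancy of the resulting states
is summarized per subject as fractional windows, mean dwell time and number
of transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class TemporalMetrics:
    """Per-subject occupancy summary of a state-label sequence."""

    fractional_windows: np.ndarray  # per state, sums to 1
    mean_dwell: np.ndarray          # mean run length in windows, 0 if unvisited
    n_transitions: int              # adjacent label changes
    n_runs: np.ndarray = field(default=None)  # maximal runs per state

    def as_dict(self, prefix: str = "") -> dict:
        d = {}
        for s in range(len(self.fractional_windows)):
            d[f"{prefix}frac_state{s+1}"] = float(self.fractional_windows[s])
            d[f"{prefix}dwell_state{s+1}"] = float(self.mean_dwell[s])
        d[f"{prefix}n_transitions"] = int(self.n_transitions)
        return d


@dataclass
class StateModel:
    """Result of the pooled L1 k-means decomposition."""

    k: int
    centroids: np.ndarray                     # k x E, Fisher-z units
    assignments: dict[str, np.ndarray]        # subject_id -> window labels (1..k)
    objective: float                          # total L1 distance to assigned centroids
    replicate_seeds: list[int]

    def subject_metrics(self) -> dict[str, TemporalMetrics]:
        return {sid: temporal_metrics(lab, self.k)
                for sid, lab in self.assignments.items()}


# ---------------------------------------------------------------------------
# temporal metrics
# ---------------------------------------------------------------------------

def run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal-run decomposition: (run labels, run lengths)."""
    labels = np.asarray(labels)
    change = np.flatnonzero(labels[1:] != labels[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(labels)]))
    return labels[starts], ends - starts


def temporal_metrics(labels: np.ndarray, k: int) -> TemporalMetrics:
    """Fractional windows, mean dwell time and transition count.

    ``fractional_windows[s] = count(s)/n``; ``mean_dwell[s]`` is the mean
    length of maximal consecutive runs of state ``s`` (0 if never visited);
    ``n_transitions`` counts adjacent label changes.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError("label out of range 1..k")
    n = labels.size
    counts = np.bincount(labels, minlength=k + 1)[1:]
    frac = counts / n
    rl_labels, rl_lens = run_lengths(labels)
    dwell = np.zeros(k)
    nruns = np.zeros(k, dtype=np.int64)
    for s in range(1, k + 1):
        m = rl_labels == s
        nruns[s - 1] = m.sum()
        if m.any():
            dwell[s - 1] = rl_lens[m].mean()
    return TemporalMetrics(frac, dwell, int(len(rl_labels) - 1), nruns)


# ---------------------------------------------------------------------------
# L1 k-means
# ---------------------------------------------------------------------------

def _l1_assign(x: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, float]:
    d = cdist(x, centroids, metric="cityblock")
    lab = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
    obj = float(d[np.arange(len(x)), lab].sum())
    return lab, obj


def _kmeans_once(x: np.ndarray, k: int, rng: np.random.Generator,
                 max_iter: int = 100, tol: float = 0.0,
                 init: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    n = len(x)
    if init is None:
        centroids = x[rng.choice(n, size=k, replace=False)].copy()
    else:
        centroids = init.copy()
    prev_obj = np.inf
    lab, obj = _l1_assign(x, centroids)
    for _ in range(max_iter):
        for c in range(k):
            m = lab == c
            if m.any():
                centroids[c] = np.median(x[m], axis=0)
            else:
                # re-seed empty cluster from the window farthest from its centroid
                d = np.abs(x - centroids[lab]).sum(axis=1)
                centroids[c] = x[int(np.argmax(d))]
        lab, obj = _l1_assign(x, centroids)
        if prev_obj - obj <= tol:
            break
        prev_obj = obj
    return centroids, lab, obj


def kmeans_l1(all_windows: np.ndarray, k: int, n_replicates: int = 100,
              seed: int = 0, max_iter: int = 100,
              subject_slices: dict[str, slice] | None = None) -> StateModel:
    """Two-pass L1 k-means over pooled windowed FC vectors.

    Pass 1 runs k-means from ``n_replicates`` random initializations and
    keeps the solution with the lowest total L1 objective; pass 2 restarts
    from those centroids and reassigns all windows to convergence.  Empty
    clusters are re-seeded from the window farthest from its assigned
    centroid.  After the final fit, states are relabeled in order of
    descending total occupancy for stable reporting.
    """
    x = np.asarray(all_windows, dtype=float)
    if k > len(np.unique(x, axis=0)):
        raise ValueError("k exceeds the number of distinct windows")
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_replicates)]
    best = (None, None, np.inf)
    for rs in rep_seeds:
        rng = np.random.default_rng(rs)
        c, lab, obj = _kmeans_once(x, k, rng, max_iter=max_iter)
        if obj < best[2]:
            best = (c, lab, obj)
    # pass 2: final clustering from the best initial centroids
    rng = np.random.default_rng(rep_seeds[0] if rep_seeds else 0)
    centroids, lab, obj = _kmeans_once(x, k, rng, max_iter=max_iter, init=best[0])

    # stable state numbering: descending occupancy
    counts = np.bincount(lab, minlength=k)
    order = np.argsort(-counts, kind="stable")
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(k)
    centroids = centroids[order]
    lab = relabel[lab] + 1  # 1-based

    if subject_slices is None:
        assignments = {"pooled": lab}
    else:
        assignments = {sid: lab[sl] for sid, sl in subject_slices.items()}
    return StateModel(k=k, centroids=centroids, assignments=assignments,
                      objective=obj, replicate_seeds=rep_seeds)


def elbow_select_k(all_windows: np.ndarray, k_range=range(2, 11), seed: int = 0,
                   n_replicates: int = 5, max_iter: int = 60,
                   subsample: int | None = 6000) -> int:
    """Choose k by the elbow criterion.

    For each k the ratio of within-cluster to between-cluster L1 distance is
    computed; the returned k maximizes the curvature (second difference) of
    that ratio.  Large pooled window sets are deterministically subsampled
    (every m-th window) before scanning, and a small replicate count is used
    per k — the final clustering at the chosen k is re-run at full strength.
    """
    ks = sorted(set(int(k) for k in k_range))
    if len(ks) == 1:
        return ks[0]
    x = np.asarray(all_windows, dtype=float)
    if subsample is not None and len(x) > subsample:
        stride = int(np.ceil(len(x) / subsample))
        x = x[::stride]
    if len(np.unique(x, axis=0)) < max(ks):
        raise ValueError("degenerate pooled data: too few distinct windows")
    ratios = []
    ss = np.random.SeedSequence(seed)
    for k, child in zip(ks, ss.spawn(len(ks))):
        k_seed = int(child.generate_state(1)[0] % (2 ** 31))
        model = kmeans_l1(x, k, n_replicates=n_replicates, seed=k_seed,
                          max_iter=max_iter)
        d = cdist(x, model.centroids, metric="cityblock")
        lab = np.argmin(d, axis=1)
        within = d[np.arange(len(x)), lab].mean()
        other = np.ones_like(d, dtype=bool)
        other[np.arange(len(x)), lab] = False
        between = d[other].reshape(len(x), k - 1).mean()
        ratios.append(within / between)
    ratios = np.asarray(ratios)
    if len(ks) == 2:
        return ks[int(np.argmin(ratios))]
    curv = ratios[:-2] - 2 * ratios[1:-1] + ratios[2:]
    return ks[1 + int(np.argmax(curv))]


# ---------------------------------------------------------------------------
# centroids, matching, masks
# ---------------------------------------------------------------------------

def subject_state_centroid(stack: np.ndarray, assignments: np.ndarray,
                           k: int) -> list[np.ndarray | None]:
    """Element-wise median of a subject's windows per state (None if unvisited)."""
    out = []
    for s in range(1, k + 1):
        m = assignments == s
        out.append(np.median(stack[m], axis=0) if m.any() else None)
    return out


def group_state_centroid(subject_centroids: list[list[np.ndarray | None]],
                         k: int) -> list[np.ndarray | None]:
    """Element-wise mean over subjects with a non-missing centroid per state."""
    out = []
    for s in range(k):
        have = [sc[s] for sc in subject_centroids if sc[s] is not None]
        out.append(np.mean(have, axis=0) if have else None)
    return out


def match_states(centroids_a: np.ndarray, centroids_b: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Match states across runs by highest Pearson correlation of centroids.

    Returns (permutation, correlation matrix, is_bijection): ``perm[i]`` is
    the index in ``centroids_b`` best matching centroid ``i`` of ``a``.  The
    match is greedy per row; when two rows claim the same column the result
    is flagged as non-bijective.
    """
    a = np.atleast_2d(centroids_a)
    b = np.atleast_2d(centroids_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("edge dimension mismatch")
    if np.any(a.std(axis=1) == 0) or np.any(b.std(axis=1) == 0):
        raise ValueError("zero-variance centroid")
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    corr = az @ bz.T / a.shape[1]
    perm = np.argmax(corr, axis=1)
    bijection = len(set(perm.tolist())) == len(perm) and a.shape[0] == b.shape[0]
    return perm, corr, bijection


def top_fraction_edges(values: np.ndarray, fraction: float = 0.05
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Mask of the ceil(fraction*E) edges with largest |value|, sign preserved.

    Ties break toward the lower (fixed) edge index.  Returns (boolean mask,
    signed masked values).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    v = np.asarray(values, dtype=float)
    n_keep = int(np.ceil(fraction * v.size))
    # stable sort on (-|v|, index) keeps the lowest index on ties
    order = np.argsort(-np.abs(v), kind="stable")
    mask = np.zeros(v.size, dtype=bool)
    mask[order[:n_keep]] = True
    masked = np.where(mask, v, 0.0)
    return mask, masked
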