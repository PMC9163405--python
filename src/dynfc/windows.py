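"""Static and tapered sliding-window functional connectivity.

Static FC is the Fisher-z-transformed Pearson correlation over the whole
scan.  Dynamic FC slides a tapered window (rectangle convolved with a
Gaussian kernel) step-wise along the time courses; within each window a
weighted covariance is estimated, regularized with the graphical LASSO
(L1-penalized sparse inverse covariance), converted to a correlation
matrix, Fisher z-transformed and vectorized over the upper triangle.  The
L1 penalty is selected per subject by repeated random cross-validation over
windows.  Finally, edge z-values can be residualized across subjects
against nuisance covariates (age, sex, education, mean framewise
displacement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import convolve
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .simulate import TimeCourseMatrix

R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class TaperedWindowSpec:
    """Sliding-window geometry: length, Gaussian taper width, step.

    The default 22-TR window at TR = 2 s spans 44 s, in the 30-60 s range
    where sliding windows capture resting-state FC fluctuations.  Under the
    default ``n_minus_w`` counting convention a 170-timepoint scan yields
    148 windows.
    """

    window_length_tr: int = 22
    taper_sigma_tr: float = 3.0
    step_tr: int = 1
    count_convention: str = "n_minus_w"  # or "n_minus_w_plus_1"

    def __post_init__(self):
        if self.window_length_tr < 3:
            raise ValueError("window length must be >= 3 TR")
        if self.taper_sigma_tr <= 0:
            raise ValueError("taper sigma must be positive")
        if self.step_tr < 1:
            raise ValueError("step must be >= 1 TR")
        if self.count_convention not in ("n_minus_w", "n_minus_w_plus_1"):
            raise ValueError("unknown count convention")

    def n_windows(self, n_timepoints: int) -> int:
        if n_timepoints <= self.window_length_tr:
            raise ValueError("time series no longer than the window")
        span = n_timepoints - self.window_length_tr
        if self.count_convention == "n_minus_w_plus_1":
            span += 1
        return 1 + (span - 1) // self.step_tr

    def duration_s(self, tr: float) -> float:
        return self.window_length_tr * tr


@dataclass
class GlassoConfig:
    """Graphical-LASSO penalty grid and cross-validation settings."""

    penalty_grid: list[float] = field(default_factory=lambda: [0.0, 0.01, 0.03, 0.1])
    n_repeats: int = 50
    cv_fraction: float = 0.2
    max_iter: int = 200
    tol: float = 1e-4

    def __post_init__(self):
        grid = sorted(set(float(x) for x in self.penalty_grid))
        if not grid:
            raise ValueError("empty penalty grid")
        if any(x < 0 for x in grid):
            raise ValueError("penalties must be nonnegative")
        self.penalty_grid = grid
        if not (0 < self.cv_fraction < 1):
            raise ValueError("cv_fraction must lie in (0, 1)")


@dataclass
class WindowedFCStack:
    """Per-subject sequence of windowed Fisher-z edge vectors (windows x E)."""

    subject_id: str
    edge_values: np.ndarray
    network_labels: list[str]
    window_centers: np.ndarray
    selected_penalty: float = 0.0

    def __post_init__(self):
        n = len(self.network_labels)
        if self.edge_values.shape[1] != n * (n - 1) // 2:
            raise ValueError("edge count must be N(N-1)/2")
        if not np.all(np.isfinite(self.edge_values)):
            raise ValueError("non-finite edge values")

    @property
    def n_windows(self) -> int:
        return self.edge_values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_values.shape[1]


def edge_index(n: int) -> list[tuple[int, int]]:
    """Fixed upper-triangle row-major edge order: (0,1), (0,2), ..., (n-2,n-1)."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def vec_to_matrix(values: np.ndarray, n: int, diagonal: float = 0.0) -> np.ndarray:
    m = np.full((n, n), diagonal, dtype=float)
    iu = np.triu_indices(n, 1)
    m[iu] = values
    m[(iu[1], iu[0])] = values
    return m


def matrix_to_vec(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], 1)]


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def make_tapered_windows(n_timepoints: int, spec: TaperedWindowSpec
                         ) -> tuple[np.ndarray, list[slice]]:
    """Tapered weight vector and window placements.

    The weight vector is a length-W rectangle convolved ('same' mode) with a
    Gaussian kernel truncated at +/-4 sigma and normalized to sum 1; it is
    symmetric about the window center.  Returns (weights, placements).
    """
    W = spec.window_length_tr
    n_win = spec.n_windows(n_timepoints)
    half = int(np.ceil(4 * spec.taper_sigma_tr))
    t = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / spec.taper_sigma_tr) ** 2)
    kernel /= kernel.sum()
    weights = convolve(np.ones(W), kernel, mode="same")
    weights = np.maximum(weights, 0.0)
    weights /= weights.sum()
    placements = [slice(w * spec.step_tr, w * spec.step_tr + W) for w in range(n_win)]
    if placements[-1].stop > n_timepoints:
        raise ValueError("window placement exceeds series length")
    return weights, placements


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher r-to-z transform with clipping to keep z finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def static_fc(tc: TimeCourseMatrix) -> np.ndarray:
    """Whole-scan pairwise Pearson correlation as a Fisher-z matrix (diag 0)."""
    if tc.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    sd = tc.data.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [tc.network_labels[i] for i in bad]
        raise ValueError(f"constant network signal: {names}")
    r = np.corrcoef(tc.data, rowvar=False)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    return z


def weighted_window_covariance(data: np.ndarray, weights: np.ndarray,
                               placement: slice) -> np.ndarray:
    """Weighted sample covariance of one window segment.

    Sigma = sum_t w_t (x_t - mu)(x_t - mu)^T with mu the weighted mean and
    weights summing to 1; symmetric positive semidefinite by construction.
    """
    x = data[placement]
    w = np.asarray(weights, dtype=float)
    if x.shape[0] != w.size:
        raise ValueError("weights must match window length")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-10):
        raise ValueError("weights must be nonnegative and sum to 1")
    if np.max(w) > 1.0 - 1e-12:
        raise ValueError("degenerate weights: all mass on one timepoint")
    mu = w @ x
    d = x - mu
    cov = (d * w[:, None]).T @ d
    return 0.5 * (cov + cov.T)


# ---------------------------------------------------------------------------
# graphical lasso
# ---------------------------------------------------------------------------

def graphical_lasso(cov: np.ndarray, penalty: float, max_iter: int = 200,
                    tol: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """L1-penalized sparse inverse covariance (regularized cov, precision).

    The precision maximizes ``log det T - tr(S T) - penalty * ||T||_1`` with
    the L1 norm over off-diagonal entries.  ``penalty=0`` is the unpenalized
    Gaussian MLE, i.e. the matrix inverse of S.
    """
    s = np.asarray(cov, dtype=float)
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    if np.any(np.diag(s) <= 0):
        raise ValueError("covariance diagonal must be positive")
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    if penalty == 0.0:
        precision = np.linalg.inv(s)
        return s.copy(), 0.5 * (precision + precision.T)
    try:
        with warnings.catch_warnings():
            # near-converged fits (dual gap ~ tol) are acceptable here
            warnings.simplefilter("ignore", ConvergenceWarning)
            w, theta = _sk_graphical_lasso(s, alpha=penalty, max_iter=max_iter,
                                           tol=tol)
    except FloatingPointError as exc:  # pragma: no cover
        raise RuntimeError(f"graphical lasso failed to converge: {exc}") from exc
    return w, theta


def _gaussian_loglik(test_cov: np.ndarray, precision: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.trace(test_cov @ precision))


def select_penalty(window_covs: np.ndarray, cfg: GlassoConfig, seed: int = 0
                   ) -> float:
    """Pick the glasso penalty by repeated random cross-validation.

    For each of ``n_repeats`` random splits of the windows, the mean training
    covariance is fitted at every grid penalty and scored by Gaussian
    log-likelihood against the mean held-out covariance; the penalty with the
    best mean score wins.  Deterministic given the seed.
    """
    covs = np.asarray(window_covs)
    n = covs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 windows for cross-validation")
    grid = cfg.penalty_grid
    if len(grid) == 1:
        return grid[0]
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(cfg.cv_fraction * n)))
    scores = np.zeros(len(grid))
    for _ in range(cfg.n_repeats):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        s_train = covs[train].mean(axis=0)
        s_test = covs[test].mean(axis=0)
        for gi, lam in enumerate(grid):
            try:
                _, theta = graphical_lasso(s_train, lam, cfg.max_iter, cfg.tol)
            except (RuntimeError, np.linalg.LinAlgError):
                scores[gi] += -np.inf
                continue
            scores[gi] += _gaussian_loglik(s_test, theta)
    return grid[int(np.argmax(scores))]


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def dynamic_fc(tc: TimeCourseMatrix, wspec: TaperedWindowSpec | None = None,
               gcfg: GlassoConfig | None = None, seed: int = 0) -> WindowedFCStack:
    """Windowed, regularized, Fisher-z functional connectivity for one subject.

    Per window: tapered weighted covariance -> graphical LASSO at the
    subject-level cross-validated penalty -> correlation from the regularized
    covariance -> Fisher z -> upper-triangle edge vector.
    """
    wspec = wspec or TaperedWindowSpec()
    gcfg = gcfg or GlassoConfig()
    weights, placements = make_tapered_windows(tc.n_timepoints, wspec)
    covs = np.stack([weighted_window_covariance(tc.data, weights, p)
                     for p in placements])
    # regularize toward the diagonal slightly so short-window covariances are invertible
    jitter = 1e-8 * np.trace(covs.mean(axis=0)) / tc.n_networks
    covs += jitter * np.eye(tc.n_networks)
    lam = select_penalty(covs, gcfg, seed=seed)
    z = np.empty((len(placements), tc.n_networks * (tc.n_networks - 1) // 2))
    for wi, s in enumerate(covs):
        w_reg, _ = graphical_lasso(s, lam, gcfg.max_iter, gcfg.tol)
        r = _cov_to_corr(w_reg)
        z[wi] = fisher_z(matrix_to_vec(r))
    centers = np.array([(p.start + p.stop - 1) / 2.0 for p in placements])
    return WindowedFCStack(tc.subject_id, z, list(tc.network_labels), centers,
                           selected_penalty=lam)


# ---------------------------------------------------------------------------
# covariate residualization
# ---------------------------------------------------------------------------

def residualize_covariates(stacks: list[WindowedFCStack], covariates: pd.DataFrame,
                           columns: tuple[str, ...] = ("age", "sex", "education",
                                                       "mean_fd")
                           ) -> list[WindowedFCStack]:
    """Residualize every (window, edge) cell across subjects on covariates.

    Covariates are z-scored, the across-subject least-squares fit removed
    cell-wise, and the grand intercept added back.  Residuals are orthogonal
    to each centered covariate.  Requires one covariate row per subject
    (matched on subject_id) and equal stack shapes.
    """
    ids = [s.subject_id for s in stacks]
    cov = covariates.set_index("subject_id").loc[ids, list(columns)]
    if cov.isna().any().any():
        missing = cov.columns[cov.isna().any()].tolist()
        raise ValueError(f"missing covariate values in {missing}")
    x = cov.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        design = np.ones((len(ids), 1))
    else:
        design = np.column_stack([np.ones(len(ids)), (x - x.mean(axis=0)) / sd])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    shapes = {s.edge_values.shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError("all subjects must share the window/edge grid")
    y = np.stack([s.edge_values.ravel() for s in stacks])  # subjects x (win*E)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef + coef[0]  # keep the grand intercept
    out = []
    for s, row in zip(stacks, resid):
        out.append(WindowedFCStack(s.subject_id,
                                   row.reshape(s.edge_values.shape),
                                   s.network_labels, s.window_centers,
                                   s.selected_penalty))
    return out
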