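"""Group comparison and brain-behavior correlation statistics.

Temporal and graph-dynamics measures are compared across groups with
Kruskal-Wallis tests; state-specific edge strengths with ANCOVA (partial
F-test of the group factor over nuisance covariates).  Multiple comparisons
are controlled with Benjamini-Hochberg FDR, both for the omnibus families
and for the FDR-corrected post hoc pairwise tests.  Associations between
dynamic measures and cognition are estimated with covariate-adjusted
two-tailed partial correlations.

Disease duration is undefined for healthy controls yet is listed among the
nuisance covariates; by default it is imputed as 0 for controls after
centering within patients (configurable to drop the covariate entirely).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_COVARIATES = ("age", "sex", "education", "disease_duration", "mean_fd")


@dataclass
class StatsResult:
    test: str
    comparison: str
    statistic: float
    p: float
    q: float | None = None
    n: int | None = None
    estimate: float | None = None

    def as_row(self) -> dict:
        return {"test": self.test, "comparison": self.comparison,
                "statistic": self.statistic, "p": self.p, "q": self.q,
                "n": self.n, "estimate": self.estimate}


def kruskal_wallis(*samples: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(s, float) for s in samples])
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical; H undefined")
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def encode_covariates(cov: pd.DataFrame,
                      columns: tuple[str, ...] = DEFAULT_COVARIATES,
                      disease_duration_mode: str = "impute_centered"
                      ) -> np.ndarray:
    """Numeric covariate matrix with the documented disease-duration handling.

    ``impute_centered``: center disease duration within subjects that have a
    value, set it to 0 where undefined (controls).  ``drop``: omit it.
    """
    cols = list(columns)
    x = []
    for c in cols:
        if c == "disease_duration":
            if disease_duration_mode == "drop":
                continue
            v = cov[c].to_numpy(dtype=float)
            have = np.isfinite(v)
            v = v - (v[have].mean() if have.any() else 0.0)
            v[~have] = 0.0
            x.append(v)
        else:
            v = cov[c].to_numpy(dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"missing values in covariate {c}")
            x.append(v)
    return np.column_stack(x) if x else np.empty((len(cov), 0))


def _ols_rss(design: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), design.shape[1]


def ancova(values: np.ndarray, groups: np.ndarray,
           covariates: np.ndarray | None = None) -> tuple[float, float]:
    """Partial F-test of the group factor adjusting for covariates.

    Compares the full linear model (group indicators + covariates) with the
    covariates-only model: F = ((RSS0 - RSS1)/df_num) / (RSS1/df_den).  With
    no covariate effect this reduces to the one-way ANOVA F.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    n = len(y)
    g_dummies = np.column_stack([(groups == lab).astype(float)
                                 for lab in labels[1:]])
    cov = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    x0 = np.column_stack([np.ones(n), cov])
    x1 = np.column_stack([x0, g_dummies])
    if np.linalg.matrix_rank(x1) < x1.shape[1]:
        raise ValueError("rank-deficient ANCOVA design")
    rss0, p0 = _ols_rss(x0, y)
    rss1, p1 = _ols_rss(x1, y)
    df_num = p1 - p0
    df_den = n - p1
    if df_den <= 0:
        raise ValueError("insufficient degrees of freedom")
    if rss1 <= 0:
        return np.inf, 0.0
    f = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    p = float(sps.f.sf(f, df_num, df_den))
    return float(f), p


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q-values, rejection mask at q < alpha)."""
    p = np.asarray(p_values, dtype=float)
    if not np.all(np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha


def posthoc_pairwise(values: np.ndarray, groups: np.ndarray,
                     covariates: np.ndarray | None = None,
                     omnibus: str = "kruskal") -> pd.DataFrame:
    """FDR-corrected pairwise tests following a significant omnibus test.

    After Kruskal-Wallis the pairwise test is the Wilcoxon rank-sum; after
    ANCOVA it is the two-group partial-F contrast with the same covariates.
    The BH-FDR family is the set of pairwise contrasts.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    rows = []
    for a, b in combinations(labels, 2):
        ma, mb = groups == a, groups == b
        if omnibus == "kruskal":
            stat, p = sps.ranksums(y[ma], y[mb])
        elif omnibus == "ancova":
            mask = ma | mb
            cov = covariates[mask] if covariates is not None else None
            stat, p = ancova(y[mask], groups[mask], cov)
        else:
            raise ValueError("omnibus must be 'kruskal' or 'ancova'")
        rows.append({"comparison": f"{a}_vs_{b}", "statistic": float(stat),
                     "p": float(p), "n": int(ma.sum() + mb.sum())})
    out = pd.DataFrame(rows)
    out["q"], out["reject"] = fdr_bh(out["p"].to_numpy())
    return out


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None = None
                        ) -> tuple[float, float]:
    """Two-tailed partial Pearson correlation controlling for covariates.

    r is the Pearson correlation of the residuals of x and y on
    [intercept | covariates]; the p-value comes from the t-distribution with
    n - n_covariates - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    cov = np.empty((n, 0)) if covariates is None else np.atleast_2d(
        np.asarray(covariates, float))
    if cov.shape[0] != n:
        cov = cov.T
    p_cov = cov.shape[1]
    if n <= p_cov + 2:
        raise ValueError("insufficient degrees of freedom")
    design = np.column_stack([np.ones(n), cov])
    bx, *_ = np.linalg.lstsq(design, x, rcond=None)
    by, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx, ry = x - design @ bx, y - design @ by
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    if sx == 0 or sy == 0:
        raise ValueError("zero residual variance")
    r = float((rx @ ry) / (sx * sy))
    df = n - p_cov - 2
    r_ = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_ * np.sqrt(df / (1 - r_ ** 2))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


def group_measure_tests(measures: pd.DataFrame, group_col: str = "group",
                        measure_cols: list[str] | None = None) -> pd.DataFrame:
    """Kruskal-Wallis per measure with BH-FDR over the measure family."""
    if measure_cols is None:
        measure_cols = [c for c in measures.columns if c != group_col]
    groups = measures[group_col].to_numpy()
    labels = list(pd.unique(groups))
    rows = []
    for c in measure_cols:
        y = measures[c].to_numpy(dtype=float)
        samples = [y[groups == lab] for lab in labels]
        try:
            h, p = kruskal_wallis(*samples)
        except ValueError:
            h, p = np.nan, 1.0
        rows.append({"measure": c, "statistic": h, "p": p,
                     "n": len(y)})
    out = pd.DataFrame(rows)
    out["q"], out["reject"] = fdr_bh(out["p"].to_numpy())
    return out
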