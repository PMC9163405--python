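"""Model-style front end: fit the whole dynamic-FC analysis to a cohort.

``DynamicFC`` holds the cohort (per-subject network time courses and the
covariate table) plus a validated ``RunConfig``; ``fit()`` runs
preprocessing, tapered sliding-window regularized FC, covariate
residualization, pooled L1 k-means state decomposition, temporal metrics,
graph-dynamics variance and the group-statistics layer, returning a
``DynamicFCResults`` that carries the estimates and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import graphmetrics, inference, preprocess, states, windows
from .config import RunConfig
from .simulate import TimeCourseMatrix


@dataclass
class DynamicFCResults:
    """Fitted dynamic-FC decomposition of one cohort."""

    config: RunConfig
    state_model: states.StateModel
    stacks: list[windows.WindowedFCStack]
    temporal: pd.DataFrame                 # one row per subject
    metric_variance: pd.DataFrame | None   # subject x metric AUC variance
    temporal_tests: pd.DataFrame | None
    variance_tests: pd.DataFrame | None
    edge_tests: dict[int, pd.DataFrame] = field(default_factory=dict)
    selected_k: int = 0

    @property
    def centroids(self) -> np.ndarray:
        return self.state_model.centroids

    def fractional_occupancy(self) -> np.ndarray:
        """Pooled fraction of all windows spent in each state."""
        all_lab = np.concatenate(list(self.state_model.assignments.values()))
        return np.bincount(all_lab, minlength=self.selected_k + 1)[1:] / all_lab.size

    def summary(self) -> str:
        lines = []
        k = self.selected_k
        lines.append("Dynamic functional connectivity decomposition")
        lines.append("=" * 54)
        n_sub = len(self.state_model.assignments)
        n_win = next(iter(self.state_model.assignments.values())).size
        lines.append(f"subjects: {n_sub}    windows/subject: {n_win}    states: {k}")
        occ = self.fractional_occupancy()
        lines.append("pooled occupancy: " + "  ".join(
            f"S{s+1} {100*occ[s]:.1f}%" for s in range(k)))
        lines.append(f"k-means objective (total L1): {self.state_model.objective:.1f}")
        lines.append("")
        lines.append("group medians of temporal metrics")
        med = self.temporal.groupby("group").median(numeric_only=True)
        lines.append(med.round(3).to_string())
        if self.temporal_tests is not None:
            lines.append("")
            lines.append("Kruskal-Wallis on temporal metrics (BH-FDR)")
            lines.append(self.temporal_tests.round(4).to_string(index=False))
        if self.variance_tests is not None:
            lines.append("")
            lines.append("Kruskal-Wallis on graph-metric AUC variance (BH-FDR)")
            lines.append(self.variance_tests.round(4).to_string(index=False))
        return "\n".join(lines)


class DynamicFC:
    """Dynamic functional-connectivity model for a cohort of subjects."""

    def __init__(self, timecourses: list[TimeCourseMatrix],
                 covariates: pd.DataFrame, config: RunConfig | None = None):
        if not timecourses:
            raise ValueError("empty cohort")
        ids = {tc.subject_id for tc in timecourses}
        table_ids = set(covariates["subject_id"])
        if ids - table_ids:
            raise ValueError(f"subjects missing from covariate table: {sorted(ids - table_ids)[:3]}")
        # subject order is fixed by the covariate table, never by input order
        order = {sid: i for i, sid in enumerate(covariates["subject_id"])}
        self.timecourses = sorted((tc for tc in timecourses),
                                  key=lambda tc: order[tc.subject_id])
        self.covariates = covariates.reset_index(drop=True)
        self.config = config or RunConfig()

    @classmethod
    def from_cohort(cls, cohort: tuple, config: RunConfig | None = None) -> "DynamicFC":
        """Build from the (timecourses, covariates, ground_truths) tuple of simulate_cohort."""
        tcs, cov, _ = cohort
        return cls(tcs, cov, config)

    # -- pipeline stages -----------------------------------------------------

    def _dfc_stacks(self, run_preprocess: bool, seed: int
                    ) -> list[windows.WindowedFCStack]:
        cfg = self.config
        wspec, gcfg = cfg.window_spec(), cfg.glasso_config()
        ss = np.random.SeedSequence(seed)
        stacks = []
        for tc, child in zip(self.timecourses, ss.spawn(len(self.timecourses))):
            if run_preprocess:
                tc = preprocess.preprocess_pipeline(tc)
            sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
            stacks.append(windows.dynamic_fc(tc, wspec, gcfg, seed=sub_seed))
        return stacks

    def fit(self, seed: int | None = None, run_preprocess: bool = True,
            residualize: bool = True, compute_graph: bool = True,
            run_stats: bool = True) -> DynamicFCResults:
        """Run the full decomposition and return the fitted results."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        stacks = self._dfc_stacks(run_preprocess, seed)
        if residualize:
            stacks = windows.residualize_covariates(stacks, self.covariates,
                                                    cfg.covariate_columns)
        pooled = np.concatenate([s.edge_values for s in stacks])
        slices, start = {}, 0
        for s in stacks:
            slices[s.subject_id] = slice(start, start + s.n_windows)
            start += s.n_windows

        if cfg.k is None:
            k = states.elbow_select_k(pooled, range(cfg.k_range[0], cfg.k_range[1] + 1),
                                      seed=seed)
        else:
            k = cfg.k
        sm = states.kmeans_l1(pooled, k, n_replicates=cfg.n_replicates,
                              seed=seed, subject_slices=slices)

        metrics = sm.subject_metrics()
        rows = []
        for sid, tm in metrics.items():
            row = {"subject_id": sid, **tm.as_dict()}
            rows.append(row)
        temporal = pd.DataFrame(rows).merge(
            self.covariates[["subject_id", "group"]], on="subject_id")

        metric_variance = None
        if compute_graph:
            grid = cfg.sparsity_grid()
            vr = []
            ss = np.random.SeedSequence(seed + 1)
            for s, child in zip(stacks, ss.spawn(len(stacks))):
                res = graphmetrics.dynamic_metric_variance(
                    s, grid, n_null=cfg.n_null,
                    seed=int(child.generate_state(1)[0] % (2 ** 31)),
                    compute_normalized=cfg.compute_normalized)
                vr.append({"subject_id": s.subject_id,
                           **{f"var_{m}": v for m, v in res["variance"].items()}})
            metric_variance = pd.DataFrame(vr).merge(
                self.covariates[["subject_id", "group"]], on="subject_id")

        temporal_tests = variance_tests = None
        edge_tests: dict[int, pd.DataFrame] = {}
        if run_stats:
            tcols = [c for c in temporal.columns if c not in ("subject_id", "group")]
            temporal_tests = inference.group_measure_tests(
                temporal[["group"] + tcols], measure_cols=tcols)
            if metric_variance is not None:
                vcols = [c for c in metric_variance.columns
                         if c.startswith("var_")
                         and np.isfinite(metric_variance[c]).all()]
                variance_tests = inference.group_measure_tests(
                    metric_variance[["group"] + vcols], measure_cols=vcols)
            edge_tests = self._edgewise_ancova(stacks, sm, k)

        return DynamicFCResults(cfg, sm, stacks, temporal, metric_variance,
                                temporal_tests, variance_tests, edge_tests,
                                selected_k=k)

    def _edgewise_ancova(self, stacks, sm: states.StateModel, k: int
                         ) -> dict[int, pd.DataFrame]:
        """Per-state edgewise ANCOVA on subject state centroids (BH-FDR per state)."""
        cfg = self.config
        cov = self.covariates.set_index("subject_id")
        xcov = inference.encode_covariates(
            self.covariates, cfg.stats_covariates, cfg.disease_duration_mode)
        xcov_by_id = {sid: xcov[i] for i, sid in enumerate(self.covariates["subject_id"])}
        results = {}
        for state in range(1, k + 1):
            vals, grp, xs = [], [], []
            for s in stacks:
                lab = sm.assignments[s.subject_id]
                cent = states.subject_state_centroid(s.edge_values, lab, k)[state - 1]
                if cent is None:
                    continue
                vals.append(cent)
                grp.append(cov.loc[s.subject_id, "group"])
                xs.append(xcov_by_id[s.subject_id])
            if len(set(grp)) < 2 or len(vals) < 8:
                continue
            vals = np.asarray(vals)
            grp = np.asarray(grp)
            xs = np.asarray(xs)
            rows = []
            for e in range(vals.shape[1]):
                try:
                    f, p = inference.ancova(vals[:, e], grp, xs)
                except ValueError:
                    f, p = np.nan, 1.0
                rows.append({"edge": e, "F": f, "p": p})
            df = pd.DataFrame(rows)
            df["q"], df["reject"] = inference.fdr_bh(df["p"].to_numpy())
            results[state] = df
        return results
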