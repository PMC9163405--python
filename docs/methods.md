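# Methods

This note documents what `dynfc` computes, the default parameter choices and
their rationale, the scope of the synthetic cohort generator, the numerical
choices that affect results, and the package's limitations.

## Model

`dynfc` implements a dynamic functional-connectivity (dFC) state analysis for
cohorts of subjects, each represented by a `timepoints x networks` matrix of
resting-state network time courses (14 named networks by default). The
pipeline has six stages, exposed individually as library modules and jointly
through the `DynamicFC` model object and the `dynfc` CLI:

1. **Postprocessing** (`dynfc.preprocess`). Per subject: joint polynomial
   detrending up to cubic order on a Legendre basis; running-median/MAD
   despiking (samples deviating from an 11-sample running median by more
   than 4 local MADs are clipped to the threshold boundary); optional
   least-squares regression of nuisance confounds (e.g., six motion
   parameters); zero-phase 5th-order Butterworth low-pass at 0.15 Hz.
2. **Tapered sliding-window FC** (`dynfc.windows`). A rectangle of
   `W = 22` TR convolved with a Gaussian of `sigma = 3` TR (truncated at
   ±4 sigma, normalized to sum 1) slides in steps of 1 TR. Within each
   window a weighted covariance is estimated and regularized with the
   graphical LASSO; the penalty is selected per subject by repeated (50x)
   random cross-validation over windows, scoring held-out Gaussian
   log-likelihood on a small grid (0, 0.01, 0.03, 0.1). The regularized
   covariance is converted to a correlation matrix, Fisher z-transformed
   (`atanh`, r clipped at 1 − 1e−7), and vectorized over the 91 upper-triangle
   edges. A 170-timepoint scan yields 148 windows under the `n_minus_w`
   counting convention. Edge values are then residualized across subjects on
   z-scored age, sex, education and mean framewise displacement, per
   (window, edge) cell, with the grand intercept restored.
3. **State decomposition** (`dynfc.states`). All subjects' windows are pooled
   and clustered with L1 (Manhattan) k-means: cityblock assignment,
   element-wise median centroid update, empty clusters re-seeded from the
   farthest window. Two passes: 100 random-start replicates keep the best
   objective, then a final pass reassigns all windows from those centroids.
   States are relabeled by descending occupancy. `k` defaults to 4; the
   elbow criterion (maximum curvature of the within/between L1 distance
   ratio over k = 2..10) is available for data-driven selection.
4. **Temporal metrics** (`dynfc.states`). Per subject: fractional windows per
   state, mean dwell time (mean maximal-run length, 0 if unvisited), and
   number of transitions (adjacent label changes).
5. **Graph dynamics** (`dynfc.graphmetrics`). Each windowed z-matrix is
   binarized by keeping the `round(S * 91)` strongest positive edges at
   sparsities S = 0.20..0.30 (step 0.01). On each graph: global efficiency,
   local efficiency, clustering coefficient, characteristic path length
   (connected pairs only), and gamma/lambda/sigma against Maslov–Sneppen
   degree-preserving rewired nulls (10·|E| attempted swaps, 100 nulls).
   Each metric is integrated over the sparsity grid (trapezoid AUC); the
   across-window variance (ddof = 1) of the AUC indexes topological
   fluctuation over the scan.
6. **Statistics** (`dynfc.inference`). Group comparisons of temporal and
   variance measures use tie-corrected Kruskal–Wallis tests with
   Benjamini–Hochberg FDR over each measure family; state-specific edge
   strengths (subject state centroids) use edgewise ANCOVA (partial F of
   the group factor over covariates) with BH-FDR per state; post hoc
   pairwise contrasts are rank-sum (or pairwise ANCOVA) with BH-FDR over
   the pairwise family. Brain–behavior associations use residual-based
   partial Pearson correlations (t-test, df = n − p − 2).

## Parameter defaults and rationale

| Parameter | Default | Rationale |
| --- | --- | --- |
| Window length | 22 TR (44 s at TR = 2 s) | inside the 30–60 s band where sliding windows resolve resting-state FC fluctuation without starving the covariance estimate |
| Taper sigma | 3 TR | smooths window edges so single extreme volumes enter/leave gradually |
| Step | 1 TR | maximal temporal resolution of the state sequence |
| Glasso grid | 0, 0.01, 0.03, 0.1 | spans unpenalized to strongly sparse; CV picks per subject |
| k-means replicates | 100 | empirically sufficient for a stable global optimum of the L1 objective at this problem size |
| Sparsity grid | 0.20–0.30, step 0.01 | densities where 14-node graphs are connected but not saturated; AUC removes single-threshold dependence |
| Nulls per graph | 100 | normalization denominators stable to ~1% |
| Low-pass cutoff | 0.15 Hz | retains the resting-state band, removes high-frequency noise |

## Synthetic cohort generator: scope

`dynfc.simulate` generates cohorts from a hidden Markov chain over `k = 4`
covariance-defined states. Each state is a unit-diagonal SPD correlation
matrix built from block designs over the 14 networks; infeasible designs
are repaired by eigenvalue clipping (floor 1e−6) with iterated
unit-diagonal rescaling. The four default states are contrasting
topological archetypes: states 1 (sensory clique + DMN triangle), 2
(fronto-parietal attention + salience-language + visual-sensorimotor
cliques) and 4 (precuneus-visual, executive-language and salience cliques)
place a modest number of strong edges in mutually detached modules, while
state 3 — the patient-sticky state — couples a strong DMN+language clique
to a dense connected scaffold spanning all systems. The three groups
(`HD` n = 50, `NonD` n = 50, `HC` n = 64 by default) differ in transition
matrices — stay probabilities 0.955 (HC), 0.972 (NonD), 0.984 (HD), plus
extra stickiness of state 3 for patients — and in multiplicative
weakening of DMN edges in state 3 (NonD x0.6, HD x0.35, SPD-repaired).
Observations are Gaussian draws from the active state's covariance, smoothed
by a variance-preserving AR(1) filter (phi = 0.25) and white noise
(sd = 0.1). Cognition scores are linear in the subject's true state-3 dwell
time and transition count plus Gaussian noise; covariates (age, sex,
education, mean FD, disease duration for patients only) are drawn per group.
Per-subject seeds come from a spawned `SeedSequence` (all < 2^31).

The generator is a study harness, not a biophysical model: it produces data
whose ground-truth state sequence, temporal metrics and group gradient are
known exactly, so recovery can be scored. Default block strengths are
calibrated so the pooled windowed-FC states satisfy an L1 centroid
separation of at least 5x the within-state spread, where spread is the
standard deviation of window-to-own-centroid L1 distances — the scale that
governs L1 assignment errors (the mean distance is an offset common to all
centroids). The topological contrast between states also injects a
topology-fluctuation gradient: windows spent in the fragmented states have
noisier binarized topology (which noise edges bridge the detached modules
varies window to window) and different mean efficiencies than windows in
the stable, densely scaffolded state 3, so subjects locked into state 3
(dialysis patients) show lower across-window variance of the efficiency
AUCs than frequent switchers (controls), through both the within-state
and the between-state channel.

## Numerical choices

- **Windowed covariance**: weighted two-pass formula with weights summing
  to 1; a jitter of 1e−8 x mean-trace/N on the diagonal keeps short-window
  covariances invertible at lambda = 0.
- **Graphical LASSO**: sklearn coordinate-descent solver, tol 1e−4,
  max_iter 200; lambda = 0 short-circuits to the exact matrix inverse.
- **Shortest paths**: dense boolean-matrix-power BFS ((A^k)_{ij} > 0 iff a
  length-k walk exists); exact for unweighted graphs and ~10x faster than
  sparse-graph routines at N = 14. Verified against brute-force BFS on all
  graphs with N ≤ 5 and random N = 14 graphs.
- **Elbow scans** deterministically subsample the pooled windows (every
  m-th window, at most 6000) and use 5 replicates per k; the final
  clustering at the chosen k runs the full two-pass 100-replicate scheme.
- **Ties**: k-means assignment and binarization ties break toward the lower
  index; majority votes over ground-truth windows break toward the lower
  state label. All stochastic steps take explicit seeds; derived seeds are
  spawned `SeedSequence` children reduced mod 2^31.
- **Fisher z** clips |r| at 1 − 1e−7 so z stays finite.

## Limitations

- The generator's states are piecewise-stationary Gaussian; real dFC has
  richer non-Gaussian and non-Markov structure, so recovery scores here are
  upper bounds on what identical settings would achieve on empirical data.
- Sliding-window FC has a known resolution/stability trade-off; the 22-TR
  default follows common practice but is not optimized per dataset. The
  `val20`/`val30` presets exist for window-length robustness checks.
- The elbow criterion on subsampled windows is a heuristic; with weak state
  separation it can return neighboring k.
- Edgewise ANCOVA on subject state centroids requires a state to be visited;
  subjects who never enter a state drop out of that state's family, which
  can bias centroid comparisons when occupancy differs by group.
- gamma/lambda/sigma are unstable on near-empty or fragmented graphs; the
  AUC step fills such windows with 1.0 (the null expectation) when
  normalization is skipped, and the sparsity grid is chosen to make this
  rare.
- No empirical claims are made about patient populations; all quantitative
  statements in the README derive from the synthetic cohort and are
  reproducible from the commands shown there.
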