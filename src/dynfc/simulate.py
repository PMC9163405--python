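"""Synthetic cohorts of network time courses with known hidden-state structure.

The generative model is a per-timepoint hidden Markov chain over a small set
of full covariance matrices ("connectivity states").  At each TR the active
state's covariance shapes a multivariate normal draw; an AR(1) filter adds
temporal smoothness and isotropic noise models residual measurement error.
Group membership selects the transition matrix and optional edge-weakening
effects, so group differences in dwell time, transition rate and state-specific
connectivity are injected with known ground truth.

Cognitive scores are generated with a configurable linear dependence on each
subject's true transition count and state-3 dwell time, so the correlation
stage downstream has a recoverable signal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .states import TemporalMetrics, temporal_metrics

GROUPS = ("HD", "NonD", "HC")

#: Canonical resting-state network labels used throughout the package.
NETWORK_LABELS = [
    "dDMN", "vDMN", "PRE", "AN", "DAN", "pVN", "hVN",
    "SMN", "aSN", "pSN", "RECN", "LECN", "LAN", "BG",
]

_EPS_SPD = 1e-6


# ---------------------------------------------------------------------------
# block designs for the default four states
# ---------------------------------------------------------------------------

def _idx(label: str) -> int:
    return NETWORK_LABELS.index(label)


def default_block_designs() -> list[dict[tuple[int, int], float]]:
    """Block designs for the four default connectivity states.

    Each design maps network pairs to signed correlation strengths.  The
    four states are contrasting topological archetypes, so states differ
    both in edge space (for clustering separation) and in binarized graph
    topology and its window-to-window stability (for the topology-
    fluctuation gradient): states 1, 2 and 4 carry relatively few strong
    edges in fragmented module/hub layouts, so their binarized graphs are
    sensitive to which noise edges enter at a given sparsity; state 3 -- the
    patient-sticky DMN-core state -- carries a dense connected scaffold of
    ~27 strong edges whose binarization is nearly deterministic over the
    whole sparsity grid.  Subjects locked into state 3 therefore fluctuate
    least, and frequent switchers fluctuate most, through both the
    between-state and the within-state channel.
    """
    def block(pairs, strength):
        return {tuple(sorted((_idx(a), _idx(b)))): strength for a, b in pairs}

    # state 1: sensory-dominated baseline -- one large sensory clique plus a
    # DMN triangle, everything else disconnected
    s1 = {}
    s1.update(block([("pVN", "hVN")], 0.6))
    s1.update(block([("DAN", "SMN")], 0.55))
    s1.update(block([("DAN", "hVN"), ("SMN", "hVN"), ("BG", "SMN")], 0.5))
    s1.update(block([("pVN", "DAN"), ("pVN", "SMN"), ("AN", "hVN"),
                     ("AN", "SMN"), ("BG", "DAN")], 0.45))
    s1.update(block([("AN", "pVN"), ("AN", "DAN"), ("BG", "pVN"),
                     ("BG", "hVN"), ("AN", "BG")], 0.4))
    s1.update(block([("dDMN", "vDMN"), ("dDMN", "PRE"), ("vDMN", "PRE")],
                    0.45))
    s1.update(block([("vDMN", "DAN")], -0.35))

    # state 2: attention-salience state -- fronto-parietal attention,
    # salience-language and posterior cliques, detached from each other
    s2 = {}
    s2.update(block([("DAN", "AN"), ("DAN", "pVN"), ("DAN", "PRE"),
                     ("DAN", "LAN")], 0.55))
    s2.update(block([("AN", "pVN"), ("AN", "PRE"), ("pVN", "PRE"),
                     ("AN", "LAN"), ("pVN", "LAN"), ("PRE", "LAN")], 0.5))
    s2.update(block([("aSN", "pSN"), ("aSN", "LECN"), ("pSN", "LECN")], 0.55))
    s2.update(block([("hVN", "SMN")], 0.55))
    s2.update(block([("SMN", "pSN")], -0.45))
    s2.update(block([("dDMN", "LECN")], -0.4))

    # state 3: DMN-core dominated, globally integrated state -- a strong
    # DMN+language clique with a connected scaffold spanning all systems;
    # the patient-sticky state
    s3 = {}
    s3.update(block([("dDMN", "vDMN")], 0.7))
    s3.update(block([("dDMN", "PRE"), ("vDMN", "PRE")], 0.65))
    s3.update(block([("dDMN", "LAN")], 0.6))
    s3.update(block([("vDMN", "LAN")], 0.55))
    s3.update(block([("PRE", "LAN"), ("dDMN", "RECN")], 0.5))
    s3.update(block([("vDMN", "RECN"), ("PRE", "RECN"), ("LAN", "RECN")],
                    0.45))
    s3.update(block([("RECN", "LECN")], 0.55))
    s3.update(block([("LECN", "aSN"), ("aSN", "AN"), ("aSN", "pSN"),
                     ("AN", "pSN")], 0.5))
    s3.update(block([("pSN", "BG"), ("LAN", "hVN"), ("PRE", "DAN"),
                     ("vDMN", "SMN"), ("pVN", "vDMN"), ("BG", "LECN"),
                     ("AN", "LECN")], 0.45))
    s3.update(block([("hVN", "pVN")], 0.5))
    s3.update(block([("DAN", "BG")], 0.4))
    s3.update(block([("pVN", "LAN")], 0.4))
    s3.update(block([("dDMN", "pSN")], -0.45))

    # state 4: precuneus-visual state -- precuneus-visual,
    # executive-language-sensorimotor and salience cliques, detached
    s4 = {}
    s4.update(block([("PRE", "vDMN"), ("PRE", "pVN")], 0.6))
    s4.update(block([("PRE", "hVN"), ("vDMN", "pVN")], 0.55))
    s4.update(block([("vDMN", "hVN"), ("pVN", "hVN")], 0.5))
    s4.update(block([("BG", "aSN"), ("BG", "pSN"), ("BG", "RECN"),
                     ("aSN", "pSN"), ("aSN", "RECN"), ("pSN", "RECN")], 0.5))
    s4.update(block([("LAN", "AN")], 0.55))
    s4.update(block([("pSN", "PRE")], -0.45))
    s4.update(block([("pSN", "pVN")], -0.4))

    return [s1, s2, s3, s4]


def default_transition_matrices(k: int = 4) -> dict[str, np.ndarray]:
    """Row-stochastic transition matrices per group.

    Healthy controls switch most; hemodialysis patients least, and both
    patient groups carry an extra bias toward entering and remaining in
    state 3 (so patients dwell longer there).  Stay probabilities are chosen
    so that the windowed transition counts over a 170-TR scan fall in the
    single-digit range typical of sliding-window state analyses.
    """
    stay = {"HC": 0.955, "NonD": 0.972, "HD": 0.984}
    extra_stay3 = {"HC": 0.0, "NonD": 0.01, "HD": 0.012}
    mats = {}
    for g in GROUPS:
        p = stay[g]
        m = np.full((k, k), (1.0 - p) / (k - 1))
        np.fill_diagonal(m, p)
        if k >= 3 and extra_stay3[g] > 0:
            s3 = 2  # zero-based index of state 3
            # patients leave state 3 less often and enter it more often
            m[s3] = (1.0 - (p + extra_stay3[g])) / (k - 1)
            m[s3, s3] = p + extra_stay3[g]
            for r in range(k):
                if r == s3:
                    continue
                leave = 1.0 - m[r, r]
                others = [c for c in range(k) if c != r]
                w = np.array([2.0 if c == s3 else 1.0 for c in others])
                m[r, others] = leave * w / w.sum()
        mats[g] = m
    return mats


def default_edge_effects() -> list[tuple[str, int, list[tuple[int, int]], float]]:
    """Multiplicative weakening of DMN-block edges in state 3 for patients.

    Returns (group, state_index_1based, [(i, j), ...], factor) tuples.  The
    factor multiplies the named covariance entries before SPD repair, so a
    factor of 1 is a no-op.  Defaults weaken within-DMN and DMN-language
    connectivity in state 3, more strongly for dialysis patients.
    """
    dmn_edges = [
        (_idx("dDMN"), _idx("vDMN")),
        (_idx("dDMN"), _idx("PRE")),
        (_idx("vDMN"), _idx("PRE")),
        (_idx("dDMN"), _idx("LAN")),
    ]
    return [("NonD", 3, dmn_edges, 0.6), ("HD", 3, dmn_edges, 0.35)]


# ---------------------------------------------------------------------------
# spec dataclasses
# ---------------------------------------------------------------------------

@dataclass
class SynthSpec:
    """Full description of the synthetic-cohort generative model.

    Defaults reproduce the study conditions assumed throughout the package:
    14 networks, 170 timepoints at TR = 2 s, four Markov-switching covariance
    states, and an HC > NonD > HD gradient in switching rate.
    """

    n_networks: int = 14
    n_timepoints: int = 170
    tr: float = 2.0
    k_states: int = 4
    state_covariances: list[np.ndarray] | None = None
    transition_matrix_per_group: dict[str, np.ndarray] = field(
        default_factory=default_transition_matrices)
    initial_distribution: np.ndarray | None = None
    edge_effects: list[tuple[str, int, list[tuple[int, int]], float]] = field(
        default_factory=default_edge_effects)
    noise_sd: float = 0.1
    ar_coeff: float = 0.25
    seed: int = 0
    # cognition model: score = intercept + b_dwell3 * dwell3 + b_trans * n_transitions + noise
    cognition_model: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            # (intercept, slope on state-3 dwell [per timepoint], slope on transitions, noise sd)
            "MMSE": (28.0, -0.010, 0.05, 0.9),
            "MoCA": (27.0, -0.010, 0.05, 0.9),
            "TMT_A": (55.0, 0.22, -1.8, 8.0),
            "TMT_B": (85.0, 0.28, -2.2, 10.0),
            "SDMT": (50.0, -0.04, 0.45, 5.0),
        })

    def __post_init__(self) -> None:
        if self.state_covariances is None:
            self.state_covariances = build_state_covariances(self)
        if self.initial_distribution is None:
            self.initial_distribution = np.full(self.k_states, 1.0 / self.k_states)
        self.validate()

    def validate(self) -> None:
        if self.n_networks < 2:
            raise ValueError("need at least 2 networks")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if len(self.state_covariances) != self.k_states:
            raise ValueError("one covariance per state required")
        for s, cov in enumerate(self.state_covariances, start=1):
            if cov.shape != (self.n_networks, self.n_networks):
                raise ValueError(f"state {s} covariance has wrong shape")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"state {s} covariance is not symmetric")
            if not np.allclose(np.diag(cov), 1.0, atol=1e-8):
                raise ValueError(f"state {s} covariance does not have unit diagonal")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"state {s} covariance is not positive definite")
        for g, m in self.transition_matrix_per_group.items():
            if m.shape != (self.k_states, self.k_states):
                raise ValueError(f"group {g} transition matrix has wrong shape")
            if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"group {g} transition matrix rows must sum to 1")
        if not np.isclose(self.initial_distribution.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")
        for g, s, edges, f in self.edge_effects:
            if not (0.0 < f <= 1.0):
                raise ValueError("weakening factors must lie in (0, 1]")
            if not (1 <= s <= self.k_states):
                raise ValueError("edge effect names an unknown state")


@dataclass
class GroundTruth:
    """Per-timepoint truth for one simulated subject."""

    state_sequence: np.ndarray          # 1-based labels, length n_timepoints
    true_temporal_metrics: TemporalMetrics
    true_state_covariances: list[np.ndarray]

    def __post_init__(self) -> None:
        k = len(self.true_state_covariances)
        if self.state_sequence.min() < 1 or self.state_sequence.max() > k:
            raise ValueError("state labels out of range")


@dataclass
class TimeCourseMatrix:
    """One subject's network time courses (timepoints x networks)."""

    subject_id: str
    network_labels: list[str]
    data: np.ndarray
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (timepoints x networks)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.data.shape[1] != len(self.network_labels):
            raise ValueError("label count must equal column count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in time courses")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_networks(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def nearest_spd_correlation(mat: np.ndarray, floor: float = _EPS_SPD,
                            max_tries: int = 50) -> tuple[np.ndarray, float]:
    """Repair a symmetric matrix into an SPD correlation matrix.

    Eigenvalues are clipped at ``floor`` and the result rescaled to unit
    diagonal; because rescaling can reintroduce tiny negative eigenvalues the
    clip/rescale cycle is iterated with a geometrically growing floor.
    Returns the repaired matrix and the Frobenius repair distance.
    """
    a = 0.5 * (mat + mat.T)
    orig = a.copy()
    f = floor
    for _ in range(max_tries):
        w, v = np.linalg.eigh(a)
        if w.min() >= floor and np.allclose(np.diag(a), 1.0, atol=1e-12):
            return a, float(np.linalg.norm(a - orig))
        w = np.clip(w, f, None)
        a = (v * w) @ v.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 1.0)
        f *= 2.0
    raise ValueError("SPD repair failed to converge")


def build_state_covariances(spec: SynthSpec | None = None,
                            block_design: list[dict[tuple[int, int], float]] | None = None,
                            n_networks: int | None = None) -> list[np.ndarray]:
    """Turn block designs (pairs -> signed strength) into SPD correlation matrices.

    Raw block matrices that are indefinite are repaired by eigenvalue clipping
    followed by rescaling to unit diagonal; the repair distance is recorded on
    the function's ``last_repair_distances`` attribute.
    """
    if block_design is None:
        block_design = default_block_designs()
    n = n_networks if n_networks is not None else (
        spec.n_networks if spec is not None else len(NETWORK_LABELS))
    if n < 2:
        raise ValueError("need at least 2 networks")
    covs = []
    repairs = []
    for s, design in enumerate(block_design, start=1):
        m = np.eye(n)
        for (i, j), strength in design.items():
            if not (-1.0 < strength < 1.0):
                raise ValueError(f"block strength {strength} outside (-1, 1)")
            m[i, j] = m[j, i] = strength
        try:
            repaired, dist = nearest_spd_correlation(m)
        except ValueError as exc:
            raise ValueError(f"SPD repair failed for state {s}") from exc
        covs.append(repaired)
        repairs.append(dist)
    build_state_covariances.last_repair_distances = repairs
    return covs


def _apply_edge_effects(spec: SynthSpec, group: str) -> list[np.ndarray]:
    """Group-specific state covariances after multiplicative edge weakening."""
    covs = [c.copy() for c in spec.state_covariances]
    for g, s, edges, f in spec.edge_effects:
        if g != group or f == 1.0:
            continue
        c = covs[s - 1]
        for i, j in edges:
            c[i, j] *= f
            c[j, i] = c[i, j]
        covs[s - 1], _ = nearest_spd_correlation(c)
    return covs


def _sample_chain(rng: np.random.Generator, trans: np.ndarray,
                  init: np.ndarray, n: int) -> np.ndarray:
    cum_init = np.cumsum(init)
    cum_trans = np.cumsum(trans, axis=1)
    u = rng.random(n)
    seq = np.empty(n, dtype=np.int64)
    seq[0] = np.searchsorted(cum_init, u[0])
    for t in range(1, n):
        seq[t] = np.searchsorted(cum_trans[seq[t - 1]], u[t])
    return seq + 1  # 1-based


def simulate_subject(spec: SynthSpec, group: str, seed: int,
                     subject_id: str | None = None) -> tuple[TimeCourseMatrix, GroundTruth]:
    """Simulate one subject's network time courses plus ground truth.

    The hidden state switches per timepoint from the group's transition
    matrix; the observation at each TR is drawn from the active state's
    covariance, AR(1)-smoothed over time (variance-preserving), with
    isotropic observation noise added.  Identical (spec, group, seed) yields
    bit-identical output.
    """
    if group not in spec.transition_matrix_per_group:
        raise KeyError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    T, N = spec.n_timepoints, spec.n_networks
    covs = _apply_edge_effects(spec, group)
    chols = [np.linalg.cholesky(c) for c in covs]

    seq = _sample_chain(rng, spec.transition_matrix_per_group[group],
                        spec.initial_distribution, T)
    eta = rng.standard_normal((T, N))
    z = np.empty((T, N))
    for s in range(1, spec.k_states + 1):
        mask = seq == s
        if mask.any():
            z[mask] = eta[mask] @ chols[s - 1].T
    phi = spec.ar_coeff
    if phi > 0:
        # x_t = phi x_{t-1} + sqrt(1-phi^2) z_t keeps the state covariance scale
        x = lfilter([np.sqrt(1.0 - phi ** 2)], [1.0, -phi], z, axis=0)
    else:
        x = z
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal((T, N))

    labels = NETWORK_LABELS[:N] if N <= len(NETWORK_LABELS) else [
        f"net{i+1}" for i in range(N)]
    tm = temporal_metrics(seq, spec.k_states)
    gt = GroundTruth(state_sequence=seq, true_temporal_metrics=tm,
                     true_state_covariances=covs)
    sid = subject_id or f"{group}_{seed}"
    return TimeCourseMatrix(sid, list(labels), x, spec.tr), gt


def _draw_covariates(rng: np.random.Generator, group: str) -> dict:
    row = {
        "group": group,
        "age": float(np.clip(rng.normal(35.4, 9.4), 18, 70)),
        "sex": int(rng.integers(0, 2)),
        "education": float(np.clip(rng.normal(11.8, 3.3), 3, 22)),
        "mean_fd": float(np.clip(rng.normal(0.05, 0.03), 0.005, 0.2)),
    }
    if group == "HC":
        row["disease_duration"] = np.nan
    else:
        mu = 30.5 if group == "HD" else 26.6
        row["disease_duration"] = float(np.clip(rng.normal(mu, 15.8), 6, 120))
    return row


def simulate_cohort(spec: SynthSpec, n_per_group: dict[str, int] | None = None,
                    seed: int | None = None
                    ) -> tuple[list[TimeCourseMatrix], pd.DataFrame, list[GroundTruth]]:
    """Simulate a full cohort: time courses, covariate table, ground truths.

    Default group sizes are 50 HD / 50 NonD / 64 HC.  Subject seeds are
    derived deterministically from the master seed via a seed sequence, so
    the cohort is reproducible byte-for-byte.  Cognitive scores depend
    linearly on each subject's true state-3 dwell time (timepoints) and true
    transition count through ``spec.cognition_model``.
    """
    if n_per_group is None:
        n_per_group = {"HD": 50, "NonD": 50, "HC": 64}
    if not n_per_group:
        raise ValueError("empty group list")
    if seed is None:
        seed = spec.seed
    master = np.random.SeedSequence(seed)
    groups = [g for g in n_per_group if n_per_group[g] > 0]
    n_total = sum(n_per_group[g] for g in groups)
    children = master.spawn(n_total + 1)
    cov_rng = np.random.default_rng(children[0])

    tcs: list[TimeCourseMatrix] = []
    gts: list[GroundTruth] = []
    rows = []
    idx = 1
    for g in groups:
        for i in range(n_per_group[g]):
            sid = f"{g}{i+1:03d}"
            sub_seed = int(children[idx].generate_state(1)[0] % (2 ** 31))
            idx += 1
            tc, gt = simulate_subject(spec, g, sub_seed, subject_id=sid)
            tcs.append(tc)
            gts.append(gt)
            row = {"subject_id": sid, **_draw_covariates(cov_rng, g)}
            tm = gt.true_temporal_metrics
            dwell3_tp = tm.mean_dwell[2] if spec.k_states >= 3 else 0.0
            ntrans = tm.n_transitions
            for score, (a, b_dwell, b_trans, sd) in spec.cognition_model.items():
                row[score] = a + b_dwell * dwell3_tp + b_trans * ntrans + (
                    sd * cov_rng.standard_normal() if sd > 0 else 0.0)
            rows.append(row)
    covariates = pd.DataFrame(rows).set_index("subject_id").reset_index()
    return tcs, covariates, gts


def ground_truth_window_labels(gt: GroundTruth, window_length: int,
                               step: int = 1, n_windows: int | None = None) -> np.ndarray:
    """Map the per-timepoint truth onto the sliding-window grid.

    Each window takes the majority label of the timepoints it covers; ties
    break toward the lowest state index.  ``n_windows`` defaults to
    T - window_length (the package's window-count convention).
    """
    seq = gt.state_sequence
    T = len(seq)
    if window_length > T:
        raise ValueError("window longer than sequence")
    if n_windows is None:
        n_windows = (T - window_length) // step
    labels = np.empty(n_windows, dtype=np.int64)
    k = int(seq.max())
    for w in range(n_windows):
        chunk = seq[w * step: w * step + window_length]
        counts = np.bincount(chunk, minlength=k + 1)[1:]
        labels[w] = int(np.argmax(counts)) + 1  # argmax takes lowest index on ties
    return labels


def ground_truth_temporal_metrics(gt: GroundTruth, window_length: int,
                                  step: int = 1,
                                  n_windows: int | None = None) -> TemporalMetrics:
    """Oracle temporal metrics on the window grid (majority-vote labels)."""
    labels = ground_truth_window_labels(gt, window_length, step, n_windows)
    return temporal_metrics(labels, len(gt.true_state_covariances))


def ground_truth_to_json(gt: GroundTruth) -> str:
    tm = gt.true_temporal_metrics
    return json.dumps({
        "state_sequence": gt.state_sequence.tolist(),
        "fractional_windows": tm.fractional_windows.tolist(),
        "mean_dwell": tm.mean_dwell.tolist(),
        "n_transitions": int(tm.n_transitions),
    })
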