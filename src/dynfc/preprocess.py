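"""Post-ICA time-course cleaning: detrend, despike, nuisance regression, low-pass.

The four stages run per subject, in this order, matching standard network
time-course postprocessing: (1) joint polynomial detrending up to cubic order
on an orthogonal Legendre basis, (2) running-median/MAD despiking with
boundary clipping, (3) least-squares regression of nuisance confounds
(e.g., six head-motion parameters), and (4) zero-phase Butterworth low-pass
filtering with a 0.15 Hz cutoff at TR = 2 s.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.polynomial import legendre
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt

from .simulate import TimeCourseMatrix

_MAD_FLOOR = 1e-9


def _replace(tc: TimeCourseMatrix, data: np.ndarray) -> TimeCourseMatrix:
    return dataclasses.replace(tc, data=data)


def detrend_poly(tc: TimeCourseMatrix, max_order: int = 3) -> TimeCourseMatrix:
    """Remove polynomial trends up to ``max_order`` (jointly fitted).

    The basis is Legendre polynomials on [-1, 1], fitted jointly by least
    squares, so the result is order-independent and each residual column has
    zero projection onto every polynomial of order <= max_order.
    """
    if not (0 <= max_order <= 3):
        raise ValueError("max_order must lie in 0..3")
    T = tc.n_timepoints
    if T <= max_order + 1:
        raise ValueError("too few timepoints for the requested order")
    t = np.linspace(-1.0, 1.0, T)
    basis = np.column_stack([legendre.Legendre.basis(d)(t)
                             for d in range(max_order + 1)])
    coef, *_ = np.linalg.lstsq(basis, tc.data, rcond=None)
    return _replace(tc, tc.data - basis @ coef)


def despike(tc: TimeCourseMatrix, threshold_mad: float = 4.0,
            window: int = 11) -> TimeCourseMatrix:
    """Clip samples deviating from a running median by > threshold * local MAD.

    Local MADs of zero (constant stretches, replicated boundary values) fall
    back to the column's global MAD, floored at a small epsilon, so clean
    samples near the boundary are not clamped to the running median.  Samples
    within the threshold are returned unchanged; outliers are replaced by the
    value at the threshold boundary (median ± threshold*MAD), preserving sign.
    """
    if threshold_mad <= 0:
        raise ValueError("threshold_mad must be positive")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > tc.n_timepoints:
        raise ValueError("window longer than series")
    x = tc.data
    med = median_filter(x, size=(window, 1), mode="nearest")
    mad = median_filter(np.abs(x - med), size=(window, 1), mode="nearest")
    global_mad = np.median(np.abs(x - np.median(x, axis=0)), axis=0)
    mad = np.where(mad <= _MAD_FLOOR,
                   np.maximum(global_mad, _MAD_FLOOR), mad)
    bound = threshold_mad * mad
    dev = x - med
    clipped = med + np.clip(dev, -bound, bound)
    return _replace(tc, clipped)


def regress_nuisance(tc: TimeCourseMatrix, confounds: np.ndarray,
                     names: list[str] | None = None) -> TimeCourseMatrix:
    """Residualize each network signal on [intercept | confounds]."""
    c = np.atleast_2d(np.asarray(confounds, dtype=float))
    if c.shape[0] != tc.n_timepoints:
        raise ValueError("confound rows must equal timepoints")
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite confound values")
    design = np.column_stack([np.ones(tc.n_timepoints), c])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        cols = names if names is not None else [f"confound{i}" for i in range(c.shape[1])]
        raise ValueError(f"rank-deficient nuisance design (columns: {cols})")
    coef, *_ = np.linalg.lstsq(design, tc.data, rcond=None)
    return _replace(tc, tc.data - design @ coef)


def lowpass_filter(tc: TimeCourseMatrix, cutoff_hz: float = 0.15,
                   order: int = 5) -> TimeCourseMatrix:
    """Zero-phase Butterworth low-pass (forward-backward, reflection padding)."""
    nyquist = 1.0 / (2.0 * tc.tr)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz at or above Nyquist {nyquist} Hz")
    b, a = butter(order, cutoff_hz / nyquist, btype="low")
    filtered = filtfilt(b, a, tc.data, axis=0, method="pad")
    return _replace(tc, filtered)


def preprocess_pipeline(tc: TimeCourseMatrix, confounds: np.ndarray | None = None,
                        detrend_order: int = 3, despike_threshold: float = 4.0,
                        despike_window: int = 11,
                        cutoff_hz: float = 0.15) -> TimeCourseMatrix:
    """Full postprocessing chain: detrend -> despike -> regression -> low-pass."""
    out = detrend_poly(tc, detrend_order)
    out = despike(out, despike_threshold, despike_window)
    if confounds is not None:
        out = regress_nuisance(out, confounds)
    out = lowpass_filter(out, cutoff_hz)
    return out
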