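"""Correlational-PPI connectivity from node time series.

The chain mirrors the standard generalized-PPI construction: observed BOLD
signals (first eigenvariate when a node has multiple constituent series) are
deconvolved against the canonical two-gamma HRF into neural-event estimates;
each condition's neural boxcar is multiplied with the neural estimate and
reconvolved, yielding one PPI term per node and condition; pairwise Pearson
correlations of those terms, Fisher z-transformed, form the condition's
connectivity matrix (the correlational-PPI convention: symmetric, computed
over the whole scan).

Deconvolution uses ridge (Tikhonov) regression against the HRF convolution
operator.  The kernel is sampled at t = TR, 2 TR, ... when the operator is
built: the two-gamma kernel is exactly zero at t = 0, and absorbing that one
leading zero keeps the Toeplitz operator lower-triangular with a nonzero
diagonal, hence exactly invertible in the noiseless case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = [
    "HRFParams",
    "TaskRegressor",
    "ConnectivityMatrix",
    "canonical_hrf",
    "build_task_regressor",
    "deconvolve",
    "make_deconvolver",
    "compute_ppi_term",
    "ppi_matrix",
    "first_eigenvariate",
    "remove_drift",
]

R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class HRFParams:
    """Canonical two-gamma HRF: 6 s peak, 16 s undershoot, 1:6 ratio, 32 s."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length: float = 32.0


@dataclass
class TaskRegressor:
    """A condition's neural boxcar and its HRF-convolved regressor."""

    condition: str
    psi_micro: np.ndarray       # microtime indicator of the condition's events
    psi: np.ndarray             # indicator sampled at the TR grid
    convolved: np.ndarray       # psi_micro * HRF, sampled at the TR grid
    microtime: int


@dataclass
class ConnectivityMatrix:
    """Fisher-z correlational-PPI matrix for one participant and condition."""

    participant_id: int
    condition: str
    z: np.ndarray
    n_timepoints: int

    def __post_init__(self) -> None:
        if not np.allclose(self.z, self.z.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectivity matrix must be finite")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


def _hrf_shape(t: np.ndarray, p: HRFParams) -> np.ndarray:
    peak = stats.gamma.pdf(t, p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
    under = stats.gamma.pdf(
        t, p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion
    )
    return peak - under / p.ratio


@lru_cache(maxsize=32)
def _hrf_peak_value(p: HRFParams) -> float:
    # continuous-time peak on a 1 ms grid, so the normalization constant does
    # not depend on the requested sampling interval
    t = np.arange(0.0, p.length, 1e-3)
    return float(_hrf_shape(t, p).max())


@lru_cache(maxsize=128)
def _cached_kernel(tr: float, p: HRFParams, shifted: bool) -> np.ndarray:
    t = np.arange(tr if shifted else 0.0, p.length + (tr if shifted else 0.0), tr)
    k = _hrf_shape(t, p) / _hrf_peak_value(p)
    k.setflags(write=False)
    return k


def canonical_hrf(tr: float, params: HRFParams | None = None) -> np.ndarray:
    """Sample the canonical two-gamma HRF at interval ``tr``, peak-normalized.

    The difference of two gamma densities (peak at ~5 s, undershoot at ~15 s,
    peak:undershoot 6:1) over a 32 s support, divided by its continuous-time
    maximum so the kernel peaks at 1 regardless of sampling rate.
    """
    if tr <= 0:
        raise ValueError("sampling interval must be positive")
    return _cached_kernel(float(tr), params or HRFParams(), shifted=False)


def build_task_regressor(
    design,
    condition: str,
    microtime: int = 16,
    hrf_params: HRFParams | None = None,
    labels=None,
) -> TaskRegressor:
    """Build a condition's neural boxcar and HRF-convolved regressor.

    The boxcar is 1 on a microtime grid (``tr / microtime``) during the
    condition's events and 0 elsewhere; the convolved regressor is the boxcar
    convolved with the canonical HRF and sampled at volume acquisition times.
    ``labels`` overrides ``design.condition_of_event``.
    """
    labels = np.asarray(design.condition_of_event if labels is None else labels)
    if len(labels) != design.n_events:
        raise ValueError("need one condition label per event")
    dt = design.tr / microtime
    n_micro = design.n_volumes * microtime
    psi_micro = np.zeros(n_micro)
    sel = labels == condition
    if not sel.any():
        warnings.warn(f"condition {condition!r} has no events; zero regressor",
                      stacklevel=2)
    for onset, dur in zip(design.onsets[sel], design.durations[sel]):
        i0, i1 = int(np.floor(onset / dt)), int(np.ceil((onset + dur) / dt))
        psi_micro[i0:min(i1, n_micro)] = 1.0
    hrf = canonical_hrf(dt, hrf_params)
    convolved = np.convolve(psi_micro, hrf)[:n_micro][::microtime]
    return TaskRegressor(
        condition=condition,
        psi_micro=psi_micro,
        psi=psi_micro[::microtime],
        convolved=convolved,
        microtime=microtime,
    )


def _hrf_tr_kernel(tr: float, hrf_params: HRFParams | None) -> np.ndarray:
    """HRF sampled at t = TR, 2 TR, ...; first sample nonzero by construction."""
    return _cached_kernel(float(tr), hrf_params or HRFParams(), shifted=True)


def make_deconvolver(
    n_timepoints: int,
    tr: float,
    ridge_lambda: float | None = None,
    hrf_params: HRFParams | None = None,
) -> np.ndarray:
    """Matrix M such that ``M @ bold`` is the ridge neural estimate.

    Minimizes ``||H n - y||^2 + lambda ||n||^2`` where H is the (invertible,
    lower-triangular) HRF convolution operator; the default regularization is
    ``0.05 * trace(H'H) / T``.
    """
    h = _hrf_tr_kernel(tr, hrf_params)
    T = n_timepoints
    H = np.zeros((T, T))
    for k, hk in enumerate(h[:T]):
        H += hk * np.eye(T, k=-k)
    if ridge_lambda is None:
        ridge_lambda = 0.05 * np.trace(H.T @ H) / T
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be nonnegative")
    if ridge_lambda == 0:
        return np.linalg.inv(H)
    return np.linalg.solve(H.T @ H + ridge_lambda * np.eye(T), H.T)


def deconvolve(
    bold: np.ndarray,
    tr: float,
    ridge_lambda: float | None = None,
    hrf_params: HRFParams | None = None,
) -> np.ndarray:
    """Deconvolve BOLD into a neural-event estimate (ridge regression).

    ``bold`` may be one series (T,) or a stack (n_series, T); the series
    length must cover at least one HRF kernel length.
    """
    bold = np.asarray(bold, dtype=float)
    T = bold.shape[-1]
    h = _hrf_tr_kernel(tr, hrf_params)
    if T < len(h):
        raise ValueError("series shorter than the HRF kernel")
    M = make_deconvolver(T, tr, ridge_lambda, hrf_params)
    return (M @ bold.T).T if bold.ndim == 2 else M @ bold


def compute_ppi_term(
    neural: np.ndarray,
    psi: np.ndarray,
    tr: float,
    hrf_params: HRFParams | None = None,
    microtime: int = 1,
    align_shift: int = 1,
) -> np.ndarray:
    """PPI interaction term: (psi * neural) reconvolved, downsampled to TR.

    With ``microtime`` 1, ``neural`` and ``psi`` share the TR grid and the
    term stays there; with ``microtime`` m, ``psi`` is on the finer grid
    (tr/m), the neural estimate is interpolated to it (band-limited - the
    estimate carries no information above the acquisition Nyquist), the
    product is convolved with the HRF at microtime resolution and then
    sampled back at volume times.  The microtime path honors event
    on/offsets that do not align with volume acquisition (the usual gPPI
    construction).  ``align_shift`` advances the neural estimate by that
    many volumes before the multiplication, compensating the one-sample
    delay the invertible (lead-absorbed) deconvolution kernel introduces.
    With ``psi`` identically 1 the term is the reconvolved neural estimate
    up to that alignment.
    """
    neural = np.asarray(neural, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if neural.shape[-1] * microtime != len(psi):
        raise ValueError("psi length must equal microtime * neural length")
    if align_shift:
        pad = neural[..., -1:].repeat(align_shift, axis=-1)
        neural = np.concatenate([neural[..., align_shift:], pad], axis=-1)
    if microtime == 1:
        h = _hrf_tr_kernel(tr, hrf_params)
        inter = neural * psi
        if inter.ndim == 1:
            return np.convolve(inter, h)[: len(psi)]
        from scipy.signal import fftconvolve

        return fftconvolve(inter, h[None, :], axes=1)[:, : len(psi)]
    from scipy.signal import resample_poly

    h = _hrf_tr_kernel(tr / microtime, hrf_params)
    up = resample_poly(neural, microtime, 1, axis=-1, padtype="line")
    inter = up * psi
    if inter.ndim == 1:
        return np.convolve(inter, h)[: len(psi)][::microtime]
    from scipy.signal import fftconvolve

    return fftconvolve(inter, h[None, :], axes=1)[:, : len(psi)][:, ::microtime]


def ppi_matrix(
    terms: np.ndarray,
    participant_id: int = 0,
    condition: str = "",
) -> ConnectivityMatrix:
    """Fisher-z matrix of pairwise Pearson correlations between PPI terms.

    ``terms`` is nodes x timepoints.  Correlations are clipped to
    +-(1 - 1e-7) before arctanh; the diagonal is zero.  A constant term
    (zero variance) gets a zero row/column with a warning.
    """
    terms = np.asarray(terms, dtype=float)
    n, T = terms.shape
    constant = np.ptp(terms, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant PPI term(s); zeroing their edges",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(terms)
    r = np.nan_to_num(r, nan=0.0)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(participant_id=participant_id, condition=condition,
                              z=z, n_timepoints=T)


def first_eigenvariate(signals: np.ndarray) -> np.ndarray:
    """Summarize multiple series for one node as the first eigenvariate.

    SVD of the centered (timepoints x series) matrix; the first left singular
    vector's time course, sign-aligned so the mean series loading is positive
    and rescaled to the mean per-series standard deviation.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))  # series x time
    if signals.shape[0] < 1 or signals.size == 0:
        raise ValueError("need at least one signal")
    X = signals.T - signals.mean(axis=1)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    u = U[:, 0]
    if Vt[0].mean() < 0:
        u = -u
    target_sd = signals.std(axis=1).mean()
    sd = u.std()
    if sd > 0 and target_sd > 0:
        u = u * (target_sd / sd)
    return u + signals.mean()


def remove_drift(
    series: np.ndarray,
    tr: float,
    cutoff_hz: float = 0.01,
    poly_order: int = 2,
) -> np.ndarray:
    """High-pass filter by regressing out polynomial and slow cosine drifts.

    A discrete-cosine basis covering frequencies below ``cutoff_hz`` plus
    polynomials up to ``poly_order`` is projected out; the residual keeps the
    original mean.  Works on (T,) or (n_series, T) arrays.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    T = x.shape[1]
    t = np.arange(T)
    cols = [np.polyval(np.eye(poly_order + 1)[i], (t - T / 2) / T)
            for i in range(poly_order + 1)]
    n_cos = int(np.floor(2 * cutoff_hz * T * tr))
    for k in range(1, n_cos + 1):
        cols.append(np.cos(np.pi * k * (t + 0.5) / T))
    B = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(B, x.T, rcond=None)
    resid = x - (B @ beta).T
    resid = resid + x.mean(axis=1, keepdims=True)
    return resid[0] if np.asarray(series).ndim == 1 else resid
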