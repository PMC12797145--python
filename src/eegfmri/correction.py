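"""Macrovascular BOLD correction.

The venous signal that contaminates perivascular BOLD is approximated by the
series of the voxel with the highest macrovascular blood-volume fraction
(fBV), demeaned and peak-normalized.  For every voxel the lag maximizing the
absolute cross-correlation with that reference is found, and the lag-shifted
reference is removed by per-voxel nuisance regression (intercept included,
voxel mean restored).

The regressor therefore has the same shape at every voxel up to lag and gain;
per-voxel biophysical forward modeling of vascular signal shapes is outside
the scope of this implementation and is documented as the approximation made.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .fmri_metrics import VolumeSeries

log = logging.getLogger(__name__)

__all__ = [
    "CorrectionModel",
    "shift_series",
    "extract_venous_reference",
    "estimate_voxel_lag",
    "regress_reference",
    "correct_volume",
]


@dataclass
class CorrectionModel:
    """Diagnostics of one correction run: the unit-peak reference, and
    per-voxel lag, regression coefficient and peak |cross-correlation|."""
    reference: np.ndarray
    lag: np.ndarray
    beta: np.ndarray
    max_abs_xcorr: np.ndarray


def shift_series(ref: np.ndarray, lag: int) -> np.ndarray:
    """``out[t] = ref[t - lag]`` with zeros outside the recorded window.

    The same convention is used by the synthetic confound injector, so
    injected lags are recoverable exactly.
    """
    out = np.zeros_like(ref)
    t = ref.shape[0]
    if lag >= 0:
        out[lag:] = ref[: t - lag]
    else:
        out[:lag] = ref[-lag:]
    return out


def extract_venous_reference(v: VolumeSeries) -> np.ndarray:
    """Prototypical venous fluctuation: the series of the maximum-fBV voxel,
    demeaned and normalized by its maximum absolute value.

    Ties on fBV are broken by the lowest linear voxel index (logged).
    """
    if v.fbv is None or not np.any(v.fbv > 0):
        raise ValueError("all-zero fBV map: supply a vessel mask / fBV estimate "
                         "before macrovascular correction")
    flat = v.fbv.ravel()
    peak = flat.max()
    ties = np.flatnonzero(flat == peak)
    if ties.size > 1:
        warnings.warn(f"{ties.size} voxels tie at max fBV; using lowest linear index",
                      stacklevel=2)
    idx = np.unravel_index(ties[0], v.fbv.shape)
    series = v.data[idx].astype(float)
    series = series - series.mean()
    peak_abs = np.abs(series).max()
    if peak_abs == 0:
        raise ValueError("max-fBV voxel has a constant series")
    return series / peak_abs


def _lag_candidates(max_lag: int):
    """Search order encoding the tie-break: smallest |lag| first, negative
    before positive."""
    out = [0]
    for k in range(1, max_lag + 1):
        out += [-k, k]
    return out


def _overlap_corr(data: np.ndarray, sref: np.ndarray, lag: int, t: int) -> np.ndarray:
    """Pearson r between rows of ``data`` and the shifted reference over the
    overlapping window only."""
    win = slice(max(0, lag), t + min(0, lag))
    x = data[:, win]
    y = sref[win]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xs = xc.std(axis=1)
    ys = yc.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (x.shape[1] * xs * ys)
    r[~np.isfinite(r)] = 0.0
    return r


def estimate_voxel_lag(x: np.ndarray, ref: np.ndarray, max_lag: int = 3):
    """Lag in [-max_lag, +max_lag] maximizing |Pearson r(x(t), ref(t - lag))|
    over the overlapping window.

    Ties take the smallest |lag|, then negative before positive.  A constant
    voxel returns (0, 0.0).
    """
    lags, xcorr = estimate_lags(np.atleast_2d(np.asarray(x, dtype=float)), ref, max_lag)
    return int(lags[0]), float(xcorr[0])


def estimate_lags(data: np.ndarray, ref: np.ndarray, max_lag: int = 3):
    """Vectorized lag search for a voxels x time matrix; see
    :func:`estimate_voxel_lag`."""
    t = ref.shape[0]
    if max_lag >= t / 4:
        raise ValueError("max_lag must be below a quarter of the series length")
    best_lag = np.zeros(data.shape[0], dtype=int)
    best_r = np.zeros(data.shape[0])
    for lag in _lag_candidates(max_lag):
        sref = shift_series(ref, lag)
        r = np.abs(_overlap_corr(data, sref, lag, t))
        better = r > best_r  # strict: earlier candidates win ties
        best_lag[better] = lag
        best_r[better] = r[better]
    return best_lag, best_r


def regress_reference(v: VolumeSeries, ref: np.ndarray, lags: np.ndarray):
    """Per-voxel OLS of the series on [intercept, lag-shifted reference];
    the corrected series is the residual plus the voxel mean (so that RSFA's
    denominator survives).

    Voxels whose shifted reference is constant are passed through unchanged
    and flagged with beta = 0.
    """
    t = v.n_frames
    flat = v.data.reshape(-1, t)
    lags = np.asarray(lags).reshape(-1)
    if lags.shape[0] != flat.shape[0]:
        raise ValueError("lag field does not match the voxel grid")
    out = flat.copy()
    beta = np.zeros(flat.shape[0])
    for lag in np.unique(lags):
        sref = shift_series(ref, int(lag))
        sc = sref - sref.mean()
        denom = float(sc @ sc)
        rows = np.flatnonzero(lags == lag)
        if denom == 0:
            log.warning("constant shifted reference at lag %d; %d voxel(s) passed "
                        "through", lag, rows.size)
            continue
        y = flat[rows]
        b = (y - y.mean(axis=1, keepdims=True)) @ sc / denom
        out[rows] = y - b[:, None] * sc[None, :]
        beta[rows] = b
    shape = v.grid_shape
    corrected = v.copy_with(out.reshape(v.data.shape))
    return corrected, beta.reshape(shape)


def correct_volume(v: VolumeSeries, max_lag: int = 3):
    """Full correction: extract the venous reference, estimate per-voxel lags,
    regress the lag-shifted reference out.  Returns the corrected volume and a
    :class:`CorrectionModel`."""
    ref = extract_venous_reference(v)
    flat = v.data.reshape(-1, v.n_frames)
    lags, xcorr = estimate_lags(flat, ref, max_lag)
    corrected, beta = regress_reference(v, ref, lags)
    model = CorrectionModel(reference=ref,
                            lag=lags.reshape(v.grid_shape),
                            beta=beta,
                            max_abs_xcorr=xcorr.reshape(v.grid_shape))
    return corrected, model
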