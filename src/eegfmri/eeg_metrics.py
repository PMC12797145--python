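"""EEG source-space metrics: fractional band power, normalized total power,
imaginary coherence (band-limited and broadband), and the multiscale-entropy
complexity index (CI).

All spectral estimates use Welch segment averaging with Hann tapers,
0.5-Hz frequency resolution and 50 % segment overlap.  Imaginary coherence —
the magnitude of the imaginary part of the complex coherency
``S_uv / sqrt(S_uu S_vv)`` — is insensitive to zero-lag (volume-conduction)
mixing, which is why it is the connectivity measure of choice here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .entropy import DEFAULT_SCALES, complexity_index, sample_entropy

log = logging.getLogger(__name__)

__all__ = [
    "SourceSignalSet",
    "BANDS",
    "MseParams",
    "SpectralMatrix",
    "detrend_sources",
    "compute_fractional_power",
    "compute_total_power",
    "compute_cross_spectrum",
    "compute_imaginary_coherence",
    "band_coherence",
    "network_coherence",
    "compute_complexity_index",
    "eeg_network_metrics",
    "EEG_METRICS",
]

#: canonical band scheme (Hz).  Bins are assigned half-open [low, high)
#: except gamma, which closes at 50 Hz, so shared edges are never counted
#: twice.
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 50.0),
}

#: canonical X-side metric names for the association grid
EEG_METRICS = (
    tuple(f"coh_{b}" for b in BANDS) + ("coh_broadband",)
    + tuple(f"power_{b}" for b in BANDS) + ("total_power", "ci")
)


@dataclass
class SourceSignalSet:
    """Source-space EEG: a sources x samples matrix with sampling rate and a
    network label per source."""

    data: np.ndarray
    rate_hz: float
    source_network: np.ndarray

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.source_network = np.asarray(self.source_network, dtype=int)
        if self.rate_hz <= 100:
            raise ValueError("sampling rate must exceed 100 Hz to cover the 30-50 Hz band")
        if self.source_network.shape[0] != self.data.shape[0]:
            raise ValueError("one network label per source required")

    @property
    def n_sources(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class MseParams:
    """Multiscale-entropy settings: per-scale SampEn embedding length,
    tolerance as a multiple of the (pre-coarse-graining) SD, and the
    coarse-graining factors."""
    m_order: int = 2
    r_factor: float = 0.5
    scales: tuple = DEFAULT_SCALES


@dataclass
class SpectralMatrix:
    """Welch cross- and auto-spectra for one source pair on a common
    frequency grid."""
    freqs: np.ndarray
    s_uv: np.ndarray
    s_uu: np.ndarray
    s_vv: np.ndarray
    n_segments: int


def band_bins(freqs: np.ndarray, band: str) -> np.ndarray:
    """Boolean selector of the frequency bins belonging to ``band``."""
    low, high = BANDS[band]
    if band == "gamma":
        return (freqs >= low) & (freqs <= high)
    return (freqs >= low) & (freqs < high)


def _total_bins(freqs: np.ndarray) -> np.ndarray:
    return (freqs >= min(b[0] for b in BANDS.values())) & \
           (freqs <= max(b[1] for b in BANDS.values()))


# ---------------------------------------------------------------------------
# preprocessing & power
# ---------------------------------------------------------------------------

def detrend_sources(s: SourceSignalSet) -> SourceSignalSet:
    """Remove the per-source least-squares line (linear detrend).

    Closed-form slope/intercept per row; output is zero-mean.
    """
    x = s.data
    n = x.shape[1]
    t = np.arange(n) - (n - 1) / 2.0
    slope = (x @ t) / (t @ t)
    out = x - x.mean(axis=1, keepdims=True) - slope[:, None] * t[None, :]
    return SourceSignalSet(out, s.rate_hz, s.source_network)


def _welch_params(rate_hz: float, df: float = 0.5, overlap: float = 0.5):
    nperseg = int(round(rate_hz / df))
    return nperseg, int(nperseg * overlap)


def _psd(s: SourceSignalSet, df: float = 0.5):
    nperseg, noverlap = _welch_params(s.rate_hz, df)
    if s.n_samples < nperseg:
        raise ValueError(f"need at least {nperseg} samples for {df}-Hz resolution")
    return sps.welch(s.data, fs=s.rate_hz, window="hann", nperseg=nperseg,
                     noverlap=noverlap, axis=1)


def compute_fractional_power(s: SourceSignalSet, df: float = 0.5) -> pd.DataFrame:
    """Per-source band power divided by total 1-50 Hz power.

    Fractions over the five bands sum to 1 per source.  All-zero sources are
    flagged missing (NaN row) and logged.
    """
    freqs, psd = _psd(s, df)
    total = psd[:, _total_bins(freqs)].sum(axis=1)
    dead = total <= 0
    if dead.any():
        log.warning("%d all-zero source(s): fractional power undefined", int(dead.sum()))
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for band in BANDS:
            frac = psd[:, band_bins(freqs, band)].sum(axis=1) / total
            out[band] = np.where(dead, np.nan, frac)
    return pd.DataFrame(out)


def compute_total_power(s: SourceSignalSet, df: float = 0.5) -> np.ndarray:
    """Total 1-50 Hz power per source, normalized by the spatial SD
    (population SD, ddof = 0, across sources) of that quantity — a
    per-participant SNR equalizer.

    Requires >= 2 sources; identical totals (zero spatial SD) yield NaN.
    """
    if s.n_sources < 2:
        raise ValueError("total-power normalization needs at least 2 sources")
    freqs, psd = _psd(s, df)
    total = psd[:, _total_bins(freqs)].sum(axis=1)
    sd = float(np.std(total))
    if sd == 0:
        log.warning("zero spatial SD of total power; normalized power undefined")
        return np.full(s.n_sources, np.nan)
    return total / sd


# ---------------------------------------------------------------------------
# coherence
# ---------------------------------------------------------------------------

def compute_cross_spectrum(u: np.ndarray, v: np.ndarray, rate_hz: float,
                           df: float = 0.5, overlap: float = 0.5) -> SpectralMatrix:
    """Welch cross-spectrum ``S_uv = (1/N) sum_n U_n(f) V_n*(f)`` with Hann
    tapers, plus the auto-spectra from the same segmentation."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nperseg = int(round(rate_hz / df))
    noverlap = int(nperseg * overlap)
    if u.shape[0] < nperseg or v.shape[0] < nperseg:
        raise ValueError(f"series shorter than one {nperseg}-sample segment")
    freqs, s_uv = sps.csd(u, v, fs=rate_hz, window="hann", nperseg=nperseg,
                          noverlap=noverlap)
    _, s_uu = sps.welch(u, fs=rate_hz, window="hann", nperseg=nperseg,
                        noverlap=noverlap)
    _, s_vv = sps.welch(v, fs=rate_hz, window="hann", nperseg=nperseg,
                        noverlap=noverlap)
    step = nperseg - noverlap
    n_seg = 1 + (min(u.shape[0], v.shape[0]) - nperseg) // step
    return SpectralMatrix(freqs, s_uv, s_uu, s_vv, n_seg)


def compute_imaginary_coherence(sm: SpectralMatrix) -> np.ndarray:
    """|Im(S_uv / sqrt(S_uu S_vv))| per frequency bin, in [0, 1]; bins with a
    zero auto-spectrum are flagged NaN."""
    denom = np.sqrt(sm.s_uu * sm.s_vv)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(denom > 0, sm.s_uv / denom, np.nan + 0j)
    return np.abs(np.imag(coh))


def band_coherence(imcoh: np.ndarray, freqs: np.ndarray) -> dict:
    """Arithmetic mean of an ImCoh spectrum over each band's bins, plus the
    broadband mean over all 1-50 Hz bins."""
    out = {}
    for band in BANDS:
        bins = band_bins(freqs, band)
        if not bins.any():
            raise ValueError(f"no frequency bins fall in band '{band}' at this resolution")
        out[band] = float(np.nanmean(imcoh[bins]))
    out["broadband"] = float(np.nanmean(imcoh[_total_bins(freqs)]))
    return out


def network_coherence(s: SourceSignalSet, df: float = 0.5) -> pd.DataFrame:
    """Mean band-limited / broadband ImCoh over all unordered within-network
    source pairs.  Single-source networks are flagged missing."""
    rows = []
    for nid in np.unique(s.source_network):
        idx = np.flatnonzero(s.source_network == nid)
        if idx.size < 2:
            log.warning("network %d has a single source; coherence undefined", nid)
            rows.append({"network": int(nid),
                         **{b: np.nan for b in (*BANDS, "broadband")}})
            continue
        acc = []
        for i, j in combinations(idx, 2):
            sm = compute_cross_spectrum(s.data[i], s.data[j], s.rate_hz, df=df)
            acc.append(band_coherence(compute_imaginary_coherence(sm), sm.freqs))
        mean = {b: float(np.mean([a[b] for a in acc])) for b in acc[0]}
        rows.append({"network": int(nid), **mean})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# complexity
# ---------------------------------------------------------------------------

def _broadband_filter(x: np.ndarray, rate_hz: float,
                      low: float = 1.0, high: float = 50.0) -> np.ndarray:
    """FFT boxcar band-pass to the full 1-50 Hz analysis band."""
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    spec = np.fft.rfft(x, axis=-1)
    spec[..., (freqs < low) | (freqs > high)] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def compute_complexity_index(x: np.ndarray, params: MseParams = MseParams()) -> float:
    """Complexity index: area under the SampEn-vs-scale curve.

    The series is coarse-grained at each scale (non-overlapping means); the
    tolerance ``r = r_factor * SD`` is fixed from the series as given (callers
    band-filter first), keeping r constant across scales.  Insufficient length
    at the largest scale yields NaN (required length is logged).
    """
    x = np.asarray(x, dtype=float).ravel()
    need = max(params.scales) * (params.m_order + 2)
    if x.shape[0] < need:
        log.warning("series length %d < %d required for scale %d; CI undefined",
                    x.shape[0], need, max(params.scales))
        return np.nan
    return complexity_index(x, m=params.m_order, r_factor=params.r_factor,
                            scales=params.scales)


def broadband_complexity(s: SourceSignalSet, params: MseParams = MseParams()) -> np.ndarray:
    """Per-source CI of the 1-50 Hz band-passed signal (the headline EEG
    entropy metric)."""
    filt = _broadband_filter(s.data, s.rate_hz)
    return np.array([compute_complexity_index(row, params) for row in filt])


# ---------------------------------------------------------------------------
# network reduction
# ---------------------------------------------------------------------------

def eeg_network_metrics(s: SourceSignalSet, params: MseParams = MseParams(),
                        df: float = 0.5,
                        metrics: tuple = EEG_METRICS) -> pd.DataFrame:
    """Network-wise values of the requested EEG metrics (long format:
    network, metric, value).  Sources are averaged within their network;
    coherence is the all-pairs within-network mean."""
    s = detrend_sources(s)
    nets = np.unique(s.source_network)
    frames = []

    def _net_mean(per_source: np.ndarray, name: str):
        vals = [float(np.nanmean(per_source[s.source_network == nid])) for nid in nets]
        frames.append(pd.DataFrame({"network": nets.astype(int), "metric": name,
                                    "value": vals}))

    want_power = any(m.startswith("power_") for m in metrics)
    if want_power:
        frac = compute_fractional_power(s, df)
        for band in BANDS:
            if f"power_{band}" in metrics:
                _net_mean(frac[band].to_numpy(), f"power_{band}")
    if "total_power" in metrics:
        _net_mean(compute_total_power(s, df), "total_power")
    if "ci" in metrics:
        _net_mean(broadband_complexity(s, params), "ci")
    want_coh = any(m.startswith("coh_") for m in metrics)
    if want_coh:
        coh = network_coherence(s, df)
        for band in (*BANDS, "broadband"):
            if f"coh_{band}" in metrics:
                frames.append(pd.DataFrame({"network": coh["network"].astype(int),
                                            "metric": f"coh_{band}",
                                            "value": coh[band]}))
    return pd.concat(frames, ignore_index=True)[["network", "metric", "value"]]
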