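"""rs-fMRI metrics on 4-D BOLD-like volumes.

Implements the five seed-independent / seed-based resting-state metrics —
RSFA, global and local functional-connectivity density (gFCD / lFCD), BOLD
sample entropy, and seed-based network FC — together with the minimal
preprocessing they require (initial-frame rejection, WM/CSF nuisance
regression, frequency-domain band-pass) and network-wise reduction to a long
metric table.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .entropy import sample_entropy

log = logging.getLogger(__name__)

__all__ = [
    "VolumeSeries",
    "BandLimits",
    "EntropyParams",
    "preprocess_bold",
    "bandpass_volume",
    "compute_rsfa",
    "compute_gfcd",
    "compute_lfcd",
    "compute_bold_entropy",
    "compute_seed_fc",
    "summarize_network",
    "fmri_network_metrics",
    "FMRI_METRICS",
]

#: canonical Y-side metric names
FMRI_METRICS = ("rsfa", "seed_fc", "gfcd", "lfcd", "entropy")

#: Fisher-z cap applied at |r| = 0.999 so degenerate (identical-signal) cases
#: stay finite
FISHER_R_CAP = 0.999


@dataclass
class VolumeSeries:
    """A 4-D voxel-by-time dataset with tissue/vessel masks and an fBV map.

    Attributes
    ----------
    data : float array, shape (x, y, z, t)
    tr_seconds : repetition interval
    masks : named boolean grids; conventional keys are ``gray``, ``white``,
        ``csf`` and ``vessel``
    fbv : per-voxel macrovascular blood-volume fraction in [0, 1], or None
    """

    data: np.ndarray
    tr_seconds: float
    masks: dict = field(default_factory=dict)
    fbv: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[-1] < 2:
            raise ValueError("need at least 2 time frames")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))
            raise ValueError(f"non-finite values at (first) voxel/frame {tuple(bad[0])}")
        for name, m in self.masks.items():
            if m.shape != self.data.shape[:3]:
                raise ValueError(f"mask '{name}' shape {m.shape} does not match grid "
                                 f"{self.data.shape[:3]}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    def copy_with(self, data: np.ndarray) -> "VolumeSeries":
        return replace(self, data=data)


@dataclass(frozen=True)
class BandLimits:
    """Pass-band in Hz; the resting-state default is 0.01-0.1 Hz."""
    low_hz: float = 0.01
    high_hz: float = 0.1

    def __post_init__(self):
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError("need 0 <= low < high")


@dataclass(frozen=True)
class EntropyParams:
    """Sample-entropy settings for BOLD: template length m and tolerance
    r = r_factor * SD."""
    m: int = 3
    r_factor: float = 0.6

    def __post_init__(self):
        if self.m < 1 or self.r_factor <= 0:
            raise ValueError("need m >= 1 and r_factor > 0")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def bandpass_volume(v: VolumeSeries, band: BandLimits) -> VolumeSeries:
    """Frequency-domain boxcar band-pass, voxel means preserved.

    Fourier bins with ``low_hz <= f <= high_hz`` are kept, all others
    (including DC) are zeroed, and the original voxel mean is restored so
    that mean-normalised metrics (RSFA) remain defined.  The operation is
    idempotent.
    """
    x = v.data
    mean = x.mean(axis=-1, keepdims=True)
    freqs = np.fft.rfftfreq(v.n_frames, d=v.tr_seconds)
    keep = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    spec = np.fft.rfft(x, axis=-1)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=v.n_frames, axis=-1) + mean
    return v.copy_with(out)


def preprocess_bold(v: VolumeSeries, band: BandLimits = BandLimits(),
                    drop_initial: int = 0) -> VolumeSeries:
    """Initial-frame rejection, WM/CSF mean-signal regression, band-pass.

    The per-voxel regression uses an intercept plus the mean white-matter and
    mean CSF series as nuisance covariates; the voxel mean is restored after
    both regression and filtering.
    """
    if v.n_frames - drop_initial < 8:
        raise ValueError(f"only {v.n_frames - drop_initial} frames would remain "
                         f"after dropping {drop_initial}; need >= 8")
    data = v.data[..., drop_initial:]
    for name in ("white", "csf"):
        if name not in v.masks or not v.masks[name].any():
            raise ValueError(f"preprocessing requires a non-empty '{name}' mask")
    t = data.shape[-1]
    wm = data[v.masks["white"]].mean(axis=0)
    csf = data[v.masks["csf"]].mean(axis=0)
    design = np.column_stack([np.ones(t), wm - wm.mean(), csf - csf.mean()])
    flat = data.reshape(-1, t)
    beta, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
    resid = flat - (design @ beta).T
    mean = flat.mean(axis=1, keepdims=True)
    cleaned = (resid + mean).reshape(data.shape)
    out = replace(v, data=cleaned)
    return bandpass_volume(out, band)


def drop_initial_frames(v: VolumeSeries, n: int) -> VolumeSeries:
    """Reject the first ``n`` frames (steady-state settling)."""
    if v.n_frames - n < 2:
        raise ValueError("too few frames would remain")
    return v.copy_with(v.data[..., n:])


def smooth_volume(v: VolumeSeries, sigma_voxels: float) -> VolumeSeries:
    """Optional spatial Gaussian smoothing, sigma in voxels (frame-wise).

    Off (sigma 0) by default: on a unitless synthetic grid a physical FWHM
    has no meaning, so smoothing is an explicit opt-in for data with known
    voxel size.
    """
    if sigma_voxels < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_voxels == 0:
        return v.copy_with(v.data.copy())
    from scipy.ndimage import gaussian_filter
    out = gaussian_filter(v.data, sigma=(sigma_voxels,) * 3 + (0,))
    return v.copy_with(out)


# ---------------------------------------------------------------------------
# per-voxel metrics
# ---------------------------------------------------------------------------

def compute_rsfa(v: VolumeSeries, mask: np.ndarray | None = None) -> np.ndarray:
    """Resting-state fluctuation amplitude: temporal SD / temporal mean.

    Voxels with non-positive mean are flagged as NaN rather than raising.
    Returns a 3-D map (NaN outside ``mask`` when given).
    """
    x = v.data
    mean = x.mean(axis=-1)
    sd = x.std(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean > 0, sd / mean, np.nan)
    if mask is not None:
        out = np.where(mask, out, np.nan)
    return out


def _standardized_rows(series: np.ndarray) -> np.ndarray:
    """Rows scaled so that ``z @ z.T`` is the Pearson correlation matrix.

    Constant rows are mapped to zero vectors: a constant series correlates
    with nothing (documented convention for degenerate synthetic voxels).
    """
    z = series - series.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    nz = sd[:, 0] > 0
    z[nz] /= sd[nz] * np.sqrt(series.shape[1])
    z[~nz] = 0.0
    if (~nz).any():
        log.info("constant series at %d voxel(s) treated as uncorrelated", int((~nz).sum()))
    return z


def compute_gfcd(v: VolumeSeries, threshold: float = 0.6,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Global FC density: per voxel, the number of other gray-matter voxels
    whose series correlate with it at r >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    mask = v.masks["gray"] if mask is None else mask
    if not mask.any():
        raise ValueError("gray-matter mask is empty")
    z = _standardized_rows(v.data[mask])
    corr = z @ z.T
    counts = (corr >= threshold).sum(axis=1)
    # subtract the self-correlation where it passed the threshold
    counts -= (np.diag(corr) >= threshold).astype(int)
    out = np.full(v.grid_shape, np.nan)
    out[mask] = counts
    return out


_FACE_NEIGHBOURS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                             [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def compute_lfcd(v: VolumeSeries, threshold: float = 0.6,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Local FC density via 6-connectivity cluster growth.

    From each index voxel the cluster grows by repeatedly adding gray-matter
    voxels face-adjacent to a cluster member whose series correlates with the
    *index* voxel at r >= threshold; the count excludes the index voxel.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    mask = v.masks["gray"] if mask is None else mask
    if not mask.any():
        raise ValueError("gray-matter mask is empty")
    coords = np.argwhere(mask)
    index_of = {tuple(c): k for k, c in enumerate(coords)}
    z = _standardized_rows(v.data[mask])
    corr = z @ z.T
    n = len(coords)
    counts = np.zeros(n, dtype=int)
    neighbours = [
        [index_of[t] for t in (tuple(c + d) for d in _FACE_NEIGHBOURS) if t in index_of]
        for c in coords
    ]
    for i in range(n):
        ok = corr[i] >= threshold
        in_cluster = np.zeros(n, dtype=bool)
        in_cluster[i] = True
        queue = deque([i])
        while queue:
            j = queue.popleft()
            for k in neighbours[j]:
                if not in_cluster[k] and ok[k]:
                    in_cluster[k] = True
                    queue.append(k)
        counts[i] = in_cluster.sum() - 1
    out = np.full(v.grid_shape, np.nan)
    out[mask] = counts
    return out


def compute_bold_entropy(v: VolumeSeries, params: EntropyParams = EntropyParams(),
                         mask: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel sample entropy of the BOLD series (Chebyshev distance,
    self-matches excluded); constant series yield 0, too-short series NaN."""
    mask = v.masks["gray"] if mask is None else mask
    series = v.data[mask]
    vals = np.array([sample_entropy(s, m=params.m, r_factor=params.r_factor)
                     for s in series])
    out = np.full(v.grid_shape, np.nan)
    out[mask] = vals
    return out


def _network_seeds(atlas: np.ndarray) -> dict:
    """Default seeds: the in-network voxel nearest each network centroid."""
    seeds = {}
    for nid in np.unique(atlas[atlas > 0]):
        coords = np.argwhere(atlas == nid)
        centroid = coords.mean(axis=0)
        seeds[int(nid)] = tuple(coords[np.argmin(((coords - centroid) ** 2).sum(axis=1))])
    return seeds


def compute_seed_fc(v: VolumeSeries, atlas: np.ndarray,
                    seeds: dict | None = None) -> dict:
    """Seed-based network FC: mean Fisher-z correlation of network voxels
    with the seed series (seed voxels excluded from the average).

    ``seeds`` maps network id to a voxel coordinate tuple or a boolean mask;
    defaults to network centroids.  Fisher z is capped at |r| = 0.999.
    Networks with no non-seed voxels return NaN.
    """
    if seeds is None:
        seeds = _network_seeds(atlas)
    out = {}
    for nid, seed in seeds.items():
        net_mask = atlas == nid
        if not net_mask.any():
            out[int(nid)] = np.nan
            continue
        seed_mask = np.zeros_like(net_mask)
        if isinstance(seed, np.ndarray) and seed.dtype == bool:
            seed_mask = seed
        else:
            seed_mask[tuple(seed)] = True
        seed_series = v.data[seed_mask].mean(axis=0)
        targets = net_mask & ~seed_mask
        if not targets.any():
            out[int(nid)] = np.nan
            continue
        z = _standardized_rows(v.data[targets])
        s = seed_series - seed_series.mean()
        sd = s.std()
        if sd == 0:
            out[int(nid)] = np.nan
            continue
        s /= sd * np.sqrt(len(s))
        r = np.clip(z @ s, -FISHER_R_CAP, FISHER_R_CAP)
        out[int(nid)] = float(np.arctanh(r).mean())
    return out


# ---------------------------------------------------------------------------
# network reduction
# ---------------------------------------------------------------------------

def summarize_network(metric_map: np.ndarray, atlas: np.ndarray,
                      log_transform: bool = False) -> pd.DataFrame:
    """Mean of a per-voxel metric over each network's voxels.

    Density-like metrics (gFCD/lFCD) follow roughly exponential distributions,
    so ``log_transform`` applies log(1 + x) voxel-wise *before* averaging.
    Missing (NaN) voxels are excluded; an all-missing network yields NaN.
    """
    if metric_map.shape != atlas.shape:
        raise ValueError("metric map and atlas shapes differ")
    rows = []
    for nid in np.unique(atlas[atlas > 0]):
        vals = metric_map[atlas == nid]
        vals = vals[np.isfinite(vals)]
        if log_transform:
            vals = np.log1p(vals)
        rows.append({"network": int(nid),
                     "value": float(vals.mean()) if vals.size else np.nan})
    return pd.DataFrame(rows)


def fmri_network_metrics(v: VolumeSeries, atlas: np.ndarray,
                         threshold: float = 0.6,
                         entropy_params: EntropyParams = EntropyParams(),
                         seeds: dict | None = None,
                         metrics: tuple = FMRI_METRICS) -> pd.DataFrame:
    """Network-wise values of the requested fMRI metrics on a preprocessed
    volume.  Returns long-format rows (network, metric, value)."""
    gray = v.masks.get("gray", atlas > 0)
    frames = []
    if "rsfa" in metrics:
        df = summarize_network(compute_rsfa(v, mask=gray), atlas)
        frames.append(df.assign(metric="rsfa"))
    if "gfcd" in metrics:
        df = summarize_network(compute_gfcd(v, threshold, mask=gray), atlas,
                               log_transform=True)
        frames.append(df.assign(metric="gfcd"))
    if "lfcd" in metrics:
        df = summarize_network(compute_lfcd(v, threshold, mask=gray), atlas,
                               log_transform=True)
        frames.append(df.assign(metric="lfcd"))
    if "entropy" in metrics:
        df = summarize_network(compute_bold_entropy(v, entropy_params, mask=gray), atlas)
        frames.append(df.assign(metric="entropy"))
    if "seed_fc" in metrics:
        fc = compute_seed_fc(v, atlas, seeds=seeds)
        frames.append(pd.DataFrame({"network": list(fc), "value": list(fc.values()),
                                    "metric": "seed_fc"}))
    return pd.concat(frames, ignore_index=True)[["network", "metric", "value"]]
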