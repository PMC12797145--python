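"""Seeded synthetic EEG/BOLD cohort generation.

The generator emulates the statistical structure the association analysis
assumes: per-participant latent neuronal amplitudes per network that are
expressed in *both* modalities, a hemodynamically low-passed BOLD response to
the driver envelope, a lagged and spatially decaying venous confound around a
synthetic vessel tree, and a binary sex covariate that modulates the
EEG-fMRI coupling strength.

Two levels are exposed:

* the full volumetric generator (:func:`make_cohort`) producing paired
  4-D BOLD volumes and source-space EEG with injectable macrovascular
  confound and recorded ground truth;
* a metric-level generator (:func:`simulate_metric_tables`) that draws
  network-wise metric observations directly from the participant-level
  coupling model ``Y = beta * X + beta_sex * Sex + gamma * X:Sex + u_p + e`` —
  the statistical skeleton the volumetric cohort inherits — for fast,
  exactly-parameterized tests of the association stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import distance_transform_edt
from scipy.stats import gamma as gamma_dist

from .eeg_metrics import BANDS, SourceSignalSet
from .fmri_metrics import VolumeSeries

__all__ = [
    "SimulationConfig",
    "VesselModel",
    "GroundTruth",
    "Participant",
    "Cohort",
    "make_atlas",
    "make_vessel_model",
    "make_neuronal_drivers",
    "render_bold",
    "make_eeg",
    "inject_macrovascular_confound",
    "make_cohort",
    "simulate_metric_tables",
    "COUPLED_PAIR",
]

#: relative band-power weights of the neuronal driver mixture (alpha carries
#: half the oscillatory power)
BAND_WEIGHTS = {"delta": 0.15, "theta": 0.15, "alpha": 0.50,
                "beta": 0.12, "gamma": 0.08}

#: the metric pair that carries the injected ground-truth coupling:
#: network RSFA (fMRI) against normalized total EEG power — both are
#: monotone images of the latent neuronal amplitude
COUPLED_PAIR = ("rsfa", "total_power")

#: baseline BOLD intensity and relative fluctuation amplitude (~2 % of
#: baseline, typical of resting-state gray matter at 3 T)
BOLD_BASELINE = 100.0
BOLD_REL_FLUCT = 0.02


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings.

    Counts/durations default to the study design being emulated: 20
    participants, 7 networks, TR = 4.5 s with 53 volumes from a 4-minute run,
    EEG at 125 Hz for 240 s.
    """

    n_participants: int = 20
    n_networks: int = 7
    voxels_per_network: int = 27          # 3x3x3 blobs
    grid_size: int = 16
    tr_seconds: float = 4.5
    n_volumes: int = 53                    # floor(240 / 4.5)
    eeg_rate_hz: float = 125.0
    eeg_duration_s: float = 240.0
    sources_per_network: int = 3
    coupling_beta: float = 0.5             # latent -> BOLD amplitude slope (log scale)
    sex_interaction: float = 0.3           # X:Sex modulation of the coupling
    sex_main: float = 0.2                  # additive Sex effect (metric-level model)
    confound_amplitude: float = 1.5        # venous gain relative to neuronal fluct.
    confound_decay: float = 3.0            # perivascular decay length (voxels)
    max_confound_lag: int = 3              # frames
    noise_sd: float = 1.0                  # voxel/metric noise relative to signal
    eeg_amp_gain: float = 0.4              # latent -> EEG amplitude slope (log scale)
    eeg_source_noise: float = 0.3
    noise_floor: float = 0.05              # broadband driver noise floor (RMS)
    master_seed: int = 0

    def validate(self) -> "SimulationConfig":
        for name in ("n_participants", "n_networks", "voxels_per_network",
                     "grid_size", "n_volumes", "sources_per_network"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.confound_amplitude < 0:
            raise ValueError("confound_amplitude must be >= 0")
        if self.eeg_rate_hz <= 2 * max(b[1] for b in BANDS.values()):
            raise ValueError("eeg_rate_hz must exceed twice the highest band edge (50 Hz)")
        if self.n_volumes * self.tr_seconds > self.eeg_duration_s + 1e-9:
            raise ValueError("drivers do not cover the scan: n_volumes * tr exceeds "
                             "eeg_duration_s")
        if self.max_confound_lag >= self.n_volumes / 4:
            raise ValueError("max_confound_lag too large for the series length")
        return self

    @property
    def n_eeg_samples(self) -> int:
        return int(round(self.eeg_duration_s * self.eeg_rate_hz))


@dataclass
class VesselModel:
    """Synthetic vessel tree: boolean mask, fBV in [0, 1] (zero outside a
    dilation of the mask) and the Euclidean distance-to-vessel map."""
    mask: np.ndarray
    fbv: np.ndarray
    distance: np.ndarray


@dataclass
class GroundTruth:
    """Everything injected into a cohort, for recovery checks."""
    config: SimulationConfig
    sex: np.ndarray                        # +1 male / -1 female, balanced
    latent: np.ndarray                     # (participants, networks)
    bold_gain: np.ndarray                  # (participants, networks)
    references: list = field(default_factory=list)      # per-participant venous series
    confound_gain: np.ndarray | None = None             # per-participant scaling
    confound_amp_map: np.ndarray | None = None          # per-voxel amplitude
    confound_lag_map: np.ndarray | None = None          # per-voxel lag (frames)


@dataclass
class Participant:
    pid: int
    volume: VolumeSeries
    eeg: SourceSignalSet


@dataclass
class Cohort:
    participants: list
    truth: GroundTruth
    atlas: np.ndarray


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _blob_centres(g: int):
    """Seven compact network locations: four flank the vessel tree (so the
    confound reaches them), three sit far from it."""
    return [
        (g * 5 // 16, g // 2, g * 3 // 16),
        (g * 11 // 16, g // 2, g * 5 // 16),
        (g * 5 // 16, g // 2, g * 11 // 16),
        (g * 11 // 16, g // 2, g * 12 // 16),
        (g * 2 // 16, g * 2 // 16, g * 2 // 16),
        (g * 13 // 16, g * 2 // 16, g * 13 // 16),
        (g * 2 // 16, g * 13 // 16, g * 13 // 16),
    ]


def make_atlas(config: SimulationConfig) -> np.ndarray:
    """Integer-labelled network atlas: compact cubes, labels 1..n_networks,
    0 = background."""
    g = config.grid_size
    half = max(1, round(config.voxels_per_network ** (1 / 3)) // 2)
    atlas = np.zeros((g, g, g), dtype=np.uint16)
    centres = _blob_centres(g)
    if config.n_networks > len(centres):
        raise ValueError(f"at most {len(centres)} networks supported by the geometry")
    for nid in range(1, config.n_networks + 1):
        cx, cy, cz = centres[nid - 1]
        sl = tuple(slice(max(0, c - half), min(g, c + half + 1)) for c in (cx, cy, cz))
        atlas[sl] = nid
    return atlas


def make_vessel_model(config: SimulationConfig) -> VesselModel:
    """A vessel tree (vertical trunk plus one branch) with an fBV map that
    peaks uniquely on the trunk and decays to zero beyond a 2-voxel
    dilation."""
    g = config.grid_size
    mask = np.zeros((g, g, g), dtype=bool)
    c = g // 2
    mask[c, c, :] = True                       # trunk along z
    mask[g // 4: 3 * g // 4, c, c] = True      # branch along x
    dist = distance_transform_edt(~mask)
    fbv = np.zeros((g, g, g))
    # on-vessel fBV rises along z so the maximum is unique (tie-break tested
    # separately); perivascular fBV decays and is clipped at the dilation edge
    zz = np.arange(g) / max(g - 1, 1)
    trunk = np.zeros((g, g, g))
    trunk[c, c, :] = 0.5 + 0.3 * zz
    fbv[mask] = np.maximum(0.5, trunk[mask])
    peri = (~mask) & (dist <= 2.0)
    fbv[peri] = 0.3 * np.exp(-dist[peri])
    return VesselModel(mask=mask, fbv=fbv, distance=dist)


def make_tissue_masks(config: SimulationConfig, atlas: np.ndarray,
                      vessel: VesselModel) -> dict:
    """Gray = atlas networks; white and CSF are fixed off-network blocks."""
    g = config.grid_size
    gray = atlas > 0
    white = np.zeros_like(gray)
    white[g * 6 // 16: g * 10 // 16, g // 16: g * 4 // 16, g * 5 // 16: g * 9 // 16] = True
    csf = np.zeros_like(gray)
    csf[g * 12 // 16: g * 15 // 16, g * 12 // 16: g * 15 // 16, g * 2 // 16: g * 5 // 16] = True
    white &= ~gray & ~vessel.mask
    csf &= ~gray & ~vessel.mask & ~white
    return {"gray": gray, "white": white, "csf": csf, "vessel": vessel.mask}


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _bandlimited_noise(rng: np.random.Generator, n: int, rate: float,
                       low: float, high: float) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to [low, high] Hz (FFT boxcar)."""
    x = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec = np.fft.rfft(x)
    spec[(freqs < low) | (freqs > high)] = 0.0
    out = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(out ** 2))
    return out / rms if rms > 0 else out


def make_neuronal_drivers(config: SimulationConfig, participant_seed: int,
                          latent: np.ndarray | None = None,
                          amplitude: np.ndarray | None = None):
    """Per-network neuronal drivers at the EEG rate.

    Each driver is ``A_n * mixture + noise_floor * white`` where the mixture
    is a sum of band-limited Gaussian oscillations with RMS weights
    ``sqrt(BAND_WEIGHTS)`` (so band powers follow the weights) and the
    amplitude ``A_n = exp(eeg_amp_gain * latent_n)`` carries the
    participant-level latent neuronal variable.  ``amplitude`` overrides the
    lognormal link directly (0 gives a pure noise-floor driver).

    Returns (drivers with shape (n_networks, n_samples), latent used).
    """
    config.validate()
    rng = np.random.default_rng(participant_seed)
    n = config.n_eeg_samples
    if latent is None:
        latent = rng.standard_normal(config.n_networks)
    latent = np.asarray(latent, dtype=float)
    amp = (np.exp(config.eeg_amp_gain * latent) if amplitude is None
           else np.broadcast_to(np.asarray(amplitude, dtype=float),
                                (config.n_networks,)))
    drivers = np.empty((config.n_networks, n))
    for k in range(config.n_networks):
        mix = np.zeros(n)
        for band, w in BAND_WEIGHTS.items():
            low, high = BANDS[band]
            mix += np.sqrt(w) * _bandlimited_noise(rng, n, config.eeg_rate_hz, low, high)
        drivers[k] = amp[k] * mix + config.noise_floor * rng.standard_normal(n)
    return drivers, latent


def _hrf_kernel(dt: float = 1.0, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic kernel (peak 6 s, undershoot 16 s,
    undershoot ratio 1/6), unit sum."""
    t = np.arange(0, duration, dt)
    h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    return h / h.sum()


def _driver_envelope_frames(driver: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Rectified driver envelope convolved with the hemodynamic kernel and
    resampled to the TR grid (frame value at the frame centre), standardized
    to zero mean / unit SD."""
    rate = config.eeg_rate_hz
    sec = int(config.eeg_duration_s)
    env = np.abs(driver)
    n1 = sec * int(rate)
    env_1hz = env[:n1].reshape(sec, int(rate)).mean(axis=1)
    hrf = _hrf_kernel(dt=1.0)
    bold_1hz = sps.fftconvolve(env_1hz, hrf, mode="full")[:sec]
    t_frames = (np.arange(config.n_volumes) + 0.5) * config.tr_seconds
    frames = np.interp(t_frames, np.arange(sec) + 0.5, bold_1hz)
    frames = frames - frames.mean()
    sd = frames.std()
    return frames / sd if sd > 0 else frames


def _venous_reference(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Slow venous waveform on the TR grid: < 0.1 Hz filtered noise plus a
    respiratory-band (0.3 Hz) component sampled at the TR (it aliases into
    the pass-band, as real physiological oscillations do).  Unit SD."""
    sec = int(config.eeg_duration_s)
    slow = _bandlimited_noise(rng, sec, 1.0, 0.0, 0.1)
    t_frames = (np.arange(config.n_volumes) + 0.5) * config.tr_seconds
    phase = rng.uniform(0, 2 * np.pi)
    ref = np.interp(t_frames, np.arange(sec) + 0.5, slow) \
        + 0.4 * np.sin(2 * np.pi * 0.3 * t_frames + phase)
    ref = ref - ref.mean()
    sd = ref.std()
    return ref / sd if sd > 0 else ref


def render_bold(drivers: np.ndarray, atlas: np.ndarray, config: SimulationConfig,
                participant_seed: int, gains: np.ndarray | None = None,
                vessel: VesselModel | None = None):
    """Render a participant's 4-D BOLD volume from the network drivers.

    Every in-network voxel receives its network's hemodynamic envelope scaled
    by ``gains[network]`` plus independent voxel noise; white-matter and CSF
    blocks carry their own shared slow signals; vessel voxels carry a strong
    venous waveform (returned for confound injection and recovery checks).

    Returns (VolumeSeries, VesselModel, venous reference on the TR grid).
    """
    config.validate()
    if drivers.shape[0] != config.n_networks:
        raise ValueError(f"expected {config.n_networks} drivers, got {drivers.shape[0]}")
    if int(atlas.max()) > config.n_networks:
        raise ValueError("atlas labels exceed the configured network count")
    rng = np.random.default_rng(participant_seed)
    if gains is None:
        gains = np.ones(config.n_networks)
    if vessel is None:
        vessel = make_vessel_model(config)
    masks = make_tissue_masks(config, atlas, vessel)
    t = config.n_volumes
    shape = (*atlas.shape, t)
    fluct = np.zeros(shape)

    env = np.array([_driver_envelope_frames(d, config) for d in drivers])
    for nid in range(1, config.n_networks + 1):
        sel = atlas == nid
        nvox = int(sel.sum())
        if nvox == 0:
            continue
        noise = config.noise_sd * rng.standard_normal((nvox, t))
        fluct[sel] = gains[nid - 1] * env[nid - 1][None, :] + noise

    vref = _venous_reference(rng, config)
    for name, common_gain in (("white", 0.6), ("csf", 0.8)):
        sel = masks[name]
        shared = _bandlimited_noise(rng, t, 1.0 / config.tr_seconds, 0.0, 0.08)
        fluct[sel] = common_gain * shared[None, :] \
            + config.noise_sd * rng.standard_normal((int(sel.sum()), t))
    background = ~(masks["gray"] | masks["white"] | masks["csf"] | vessel.mask)
    fluct[background] = config.noise_sd * rng.standard_normal((int(background.sum()), t))
    fluct[vessel.mask] = 2.0 * vref[None, :] \
        + 0.1 * rng.standard_normal((int(vessel.mask.sum()), t))

    data = BOLD_BASELINE * (1.0 + BOLD_REL_FLUCT * fluct)
    vol = VolumeSeries(data=data, tr_seconds=config.tr_seconds, masks=masks,
                       fbv=vessel.fbv)
    return vol, vessel, vref


def make_eeg(drivers: np.ndarray, config: SimulationConfig,
             participant_seed: int) -> SourceSignalSet:
    """Source-space EEG: each network contributes ``sources_per_network``
    sources carrying the network driver at small per-source sample lags
    (yielding non-zero imaginary coherence) plus independent sensor noise."""
    rng = np.random.default_rng(participant_seed)
    rows, labels = [], []
    for nid in range(1, config.n_networks + 1):
        d = drivers[nid - 1]
        for k in range(config.sources_per_network):
            rows.append(np.roll(d, 2 * k)
                        + config.eeg_source_noise * rng.standard_normal(d.shape[0]))
            labels.append(nid)
    return SourceSignalSet(np.array(rows), config.eeg_rate_hz, np.array(labels))


# ---------------------------------------------------------------------------
# confound injection
# ---------------------------------------------------------------------------

def confound_field(vessel: VesselModel, config: SimulationConfig):
    """Per-voxel confound amplitude (exponential decay with distance from the
    vessel at scale ``confound_decay``, cut at 4 decay lengths) and integer
    lag growing with distance, capped at ``max_confound_lag``."""
    d = vessel.distance
    amp = config.confound_amplitude * np.exp(-d / config.confound_decay)
    amp[d > 4 * config.confound_decay] = 0.0
    lag = np.minimum(config.max_confound_lag, (d // 2).astype(int))
    lag[amp == 0] = 0
    return amp, lag


def inject_macrovascular_confound(volume: VolumeSeries, vessel: VesselModel,
                                  reference: np.ndarray, config: SimulationConfig,
                                  gain: float = 1.0):
    """Add ``amp(v) * gain * reference(t - lag(v))`` (in BOLD fluctuation
    units) to each voxel.  With ``confound_amplitude = 0`` the output equals
    the input exactly.  Returns (new VolumeSeries, amplitude map, lag map)."""
    from .correction import shift_series  # local import avoids a cycle

    if config.max_confound_lag >= volume.n_frames:
        raise ValueError("confound lag exceeds the series length")
    amp, lag = confound_field(vessel, config)
    if config.confound_amplitude == 0:
        return volume.copy_with(volume.data.copy()), amp, lag
    data = volume.data.copy()
    for lv in np.unique(lag[amp > 0]):
        sref = shift_series(reference, int(lv))
        sel = (lag == lv) & (amp > 0)
        data[sel] += BOLD_BASELINE * BOLD_REL_FLUCT * gain \
            * amp[sel][:, None] * sref[None, :]
    return volume.copy_with(data), amp, lag


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _participant_seeds(master_seed: int, n: int, streams: int = 4) -> np.ndarray:
    """Deterministic per-participant, per-stream seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n * streams, dtype=np.uint64)
            .reshape(n, streams) % (2 ** 31)).astype(np.int64)


def balanced_sex(n: int) -> np.ndarray:
    """+1 (male) / -1 (female), balanced when n is even."""
    return np.array([1 if i % 2 == 0 else -1 for i in range(n)])


def make_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full synthetic cohort with recorded ground truth.

    Identical configs (including ``master_seed``) give bit-identical output.
    """
    config.validate()
    atlas = make_atlas(config)
    vessel = make_vessel_model(config)
    seeds = _participant_seeds(config.master_seed, config.n_participants)
    sex = balanced_sex(config.n_participants)
    cohort_rng = np.random.default_rng(int(seeds[0, 3]) ^ 0x5EED)
    latent = cohort_rng.standard_normal((config.n_participants, config.n_networks))
    gains = np.exp(config.coupling_beta * latent
                   * (1.0 + config.sex_interaction * sex[:, None]))
    confound_gain = np.exp(0.5 * cohort_rng.standard_normal(config.n_participants))
    truth = GroundTruth(config=config, sex=sex, latent=latent, bold_gain=gains,
                        confound_gain=confound_gain)
    participants = []
    for p in range(config.n_participants):
        drivers, _ = make_neuronal_drivers(config, int(seeds[p, 0]), latent=latent[p])
        vol, _, vref = render_bold(drivers, atlas, config, int(seeds[p, 1]),
                                   gains=gains[p], vessel=vessel)
        truth.references.append(vref)
        vol, amp_map, lag_map = inject_macrovascular_confound(
            vol, vessel, vref, config, gain=float(confound_gain[p]))
        truth.confound_amp_map, truth.confound_lag_map = amp_map, lag_map
        eeg = make_eeg(drivers, config, int(seeds[p, 2]))
        participants.append(Participant(pid=p, volume=vol, eeg=eeg))
    return Cohort(participants=participants, truth=truth, atlas=atlas)


# ---------------------------------------------------------------------------
# metric-level generator
# ---------------------------------------------------------------------------

def simulate_metric_tables(config: SimulationConfig, seed: int,
                           x_metrics: tuple = None, y_metrics: tuple = None,
                           state: str = "pre"):
    """Draw network-wise metric tables directly from the participant-level
    coupling model.

    For the coupled pair ``Y = coupling_beta * X + sex_main * Sex +
    sex_interaction * X * Sex + u_p + noise_sd * e`` with ``X`` standard
    normal (participant + network components) and participant intercepts
    ``u_p ~ N(0, 0.5^2)``.  All other metrics are independent noise with their
    own participant intercepts.  Returns (fmri table, eeg table, sex labels
    DataFrame) in the long MetricTable schema.
    """
    from .association import DEFAULT_X_METRICS, DEFAULT_Y_METRICS

    config.validate()
    x_metrics = DEFAULT_X_METRICS if x_metrics is None else x_metrics
    y_metrics = DEFAULT_Y_METRICS if y_metrics is None else y_metrics
    rng = np.random.default_rng(seed)
    n_p, n_n = config.n_participants, config.n_networks
    sex = balanced_sex(n_p)
    y_cpl, x_cpl = COUPLED_PAIR

    def latent_field():
        return (0.5 * rng.standard_normal((n_p, 1))
                + np.sqrt(1 - 0.25) * rng.standard_normal((n_p, n_n)))

    x_val = {m: latent_field() for m in x_metrics}
    u = 0.5 * rng.standard_normal((n_p, 1))
    y_val = {}
    for m in y_metrics:
        if m == y_cpl and x_cpl in x_val:
            x = x_val[x_cpl]
            y_val[m] = (config.coupling_beta * x
                        + config.sex_main * sex[:, None]
                        + config.sex_interaction * x * sex[:, None]
                        + u + config.noise_sd * rng.standard_normal((n_p, n_n)))
        else:
            y_val[m] = (0.5 * rng.standard_normal((n_p, 1))
                        + rng.standard_normal((n_p, n_n)))

    def long(values: dict) -> pd.DataFrame:
        rows = []
        for m, grid in values.items():
            for p in range(n_p):
                for n in range(n_n):
                    rows.append((p, n + 1, m, state, grid[p, n]))
        return pd.DataFrame(rows, columns=["participant", "network", "metric",
                                           "state", "value"])

    sex_df = pd.DataFrame({"participant": np.arange(n_p), "sex": sex})
    return long(y_val), long(x_val), sex_df
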