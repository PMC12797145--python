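"""EEG metrics: spectral closed forms, imaginary-coherence identities,
band-averaging oracles, and complexity-index ordering properties."""

import numpy as np
import pandas as pd
import pytest

from eegfmri.eeg_metrics import (BANDS, MseParams, SourceSignalSet,
                                 band_bins, band_coherence,
                                 compute_complexity_index,
                                 compute_cross_spectrum,
                                 compute_fractional_power,
                                 compute_imaginary_coherence,
                                 compute_total_power, detrend_sources,
                                 eeg_network_metrics, network_coherence)
from eegfmri.entropy import coarse_grain, sample_entropy

from _oracles import naive_band_means

RATE = 125.0


def _sset(rows, networks=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    networks = networks if networks is not None else np.ones(rows.shape[0], int)
    return SourceSignalSet(rows, RATE, np.asarray(networks))


def _t(n=int(RATE * 40)):
    return np.arange(n) / RATE


# -- detrending -------------------------------------------------------------

def test_detrend_ramp_to_zero():
    ramp = 3.0 + 0.5 * np.arange(1000)
    out = detrend_sources(_sset([ramp])).data[0]
    assert np.abs(out).max() < 1e-9


def test_detrend_recovers_sinusoid():
    t = _t()
    sig = np.sin(2 * np.pi * 5 * t)
    # construction oracle: project the tone off {1, t} so the added ramp is
    # exactly the non-oscillatory part
    design = np.column_stack([np.ones(t.size), t])
    sig = sig - design @ np.linalg.lstsq(design, sig, rcond=None)[0]
    out = detrend_sources(_sset([sig + 2.0 + 0.3 * t])).data[0]
    assert np.abs(out - sig).max() < 1e-6 * np.abs(sig).max()


# -- fractional power -------------------------------------------------------

def test_pure_alpha_tone():
    t = _t()
    frac = compute_fractional_power(_sset([np.sin(2 * np.pi * 10 * t)]))
    assert frac.loc[0, "alpha"] > 0.99
    assert all(frac.loc[0, b] < 0.01 for b in BANDS if b != "alpha")


def test_two_equal_tones_split():
    t = _t()
    sig = np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 40 * t)
    frac = compute_fractional_power(_sset([sig]))
    assert frac.loc[0, "delta"] == pytest.approx(0.5, abs=0.01)
    assert frac.loc[0, "gamma"] == pytest.approx(0.5, abs=0.01)


def test_fractions_sum_to_one(rng):
    s = _sset(rng.standard_normal((4, 5000)))
    frac = compute_fractional_power(s)
    np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-6)


def test_white_noise_fractions_follow_bin_counts():
    """Flat-spectrum oracle: expected fraction = band bin count / total bins."""
    freqs = np.arange(0, RATE / 2 + 0.5, 0.5)
    total_bins = ((freqs >= 1) & (freqs <= 50)).sum()
    got = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        frac = compute_fractional_power(_sset(rng.standard_normal((1, 10000))))
        got.append(frac.iloc[0])
    mean = pd.DataFrame(got).mean()
    for band in BANDS:
        expected = band_bins(freqs, band).sum() / total_bins
        assert mean[band] == pytest.approx(expected, abs=0.01)


# -- total power ------------------------------------------------------------

def test_total_power_population_sd_convention(rng):
    """Two sources with raw totals {p, 3p} have population SD p -> {1, 3}."""
    t = _t()
    a = np.sin(2 * np.pi * 10 * t)
    b = np.sqrt(3.0) * np.sin(2 * np.pi * 20 * t)
    out = compute_total_power(_sset([a, b]))
    assert out[0] == pytest.approx(1.0, abs=0.02)
    assert out[1] == pytest.approx(3.0, abs=0.05)


def test_total_power_degenerate_and_scale_invariant(rng):
    t = _t()
    same = np.sin(2 * np.pi * 10 * t)
    assert np.isnan(compute_total_power(_sset([same, same]))).all()
    x = rng.standard_normal((3, 4000))
    np.testing.assert_allclose(compute_total_power(_sset(x)),
                               compute_total_power(_sset(5.0 * x)), rtol=1e-10)


# -- cross-spectrum & imaginary coherence -----------------------------------

def test_autospectrum_identity(rng):
    u = rng.standard_normal(4000)
    sm = compute_cross_spectrum(u, u, RATE)
    assert np.abs(np.imag(sm.s_uv)).max() < 1e-12
    np.testing.assert_allclose(np.real(sm.s_uv), sm.s_uu, rtol=1e-10)
    assert (sm.s_uu >= 0).all()


def test_cross_spectrum_peaks_at_tone(rng):
    t = _t()
    tone = np.sin(2 * np.pi * 10 * t)
    sm = compute_cross_spectrum(tone, tone, RATE)
    assert sm.freqs[np.argmax(np.abs(sm.s_uv))] == pytest.approx(10.0)


def test_imcoh_identical_signals_zero(rng):
    u = rng.standard_normal(6000)
    imcoh = compute_imaginary_coherence(compute_cross_spectrum(u, u, RATE))
    assert np.nanmax(imcoh) < 1e-10


def test_imcoh_quadrature_pair(rng):
    t = _t()
    u = np.sin(2 * np.pi * 10 * t) + 0.05 * rng.standard_normal(t.size)
    v = np.cos(2 * np.pi * 10 * t) + 0.05 * rng.standard_normal(t.size)
    sm = compute_cross_spectrum(u, v, RATE)
    imcoh = compute_imaginary_coherence(sm)
    assert imcoh[sm.freqs == 10.0][0] >= 0.95
    assert np.nanmin(imcoh) >= 0 and np.nanmax(imcoh) <= 1


def test_imcoh_symmetry(rng):
    u, v = rng.standard_normal((2, 4000))
    a = compute_imaginary_coherence(compute_cross_spectrum(u, v, RATE))
    b = compute_imaginary_coherence(compute_cross_spectrum(v, u, RATE))
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_zero_lag_mixtures_at_chance(rng):
    """Volume-conduction insensitivity: instantaneous mixtures of the same
    sources show no more ImCoh than phase-randomized surrogates."""
    n = 6000
    s1, s2 = rng.standard_normal((2, n))
    u = 0.7 * s1 + 0.3 * s2
    v = 0.4 * s1 + 0.6 * s2
    sm = compute_cross_spectrum(u, v, RATE)
    observed = np.nanmean(compute_imaginary_coherence(sm))
    null = []
    spec = np.fft.rfft(v)
    for _ in range(100):
        phases = np.exp(2j * np.pi * rng.uniform(size=spec.size))
        surr = np.fft.irfft(np.abs(spec) * phases, n=n)
        smn = compute_cross_spectrum(u, surr, RATE)
        null.append(np.nanmean(compute_imaginary_coherence(smn)))
    assert observed <= np.percentile(null, 97.5)


# -- band averaging ---------------------------------------------------------

def test_band_averaging_against_hand_oracle(rng):
    freqs = np.arange(0, 62.6, 0.5)
    spectrum = rng.uniform(size=freqs.size)
    got = band_coherence(spectrum, freqs)
    want = naive_band_means(spectrum, freqs, BANDS)
    for k in want:
        assert got[k] == pytest.approx(want[k], abs=1e-12)


def test_band_averaging_flat_and_single_band():
    freqs = np.arange(0, 62.6, 0.5)
    flat = band_coherence(np.full(freqs.size, 0.37), freqs)
    assert all(v == pytest.approx(0.37) for v in flat.values())
    alpha_only = np.where((freqs >= 8) & (freqs < 12), 0.8, 0.0)
    got = band_coherence(alpha_only, freqs)
    assert got["alpha"] == pytest.approx(0.8)
    assert got["delta"] == got["theta"] == got["beta"] == got["gamma"] == 0.0


# -- network coherence ------------------------------------------------------

def test_network_coherence_pair_and_triple(rng):
    x = rng.standard_normal((3, 4000))
    two = _sset(x[:2], networks=[1, 1])
    pair = network_coherence(two).set_index("network")
    sm = compute_cross_spectrum(x[0], x[1], RATE)
    want = band_coherence(compute_imaginary_coherence(sm), sm.freqs)
    assert pair.loc[1, "alpha"] == pytest.approx(want["alpha"], abs=1e-12)

    three = _sset(x, networks=[1, 1, 1])
    tri = network_coherence(three).set_index("network")
    acc = []
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        smp = compute_cross_spectrum(x[i], x[j], RATE)
        acc.append(band_coherence(compute_imaginary_coherence(smp), smp.freqs)["beta"])
    assert tri.loc[1, "beta"] == pytest.approx(np.mean(acc), abs=1e-12)


def test_source_order_invariance(rng):
    x = rng.standard_normal((4, 4000))
    nets = np.array([1, 1, 2, 2])
    a = eeg_network_metrics(_sset(x, nets), metrics=("power_alpha", "coh_alpha"))
    perm = [2, 0, 3, 1]
    b = eeg_network_metrics(_sset(x[perm], nets[perm]),
                            metrics=("power_alpha", "coh_alpha"))
    key = ["network", "metric"]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"))
    np.testing.assert_allclose(merged["value_a"], merged["value_b"], atol=1e-10)


# -- complexity index -------------------------------------------------------

def test_ci_constant_is_zero():
    p = MseParams(scales=(3, 6, 13))
    assert compute_complexity_index(np.full(2000, 4.0), p) == 0.0


def test_ci_insufficient_length_is_nan():
    assert np.isnan(compute_complexity_index(np.random.default_rng(0)
                                             .standard_normal(100)))


def test_white_noise_beats_ar1_at_scale_three():
    """At the finest scale, white noise is less predictable than AR(1)
    (phi = 0.95) of equal variance."""
    wins = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        n = 3000
        white = rng.standard_normal(n)
        ar = np.empty(n)
        ar[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - 0.95 ** 2)
        for i in range(1, n):
            ar[i] = 0.95 * ar[i - 1] + eps[i]
        def scale3_entropy(x):
            return sample_entropy(coarse_grain(x, 3), m=2, r=0.5 * np.std(x))
        if scale3_entropy(white) > scale3_entropy(ar):
            wins += 1
    assert wins >= 48
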