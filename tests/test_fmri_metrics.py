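"""fMRI metric operations: closed forms, brute-force oracle agreement, and
filter/regression identities."""

import numpy as np
import pandas as pd
import pytest

from eegfmri.fmri_metrics import (BandLimits, EntropyParams, VolumeSeries,
                                  bandpass_volume, compute_bold_entropy,
                                  compute_gfcd, compute_lfcd, compute_rsfa,
                                  compute_seed_fc, preprocess_bold,
                                  summarize_network)

from _oracles import naive_gfcd, naive_lfcd
from conftest import make_volume


def _toy_volume(rng, n_voxels=20, t=30, grid=(4, 4, 4), threshold_guard=True):
    """Random gray-matter toy whose correlations stay away from the 0.6
    threshold boundary (so exact count comparison is well-posed)."""
    while True:
        coords = [tuple(int(i) for i in np.unravel_index(c, grid)) for c in
                  rng.choice(np.prod(grid), size=n_voxels, replace=False)]
        base = rng.standard_normal(t)
        series = [base * rng.uniform(0.3, 1.5) + rng.standard_normal(t)
                  for _ in range(n_voxels)]
        if not threshold_guard:
            break
        rs = np.corrcoef(np.array(series))
        off = rs[~np.eye(n_voxels, dtype=bool)]
        if np.all(np.abs(off - 0.6) > 1e-6):
            break
    mask = np.zeros(grid, dtype=bool)
    data = np.zeros((*grid, t))
    for c, s in zip(coords, series):
        mask[c] = True
        data[c] = s
    v = VolumeSeries(data=data, tr_seconds=1.0, masks={"gray": mask})
    return v, mask, coords, series


# -- preprocessing ----------------------------------------------------------

def _tone_volume(f, t=64, tr=1.0):
    tt = np.arange(t) * tr
    series = 10.0 + np.sin(2 * np.pi * f * tt)
    masks = {"gray": np.zeros((2, 2, 2), dtype=bool),
             "white": np.zeros((2, 2, 2), dtype=bool),
             "csf": np.zeros((2, 2, 2), dtype=bool)}
    masks["white"][0, 0, 1] = True
    masks["csf"][0, 1, 0] = True
    # constant nuisance covariates: rank-deficient with the intercept, so the
    # regression step is exercised without injecting chance correlations
    v = make_volume({(0, 0, 0): series}, grid=(2, 2, 2), tr=tr, baseline=10.0,
                    masks=masks)
    return v


def test_bandpass_keeps_in_band_tone():
    v = _tone_volume(f=4 / 64)  # on-bin, inside 0.01-0.1 Hz
    out = preprocess_bold(v, BandLimits(0.01, 0.1))
    got = out.data[0, 0, 0] - out.data[0, 0, 0].mean()
    want = v.data[0, 0, 0] - 10.0
    assert np.abs(got).max() == pytest.approx(1.0, rel=0.01)
    assert np.corrcoef(got, want)[0, 1] > 0.999


def test_bandpass_removes_out_of_band_tone():
    v = _tone_volume(f=16 / 64)  # 0.25 Hz, outside the band
    out = preprocess_bold(v, BandLimits(0.01, 0.1))
    resid = out.data[0, 0, 0] - out.data[0, 0, 0].mean()
    assert np.abs(resid).max() < 0.01


def test_wm_regression_identity(rng):
    """A voxel equal to the WM mean signal is fully regressed out."""
    t = 40
    wm_sig = 5.0 + np.cumsum(rng.standard_normal(t)) * 0.1
    masks = {k: np.zeros((3, 3, 3), dtype=bool) for k in ("gray", "white", "csf")}
    masks["white"][0, 0, 1] = masks["white"][0, 0, 2] = True
    masks["csf"][0, 1, 0] = True
    v = make_volume({(0, 0, 1): wm_sig, (0, 0, 2): wm_sig,
                     (2, 2, 2): wm_sig,
                     (0, 1, 0): 5.0 + rng.standard_normal(t) * 0.1},
                    grid=(3, 3, 3), tr=1.0, baseline=5.0, masks=masks)
    out = preprocess_bold(v, BandLimits(0.01, 0.45))
    resid = out.data[2, 2, 2] - out.data[2, 2, 2].mean()
    assert np.abs(resid).max() < 1e-8


def test_bandpass_idempotent(rng):
    data = 100 + rng.standard_normal((3, 3, 3, 32))
    v = VolumeSeries(data=data, tr_seconds=2.0)
    once = bandpass_volume(v, BandLimits(0.01, 0.1))
    twice = bandpass_volume(once, BandLimits(0.01, 0.1))
    np.testing.assert_allclose(twice.data, once.data, atol=1e-10)


def test_preprocess_rejects_short_series(rng):
    v = VolumeSeries(data=100 + rng.standard_normal((2, 2, 2, 10)), tr_seconds=1.0,
                     masks={"white": np.ones((2, 2, 2), bool),
                            "csf": np.ones((2, 2, 2), bool)})
    with pytest.raises(ValueError, match="frames"):
        preprocess_bold(v, drop_initial=5)


# -- RSFA -------------------------------------------------------------------

def test_rsfa_closed_form():
    t = np.arange(1000)
    s = 100.0 + 10.0 * np.sin(2 * np.pi * t / 50.0)  # integer cycles
    v = make_volume({(0, 0, 0): s})
    rsfa = compute_rsfa(v)[0, 0, 0]
    assert rsfa == pytest.approx((10 / np.sqrt(2)) / 100, rel=1e-6)


def test_rsfa_constant_and_scale_invariance(rng):
    s = 50.0 + rng.standard_normal(80)
    v = make_volume({(0, 0, 0): np.full(30, 7.0), (1, 1, 1): s[:30],
                     (2, 2, 2): 3.0 * s[:30]})
    out = compute_rsfa(v)
    assert out[0, 0, 0] == 0.0
    assert out[2, 2, 2] == pytest.approx(out[1, 1, 1], rel=1e-12)


def test_rsfa_nonpositive_mean_is_missing():
    v = make_volume({(0, 0, 0): np.array([-1.0, 1.0, -1.0, 1.0])})
    assert np.isnan(compute_rsfa(v)[0, 0, 0])


# -- FCD --------------------------------------------------------------------

def test_gfcd_identical_and_orthogonal():
    t = np.arange(16.0)
    same = np.sin(t)
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[0, 0, 0] = mask[0, 0, 1] = mask[3, 3, 3] = True
    v = make_volume({(0, 0, 0): same, (0, 0, 1): same, (3, 3, 3): same},
                    masks={"gray": mask})
    out = compute_gfcd(v, 0.6)
    assert out[0, 0, 0] == 2 and out[3, 3, 3] == 2
    # orthogonal pair
    mask2 = np.zeros((4, 4, 4), dtype=bool)
    mask2[0, 0, 0] = mask2[0, 0, 1] = True
    u = np.array([1., -1.] * 8)
    w = np.array([1., 1., -1., -1.] * 4)
    v2 = make_volume({(0, 0, 0): u, (0, 0, 1): w}, masks={"gray": mask2})
    assert np.nansum(compute_gfcd(v2, 0.6)) == 0


def test_gfcd_matches_bruteforce(rng):
    v, mask, coords, series = _toy_volume(rng)
    got = compute_gfcd(v, 0.6)
    want = naive_gfcd(series, 0.6)
    for c, w in zip(coords, want):
        assert got[c] == w


def test_lfcd_chain_flood_fill():
    """Four face-adjacent voxels all correlated with the first -> lFCD 3."""
    t = 24
    rng = np.random.default_rng(5)
    base = rng.standard_normal(t)
    mask = np.zeros((4, 4, 4), dtype=bool)
    chain = [(0, 0, 0), (0, 0, 1), (0, 0, 2), (0, 0, 3)]
    series = {c: base + 0.1 * rng.standard_normal(t) for c in chain}
    for c in chain:
        mask[c] = True
    v = make_volume(series, masks={"gray": mask})
    out = compute_lfcd(v, 0.6)
    assert out[0, 0, 0] == 3


def test_lfcd_isolated_voxel_is_zero(rng):
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[1, 1, 1] = True
    for c in [(0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)]:
        mask[c] = True
    series = {tuple(c): rng.standard_normal(20) for c in np.argwhere(mask)}
    v = make_volume(series, masks={"gray": mask})
    assert compute_lfcd(v, 0.99)[1, 1, 1] == 0


def test_lfcd_matches_bruteforce_and_bounded_by_gfcd(rng):
    for seed in range(3):
        local = np.random.default_rng(seed)
        v, mask, coords, series = _toy_volume(local, n_voxels=30)
        lf = compute_lfcd(v, 0.6)
        gf = compute_gfcd(v, 0.6)
        want = naive_lfcd(series, coords, 0.6)
        for c, w in zip(coords, want):
            assert lf[c] == w
            assert lf[c] <= gf[c]


# -- entropy map ------------------------------------------------------------

def test_bold_entropy_constant_voxel_zero(rng):
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[0, 0, 0] = mask[1, 1, 1] = True
    v = make_volume({(0, 0, 0): np.full(40, 2.0),
                     (1, 1, 1): rng.standard_normal(40)}, masks={"gray": mask})
    out = compute_bold_entropy(v, EntropyParams(m=3, r_factor=0.6))
    assert out[0, 0, 0] == 0.0
    assert np.isfinite(out[1, 1, 1])


# -- seed FC ----------------------------------------------------------------

def test_seed_fc_closed_forms(rng):
    atlas = np.zeros((4, 4, 4), dtype=int)
    atlas[0, 0, 0] = atlas[0, 0, 1] = 1
    t = 500
    x = rng.standard_normal(t)
    e = rng.standard_normal(t)
    rho = 0.5
    y = rho * x + np.sqrt(1 - rho ** 2) * e
    # make the sample correlation exactly 0.5 via whitening
    x = (x - x.mean()) / x.std()
    e = (e - e.mean()) / e.std()
    e -= (e @ x) / t * x  # orthogonalize
    e /= e.std()
    y = rho * x + np.sqrt(1 - rho ** 2) * e
    v = make_volume({(0, 0, 0): x, (0, 0, 1): y})
    fc = compute_seed_fc(v, atlas, seeds={1: (0, 0, 0)})
    assert fc[1] == pytest.approx(np.arctanh(0.5), abs=1e-10)


def test_seed_fc_identical_is_capped(rng):
    atlas = np.zeros((2, 2, 2), dtype=int)
    atlas[0, 0, 0] = atlas[0, 0, 1] = 1
    s = rng.standard_normal(50)
    v = make_volume({(0, 0, 0): s, (0, 0, 1): s}, grid=(2, 2, 2))
    fc = compute_seed_fc(v, atlas, seeds={1: (0, 0, 0)})
    assert fc[1] == pytest.approx(np.arctanh(0.999), abs=1e-12)


# -- network reduction ------------------------------------------------------

def test_summarize_network_values():
    atlas = np.zeros((2, 2, 2), dtype=int)
    atlas[0] = 1
    atlas[1] = 2
    m = np.zeros((2, 2, 2))
    m[0] = 2.5
    m[1, :, :] = np.array([[0, 3], [0, 3]])
    plain = summarize_network(m, atlas)
    assert plain.set_index("network").loc[1, "value"] == pytest.approx(2.5)
    logt = summarize_network(m, atlas, log_transform=True)
    assert logt.set_index("network").loc[2, "value"] == pytest.approx(
        0.5 * (np.log(1) + np.log(4)), abs=1e-12)
    zeros = summarize_network(np.zeros((2, 2, 2)), atlas, log_transform=True)
    assert (zeros["value"] == 0).all()


def test_smoothing_optional_and_mass_preserving(rng):
    from eegfmri.fmri_metrics import smooth_volume
    data = 100 + rng.standard_normal((6, 6, 6, 5))
    v = VolumeSeries(data=data, tr_seconds=1.0)
    assert np.array_equal(smooth_volume(v, 0.0).data, data)
    sm = smooth_volume(v, 1.0)
    # frame-wise smoothing preserves each frame's mean and reduces variance
    np.testing.assert_allclose(sm.data.mean(axis=(0, 1, 2)),
                               data.mean(axis=(0, 1, 2)), rtol=1e-3)
    assert sm.data.std() < data.std()
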