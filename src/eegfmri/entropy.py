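"""Sample entropy and multiscale-entropy (MSE) primitives.

Sample entropy SampEn(m, r) is the negative natural log of the conditional
probability that two sequences matching for ``m`` points (Chebyshev distance
<= r) also match for ``m + 1`` points, with self-matches excluded.  The MSE
complexity index is the area under the entropy-vs-scale curve after
non-overlapping coarse-graining.

Neighbour counting uses a k-d tree with the Chebyshev (max-norm) metric, which
gives counts identical to the naive O(n^2) double loop while scaling to the
series lengths produced by minutes of EEG.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "sample_entropy",
    "coarse_grain",
    "multiscale_entropy",
    "complexity_index",
]

#: default coarse-graining factors for the complexity index
DEFAULT_SCALES = (3, 6, 13, 21, 62)


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """Delay-embedding matrix of shape (n - m + 1, m) with unit lag."""
    n = x.shape[0]
    return np.lib.stride_tricks.sliding_window_view(x, m) if n >= m else np.empty((0, m))


def _pair_count(templates: np.ndarray, r: float) -> int:
    """Number of unordered template pairs within Chebyshev distance r."""
    if templates.shape[0] < 2:
        return 0
    tree = cKDTree(templates)
    total = tree.count_neighbors(tree, r, p=np.inf)  # ordered pairs incl. self
    return int(total - templates.shape[0]) // 2


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   r_factor: float | None = None) -> float:
    """SampEn(m, r) of a 1-D series.

    Parameters
    ----------
    x : 1-D array.
    m : template (embedding) length, >= 1.
    r : absolute tolerance.  If None, ``r_factor * SD(x)`` is used
        (population SD).
    r_factor : tolerance as a multiple of the series SD; ignored when ``r``
        is given.

    Returns
    -------
    float
        ``-ln(A / B)`` where B counts m-point matches and A counts
        (m+1)-point matches over the same ``n - m`` templates.  A constant
        series returns 0 (every template matches).  Series too short
        (``n <= m + 1``) or with no matches return NaN.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.shape[0]
    if n <= m + 1:
        return np.nan
    if r is None:
        if r_factor is None:
            raise ValueError("either r or r_factor must be given")
        r = float(r_factor) * float(np.std(x))
    # n - m templates for both lengths so the ratio is a probability
    tm = _embed(x, m)[: n - m]
    tm1 = _embed(x, m + 1)
    b = _pair_count(np.ascontiguousarray(tm), r)
    a = _pair_count(np.ascontiguousarray(tm1), r)
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping means of ``scale`` consecutive samples."""
    x = np.asarray(x, dtype=float).ravel()
    if scale < 1:
        raise ValueError("scale must be >= 1")
    n = (x.shape[0] // scale) * scale
    if n == 0:
        return np.empty(0)
    return x[:n].reshape(-1, scale).mean(axis=1)


def multiscale_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.5,
                       scales: tuple[int, ...] = DEFAULT_SCALES) -> np.ndarray:
    """SampEn of the coarse-grained series at each scale.

    The tolerance ``r = r_factor * SD(x)`` is fixed from the *original*
    series so that entropies are comparable across scales.
    """
    x = np.asarray(x, dtype=float).ravel()
    r = float(r_factor) * float(np.std(x))
    return np.array([sample_entropy(coarse_grain(x, s), m=m, r=r) for s in scales])


def complexity_index(x: np.ndarray, m: int = 2, r_factor: float = 0.5,
                     scales: tuple[int, ...] = DEFAULT_SCALES) -> float:
    """Area under the multiscale-entropy curve (trapezoid over scale values).

    Returns NaN when any scale's entropy is undefined (series too short at the
    largest scale, or no template matches).
    """
    ent = multiscale_entropy(x, m=m, r_factor=r_factor, scales=scales)
    if np.any(np.isnan(ent)):
        return np.nan
    return float(np.trapezoid(ent, np.asarray(scales, dtype=float)))
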