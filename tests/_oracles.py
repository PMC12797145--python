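"""Independent brute-force oracles used only by the tests.

Every function here is a direct transcription of the defining formula,
written without vectorization or shared code with the package, so that
agreement with the package is a genuine two-route check.
"""

import numpy as np


def naive_sample_entropy(x, m, r):
    """Richman-Moorman SampEn by explicit double loop (Chebyshev, <= r,
    self-matches excluded, n - m templates for both lengths)."""
    x = list(map(float, x))
    n = len(x)
    if n <= m + 1:
        return float("nan")

    def count(length):
        templates = [x[i:i + length] for i in range(n - m)]
        c = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                d = max(abs(a - b) for a, b in zip(templates[i], templates[j]))
                if d <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def naive_gfcd(series, threshold):
    """series: list of 1-D arrays.  Count of other voxels with r >= thr."""
    n = len(series)
    out = []
    for i in range(n):
        c = 0
        for j in range(n):
            if i == j:
                continue
            si, sj = np.asarray(series[i]), np.asarray(series[j])
            if si.std() == 0 or sj.std() == 0:
                continue
            r = np.corrcoef(si, sj)[0, 1]
            if r >= threshold:
                c += 1
        out.append(c)
    return out


def naive_lfcd(series, coords, threshold):
    """Flood-fill local FC density with 6-connectivity, recursion on a set."""
    coords = [tuple(c) for c in coords]
    pos = {c: k for k, c in enumerate(coords)}
    out = []
    for i in range(len(coords)):
        si = np.asarray(series[i])
        cluster = {i}
        frontier = [i]
        while frontier:
            j = frontier.pop()
            cx, cy, cz = coords[j]
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                               (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                nb = (cx + dx, cy + dy, cz + dz)
                if nb not in pos:
                    continue
                k = pos[nb]
                if k in cluster:
                    continue
                sk = np.asarray(series[k])
                if si.std() == 0 or sk.std() == 0:
                    continue
                if np.corrcoef(si, sk)[0, 1] >= threshold:
                    cluster.add(k)
                    frontier.append(k)
        out.append(len(cluster) - 1)
    return out


def naive_bh(p_values, q):
    """Benjamini-Hochberg step-up by its textbook definition."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    flags = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_star:
            flags[idx] = True
    return flags


def naive_band_means(spectrum, freqs, bands):
    """Hand band averaging with half-open bins ([low, high), gamma closes)."""
    out = {}
    names = list(bands)
    for name in names:
        low, high = bands[name]
        vals = [s for s, f in zip(spectrum, freqs)
                if (low <= f <= high if name == names[-1] else low <= f < high)]
        out[name] = sum(vals) / len(vals)
    total = [s for s, f in zip(spectrum, freqs) if 1.0 <= f <= 50.0]
    out["broadband"] = sum(total) / len(total)
    return out
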