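"""Independent brute-force reference implementations of the entropy measures.

Written from the definitions, deliberately sharing no code with the package:
explicit template construction, per-template distance scans and dictionary
counting.  They are slow and exist only as oracles for the test suite.
"""

from __future__ import annotations

import math

import numpy as np


def embed_ref(x, m, delay):
    n = len(x) - (m - 1) * delay
    return np.array([[x[i + k * delay] for k in range(m)] for i in range(n)])


def svd_entropy_ref(x, m, delay=1):
    a = embed_ref(x, m, delay)
    lam = np.linalg.svd(a, compute_uv=False)
    lam = lam / lam.sum()
    h = 0.0
    for v in lam:
        if v > 0:
            h -= v * math.log2(v)
    return h / math.log2(m)


def perm_entropy_ref(x, m, delay=1):
    a = embed_ref(x, m, delay)
    counts: dict[tuple, int] = {}
    for row in a:
        pattern = tuple(int(i) for i in np.argsort(row, kind="stable"))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    h = 0.0
    for c in counts.values():
        p = c / total
        h -= p * math.log2(p)
    return h / math.log2(math.factorial(m))


def samp_entropy_ref(x, m, r):
    x = np.asarray(x, float)
    tol = r * x.std()
    n_t = len(x) - m  # Richman-Moorman: same template count at both dims
    tm = np.array([x[i:i + m] for i in range(n_t)])
    tm1 = np.array([x[i:i + m + 1] for i in range(n_t)])
    c0 = c1 = 0
    for i in range(n_t - 1):
        c0 += int(np.sum(np.max(np.abs(tm[i + 1:] - tm[i]), axis=1) <= tol))
        c1 += int(np.sum(np.max(np.abs(tm1[i + 1:] - tm1[i]), axis=1) <= tol))
    if c0 == 0 or c1 == 0:
        return float("nan")
    return -math.log(c1 / c0)


def cosi_entropy_ref(x, m, r):
    x = np.asarray(x, float)
    templates = np.array([x[i:i + m] for i in range(len(x) - m + 1)])
    norms = np.array([np.linalg.norm(t) for t in templates])
    templates = templates[norms > 0]
    norms = norms[norms > 0]
    n = len(templates)
    within = total = 0
    for i in range(n - 1):
        cos = templates[i + 1:] @ templates[i] / (norms[i + 1:] * norms[i])
        ang = np.arccos(np.clip(cos, -1.0, 1.0)) / math.pi
        total += len(ang)
        within += int(np.sum(ang <= r))
    b = within / total
    if b in (0.0, 1.0):
        return 0.0
    return -(b * math.log2(b) + (1 - b) * math.log2(1 - b))


def cosi_pair_distances_ref(x, m):
    """All pairwise angular distances, for constructing exact-B inputs."""
    x = np.asarray(x, float)
    templates = [x[i:i + m] for i in range(len(x) - m + 1)]
    templates = [t for t in templates if np.linalg.norm(t) > 0]
    out = []
    for i in range(len(templates)):
        for j in range(i + 1, len(templates)):
            cos = float(np.dot(templates[i], templates[j])
                        / (np.linalg.norm(templates[i]) * np.linalg.norm(templates[j])))
            out.append(math.acos(max(-1.0, min(1.0, cos))) / math.pi)
    return np.array(out)


def fuzzy_entropy_ref(x, m, r, r2):
    x = np.asarray(x, float)
    tol = r * x.std()

    def phi(dim):
        n = len(x) - dim + 1
        templates = np.array([x[i:i + dim] for i in range(n)])
        centred = templates - templates.mean(axis=1, keepdims=True)
        acc = 0.0
        cnt = 0
        for i in range(n - 1):
            d = np.max(np.abs(centred[i + 1:] - centred[i]), axis=1)
            acc += 2 * float(np.sum(np.exp(-(d ** r2) / tol)))  # ordered pairs
            cnt += 2 * len(d)
        return acc / cnt

    return math.log(phi(m)) - math.log(phi(m + 1))


def phase_entropy_ref(x, K):
    x = np.asarray(x, float)
    s = [0.0] * K
    for j in range(1, len(x) - 1):
        y = x[j + 1] - x[j]
        w = x[j] - x[j - 1]
        theta = math.atan2(y, w)
        if theta < 0:
            theta += 2 * math.pi
        sector = int(theta / (2 * math.pi / K))
        if sector == K:
            sector -= 1
        s[sector] += theta
    total = sum(s)
    if total == 0:
        return 0.0
    h = 0.0
    for v in s:
        p = v / total
        if p > 0:
            h -= p * math.log(p)
    return h / math.log(K)


def phase_sector_sums_ref(x, K):
    """Per-sector angle sums, for constructing exact-uniform inputs."""
    x = np.asarray(x, float)
    s = [0.0] * K
    for j in range(1, len(x) - 1):
        y = x[j + 1] - x[j]
        w = x[j] - x[j - 1]
        theta = math.atan2(y, w)
        if theta < 0:
            theta += 2 * math.pi
        sector = min(int(theta / (2 * math.pi / K)), K - 1)
        s[sector] += theta
    return s


def attn_entropy_ref(x):
    x = np.asarray(x, float)
    maxima, minima = [], []
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            maxima.append(i)
        elif x[i] < x[i - 1] and x[i] < x[i + 1]:
            minima.append(i)

    def shannon(intervals):
        if not intervals:
            return 0.0
        counts: dict[int, int] = {}
        for v in intervals:
            counts[v] = counts.get(v, 0) + 1
        total = sum(counts.values())
        h = 0.0
        for c in counts.values():
            p = c / total
            h -= p * math.log(p)
        return h

    i_mm = [b - a for a, b in zip(maxima, maxima[1:])]
    i_nn = [b - a for a, b in zip(minima, minima[1:])]
    events = sorted([(i, "max") for i in maxima] + [(i, "min") for i in minima])
    i_max_min, i_min_max = [], []
    for (pos_a, kind_a), (pos_b, kind_b) in zip(events, events[1:]):
        if kind_a == "max" and kind_b == "min":
            i_max_min.append(pos_b - pos_a)
        elif kind_a == "min" and kind_b == "max":
            i_min_max.append(pos_b - pos_a)
    return (shannon(i_mm) + shannon(i_nn)
            + shannon(i_max_min) + shannon(i_min_max)) / 4.0


def band_power_fractions_ref(x, fs, bands):
    """Welch-periodogram band-power fractions (the spectral oracle)."""
    from scipy.signal import welch

    f, pxx = welch(x, fs=fs, nperseg=min(len(x), 4 * int(fs)))
    total = np.trapezoid(pxx, f)
    out = {}
    for name, (lo, hi) in bands.items():
        mask = (f >= lo) & (f < hi)
        out[name] = float(np.trapezoid(pxx[mask], f[mask]) / total)
    return out
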