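"""Seven entropy estimators for one-dimensional time series.

The estimators quantify signal irregularity through different lenses:

* ``svd_entropy`` — Shannon entropy (base 2) of the normalized singular-value
  spectrum of the delay-embedding matrix, divided by log2(m) so the result
  lies in [0, 1].
* ``perm_entropy`` — normalized Shannon entropy of the ordinal-pattern
  distribution of the embedding rows ([0, 1]).
* ``samp_entropy`` — negative log conditional probability that template
  vectors close (Chebyshev distance ≤ r·std) at dimension m stay close at
  m+1; the Richman–Moorman convention (first N−m templates at both
  dimensions, self-matches excluded) is used.
* ``cosi_entropy`` — binary Shannon entropy of the proportion B of template
  pairs whose angular distance (arccos of cosine similarity, scaled by 1/π)
  is within r ([0, 1]).
* ``fuzzy_entropy`` — like SampEn but on mean-centred templates with a smooth
  membership exp(−d^r2 / r·std) instead of a hard threshold.
* ``phase_entropy`` — normalized Shannon entropy of the angle mass accumulated
  in K equal sectors of the second-order difference plot ([0, 1]).
* ``attn_entropy`` — mean Shannon entropy (natural log) of the four
  interval-length distributions between successive local extrema
  (max–max, min–min, max–min, min–max).

Tolerances written "×std" are taken relative to the population standard
deviation of the analysed series itself.  Degenerate inputs raise
:class:`~eegentropy.exceptions.DegenerateInputError`; an undefined SampEn
(zero template matches) returns NaN with
:class:`~eegentropy.exceptions.UndefinedEntropyWarning` and is rejected
loudly downstream rather than imputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist

from .exceptions import (
    DegenerateInputError,
    InvalidArgumentError,
    UndefinedEntropyWarning,
)

__all__ = [
    "svd_entropy",
    "perm_entropy",
    "samp_entropy",
    "cosi_entropy",
    "fuzzy_entropy",
    "phase_entropy",
    "attn_entropy",
    "EntropyConfig",
    "entropy_grid",
    "METHODS",
]

METHODS = ("SVDEn", "PermEn", "SampEn", "CoSiEn", "FuzzyEn", "PhaseEn", "AttnEn")


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise InvalidArgumentError("input series must be one-dimensional")
    return x


def _embed(x: np.ndarray, m: int, delay: int) -> np.ndarray:
    """Delay-embedding matrix: rows [x_i, x_{i+delay}, ..., x_{i+(m-1)delay}]."""
    if m < 1 or delay < 1:
        raise InvalidArgumentError("m and delay must be positive integers")
    n_rows = len(x) - (m - 1) * delay
    if n_rows < 1:
        raise InvalidArgumentError(
            f"series of length {len(x)} too short for m={m}, delay={delay}"
        )
    if delay == 1:
        return sliding_window_view(x, m)
    return sliding_window_view(x, (m - 1) * delay + 1)[:, ::delay]


def _shannon(p: np.ndarray, base: float | None = None) -> float:
    """−Σ p log p with 0·log 0 ≡ 0; natural log unless a base is given."""
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / math.log(base) if base else h


def svd_entropy(x, m: int = 3, delay: int = 1) -> float:
    """Normalized singular-value-spectrum entropy in [0, 1]."""
    x = _as_series(x)
    if m < 2:
        raise InvalidArgumentError("svd_entropy requires m >= 2")
    if len(x) < m * delay + 1:
        raise InvalidArgumentError(
            f"svd_entropy needs at least m*delay+1={m * delay + 1} samples"
        )
    a = _embed(x, m, delay)
    s = np.linalg.svd(a, compute_uv=False)
    # rank tolerance: numerically-zero singular values of a rank-deficient
    # embedding must not contribute entropy noise
    s = np.where(s > max(a.shape) * np.finfo(float).eps * s.max(initial=0.0),
                 s, 0.0)
    total = s.sum()
    if total == 0:
        raise DegenerateInputError("all singular values are zero (all-zero input)")
    lam = s / total
    return _shannon(lam, base=2.0) / math.log2(m)


def perm_entropy(x, m: int = 3, delay: int = 1) -> float:
    """Normalized ordinal-pattern entropy in [0, 1]; ties broken by index order."""
    x = _as_series(x)
    if len(x) < (m - 1) * delay + 1:
        raise InvalidArgumentError("series too short for requested embedding")
    if m < 2:
        raise InvalidArgumentError("perm_entropy requires m >= 2")
    a = _embed(x, m, delay)
    patterns = np.argsort(a, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    return _shannon(p, base=2.0) / math.log2(math.factorial(m))


def samp_entropy(x, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy; ``r`` is a fraction of the series' population std.

    Returns NaN with :class:`UndefinedEntropyWarning` when either template
    count is zero (no matches at dimension m or m+1).
    """
    x = _as_series(x)
    if r <= 0:
        raise InvalidArgumentError("tolerance factor r must be positive")
    if len(x) < m + 2:
        raise InvalidArgumentError("samp_entropy needs at least m+2 samples")
    tol = r * x.std()
    emb1 = _embed(x, m + 1, 1)               # N-m rows
    emb0 = _embed(x, m, 1)[: len(emb1)]      # same N-m rows at dimension m
    c0 = int(np.count_nonzero(pdist(emb0, "chebyshev") <= tol))
    c1 = int(np.count_nonzero(pdist(emb1, "chebyshev") <= tol))
    if c0 == 0 or c1 == 0:
        warnings.warn(
            "SampEn undefined: no template matches within tolerance",
            UndefinedEntropyWarning, stacklevel=2,
        )
        return float("nan")
    return float(-math.log(c1 / c0))


def cosi_entropy(x, m: int = 3, r: float = 0.05) -> float:
    """Cosine-similarity entropy in [0, 1]; ``r`` is an absolute angular
    tolerance on the (1/π)·arccos scale.  Zero-norm templates are excluded."""
    x = _as_series(x)
    if r <= 0:
        raise InvalidArgumentError("angular tolerance r must be positive")
    if len(x) < m + 1:
        raise InvalidArgumentError("cosi_entropy needs at least m+1 samples")
    t = _embed(x, m, 1)
    norms = np.linalg.norm(t, axis=1)
    t = t[norms > 0]
    if len(t) < 2:
        raise DegenerateInputError("fewer than 2 nonzero templates")
    cos_sim = 1.0 - pdist(t, "cosine")
    ang = np.arccos(np.clip(cos_sim, -1.0, 1.0)) / np.pi
    b = float(np.mean(ang <= r))
    if b in (0.0, 1.0):
        return 0.0
    return float(-(b * math.log2(b) + (1 - b) * math.log2(1 - b)))


def fuzzy_entropy(x, m: int = 1, r: float = 0.15, r2: float = 5) -> float:
    """Fuzzy entropy with membership exp(−d^r2 / (r·std)).

    Templates are mean-centred; d is the Chebyshev distance between centred
    templates.  A constant series returns 0.0 by convention (all centred
    templates coincide).
    """
    x = _as_series(x)
    if r <= 0:
        raise InvalidArgumentError("tolerance factor r must be positive")
    if r2 <= 0:
        raise InvalidArgumentError("membership exponent r2 must be positive")
    if len(x) < m + 2:
        raise InvalidArgumentError("fuzzy_entropy needs at least m+2 samples")
    sd = x.std()
    if sd == 0:
        return 0.0
    tol = r * sd
    log_phi = []
    for dim in (m, m + 1):
        if dim == 1:
            # centred length-1 templates are identically zero: phi = 1
            log_phi.append(0.0)
            continue
        if dim == 2:
            # centred pair templates are (+a, -a) with a = (x_i - x_{i+1})/2,
            # so the Chebyshev distance collapses to |a_i - a_j|
            c = np.ascontiguousarray(0.5 * (x[:-1] - x[1:]))[:, None]
        else:
            t = _embed(x, dim, 1)
            c = np.ascontiguousarray(t - t.mean(axis=1, keepdims=True))
        d = pdist(c, "chebyshev")
        if r2 == 1:
            dr = d
        elif r2 == 5:
            dr = d * d
            dr *= dr
            dr *= d
        elif float(r2).is_integer() and r2 <= 6:
            dr = d * d
            for _ in range(int(r2) - 2):
                dr *= d
        else:
            dr = d ** r2
        dr *= -1.0 / tol
        np.exp(dr, out=dr)
        log_phi.append(math.log(float(dr.mean())))
    return float(log_phi[0] - log_phi[1])


def phase_entropy(x, K: int = 6) -> float:
    """Normalized sector entropy of the second-order difference plot, in [0, 1]."""
    x = _as_series(x)
    if len(x) < 4:
        raise InvalidArgumentError("phase_entropy needs at least 4 samples")
    if K < 2:
        raise InvalidArgumentError("K must be at least 2")
    y = x[2:] - x[1:-1]
    w = x[1:-1] - x[:-2]
    theta = np.mod(np.arctan2(y, w), 2 * np.pi)
    sector = np.minimum((theta // (2 * np.pi / K)).astype(int), K - 1)
    s = np.bincount(sector, weights=theta, minlength=K)
    total = s.sum()
    if total == 0:
        warnings.warn(
            "all sector sums are zero; PhaseEn defined as 0",
            UndefinedEntropyWarning, stacklevel=2,
        )
        return 0.0
    return _shannon(s / total) / math.log(K)


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    interior = x[1:-1]
    maxima = np.flatnonzero((interior > x[:-2]) & (interior > x[2:])) + 1
    minima = np.flatnonzero((interior < x[:-2]) & (interior < x[2:])) + 1
    return maxima, minima


def _interval_entropy(intervals: np.ndarray) -> float:
    if len(intervals) == 0:
        return 0.0
    _, counts = np.unique(intervals, return_counts=True)
    return _shannon(counts / counts.sum())


def attn_entropy(x) -> float:
    """Attention entropy: mean Shannon entropy of extremum-interval distributions."""
    x = _as_series(x)
    if len(x) < 3:
        raise InvalidArgumentError("attn_entropy needs at least 3 samples")
    maxima, minima = _local_extrema(x)
    if len(maxima) == 0 or len(minima) == 0:
        raise DegenerateInputError(
            "series has no strict local maximum/minimum pair (monotone input?)"
        )
    events = np.concatenate([maxima, minima])
    kinds = np.concatenate([np.zeros(len(maxima), int), np.ones(len(minima), int)])
    order = np.argsort(events, kind="stable")
    events, kinds = events[order], kinds[order]
    steps = np.diff(events)
    pair = (kinds[:-1], kinds[1:])
    i_max_min = steps[(pair[0] == 0) & (pair[1] == 1)]
    i_min_max = steps[(pair[0] == 1) & (pair[1] == 0)]
    parts = [
        _interval_entropy(np.diff(maxima)),
        _interval_entropy(np.diff(minima)),
        _interval_entropy(i_max_min),
        _interval_entropy(i_min_max),
    ]
    return float(np.mean(parts))


_DISPATCH = {
    "SVDEn": lambda x, c: svd_entropy(x, m=c.m, delay=c.delay),
    "PermEn": lambda x, c: perm_entropy(x, m=c.m, delay=c.delay),
    "SampEn": lambda x, c: samp_entropy(x, m=c.m, r=c.r),
    "CoSiEn": lambda x, c: cosi_entropy(x, m=c.m, r=c.r),
    "FuzzyEn": lambda x, c: fuzzy_entropy(x, m=c.m, r=c.r, r2=c.r2),
    "PhaseEn": lambda x, c: phase_entropy(x, K=c.K),
    "AttnEn": lambda x, c: attn_entropy(x),
}


def _fmt(v) -> str:
    return f"{v:g}"


@dataclass(frozen=True)
class EntropyConfig:
    """One estimator plus its hyperparameters.

    ``r`` is a ×std factor for SampEn/FuzzyEn and an absolute angular
    tolerance for CoSiEn; ``r2`` is the FuzzyEn membership exponent; ``K`` the
    PhaseEn sector count.
    """

    method: str
    m: int | None = None
    delay: int | None = None
    r: float | None = None
    r2: float | None = None
    K: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InvalidArgumentError(
                f"unknown entropy method {self.method!r}; choose from {METHODS}"
            )

    def compute(self, x) -> float:
        return _DISPATCH[self.method](x, self)

    def label(self) -> str:
        parts = []
        for key in ("m", "delay", "r", "r2", "K"):
            v = getattr(self, key)
            if v is not None:
                parts.append(f"{key}={_fmt(v)}")
        return f"{self.method}|{','.join(parts) if parts else '-'}"

    @classmethod
    def from_label(cls, label: str) -> "EntropyConfig":
        method, _, params = label.partition("|")
        kwargs = {}
        if params and params != "-":
            for item in params.split(","):
                key, _, val = item.partition("=")
                kwargs[key] = int(val) if key in ("m", "delay", "K") else float(val)
        return cls(method=method, **kwargs)


_R_GRID = tuple(round(0.05 * i, 2) for i in range(1, 11))  # 0.05 .. 0.50


def entropy_grid(method: str) -> list[EntropyConfig]:
    """Full hyperparameter grid for one estimator.

    SVDEn/PermEn: m = 2..10, delay = 1.  SampEn: m = 1..3 × r = 0.05..0.5×std.
    CoSiEn: m = 2..3 × r = 0.05..0.5.  FuzzyEn: m = 1..2 × r = 0.05..0.5×std ×
    r2 = 1..5.  PhaseEn: K = 2..10.  AttnEn: the single parameterless config.
    """
    if method in ("SVDEn", "PermEn"):
        return [EntropyConfig(method, m=m, delay=1) for m in range(2, 11)]
    if method == "SampEn":
        return [EntropyConfig(method, m=m, r=r)
                for m, r in product(range(1, 4), _R_GRID)]
    if method == "CoSiEn":
        return [EntropyConfig(method, m=m, r=r)
                for m, r in product(range(2, 4), _R_GRID)]
    if method == "FuzzyEn":
        return [EntropyConfig(method, m=m, r=r, r2=r2)
                for m, r, r2 in product(range(1, 3), _R_GRID, range(1, 6))]
    if method == "PhaseEn":
        return [EntropyConfig(method, K=k) for k in range(2, 11)]
    if method == "AttnEn":
        return [EntropyConfig(method)]
    raise InvalidArgumentError(
        f"unknown entropy method {method!r}; choose from {METHODS}"
    )


def iter_full_grid() -> Iterator[EntropyConfig]:
    for method in METHODS:
        yield from entropy_grid(method)
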