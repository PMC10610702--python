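"""Subband signal variants via discrete wavelet decomposition.

Each channel is decomposed with a 4-level db4 DWT and re-expanded into nine
full-length signals: the original (O) plus, for each level k, the signal
reconstructed from *only* the level-k approximation coefficients (cAk) or only
the level-k detail coefficients (cDk), every other coefficient vector zeroed.
At 128 Hz the nominal dyadic bands are O 0-64, cA1 0-32, cA2 0-16, cA3 0-8,
cA4 0-4, cD1 32-64, cD2 16-32, cD3 8-16, cD4 4-8 Hz.

Boundary handling is symmetric (half-sample) extension; reconstructions are
cropped to the source length.  Because the filter bank is perfectly
reconstructing, x = cA4 + cD4 + cD3 + cD2 + cD1 and cAk = cA(k+1) + cD(k+1)
hold to floating-point precision, which the tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .exceptions import InvalidArgumentError

__all__ = ["VARIANT_ORDER", "NOMINAL_BANDS", "SignalVariantSet", "make_variants"]

#: Fixed column ordering of the nine variants throughout the pipeline.
VARIANT_ORDER: tuple[str, ...] = (
    "O", "cA1", "cA2", "cA3", "cA4", "cD1", "cD2", "cD3", "cD4",
)

#: Nominal dyadic bands (Hz) at the reference sampling rate of 128 Hz.
NOMINAL_BANDS: dict[str, tuple[float, float]] = {
    "O": (0.0, 64.0),
    "cA1": (0.0, 32.0), "cA2": (0.0, 16.0), "cA3": (0.0, 8.0), "cA4": (0.0, 4.0),
    "cD1": (32.0, 64.0), "cD2": (16.0, 32.0), "cD3": (8.0, 16.0), "cD4": (4.0, 8.0),
}


@dataclass
class SignalVariantSet:
    variants: dict[str, np.ndarray]
    nominal_bands: dict[str, tuple[float, float]]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.variants[name]


def _reconstruct_single(coeffs: list[np.ndarray], keep: int,
                        wavelet: str, n: int) -> np.ndarray:
    kept = [c if i == keep else np.zeros_like(c) for i, c in enumerate(coeffs)]
    y = pywt.waverec(kept, wavelet, mode="symmetric")
    return y[:n] if len(y) >= n else np.pad(y, (0, n - len(y)))


def make_variants(
    x: np.ndarray,
    wavelet_name: str = "db4",
    levels: int = 4,
) -> SignalVariantSet:
    """Build the O/cA1..cA{levels}/cD1..cD{levels} variant set of a series."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise InvalidArgumentError("input series must be one-dimensional")
    if levels < 1:
        raise InvalidArgumentError("levels must be at least 1")
    wavelet = pywt.Wavelet(wavelet_name)
    min_len = (wavelet.dec_len - 1) * 2 ** levels
    if len(x) < min_len:
        raise InvalidArgumentError(
            f"series of length {len(x)} is too short for {levels} "
            f"{wavelet_name} levels (minimum {min_len} samples)"
        )
    n = len(x)
    variants: dict[str, np.ndarray] = {"O": x.copy()}
    for k in range(1, levels + 1):
        coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=k)
        # coeffs = [cA_k, cD_k, cD_{k-1}, ..., cD_1]
        variants[f"cA{k}"] = _reconstruct_single(coeffs, 0, wavelet_name, n)
        variants[f"cD{k}"] = _reconstruct_single(coeffs, 1, wavelet_name, n)
    if levels == 4:
        bands = dict(NOMINAL_BANDS)
    else:  # generic dyadic split of the reference 0-64 Hz range
        bands = {"O": (0.0, 64.0)}
        for k in range(1, levels + 1):
            bands[f"cA{k}"] = (0.0, 64.0 / 2 ** k)
            bands[f"cD{k}"] = (64.0 / 2 ** k, 64.0 / 2 ** (k - 1))
    return SignalVariantSet(variants=variants, nominal_bands=bands)
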