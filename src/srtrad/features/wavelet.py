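"""Single-level 3D discrete wavelet decomposition and band-limited images.

Sub-bands are labelled by the per-axis low/high-pass split in axis order
(x, y, z): ``LLL`` is the all-approximation band, ``HHH`` the all-detail
band. The default wavelet is Haar; any orthogonal PyWavelets family works.

For texture extraction each sub-band is reconstructed back onto the
original voxel grid (inverse transform with the other seven bands zeroed),
so the sub-lesion masks apply unchanged.
"""

from __future__ import annotations

import numpy as np
import pywt

from .names import WAVELET_BANDS

_AXIS_LETTER = {"a": "L", "d": "H"}


def _band_from_key(key: str) -> str:
    return "".join(_AXIS_LETTER[c] for c in key)


def _key_from_band(band: str) -> str:
    return "".join("a" if c == "L" else "d" for c in band)


def wavelet_decompose_3d(
    image: np.ndarray, wavelet: str = "haar"
) -> dict[str, np.ndarray]:
    """Single-level 3D DWT; returns the 8 coefficient grids keyed LLL..HHH."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3:
        raise ValueError("expected a 3D volume")
    w = pywt.Wavelet(wavelet)
    for ax, size in enumerate(image.shape):
        if size < w.dec_len:
            raise ValueError(
                f"axis {ax} has {size} samples, shorter than the "
                f"{w.dec_len}-tap {wavelet} filter"
            )
    coeffs = pywt.dwtn(image, w, axes=(0, 1, 2))
    out = {_band_from_key(k): v for k, v in coeffs.items()}
    assert set(out) == set(WAVELET_BANDS)
    return out


def wavelet_reconstruct_3d(
    bands: dict[str, np.ndarray], wavelet: str = "haar"
) -> np.ndarray:
    """Inverse of :func:`wavelet_decompose_3d`."""
    coeffs = {_key_from_band(b): v for b, v in bands.items()}
    return pywt.idwtn(coeffs, pywt.Wavelet(wavelet), axes=(0, 1, 2))


def band_images(image: np.ndarray, wavelet: str = "haar") -> dict[str, np.ndarray]:
    """Eight band-limited images on the original grid.

    Each output is the inverse transform of one sub-band with the others
    zeroed; the eight outputs sum to the original image (linearity of the
    inverse transform).
    """
    image = np.asarray(image, dtype=np.float64)
    bands = wavelet_decompose_3d(image, wavelet)
    zeros = {b: np.zeros_like(v) for b, v in bands.items()}
    out: dict[str, np.ndarray] = {}
    for b in WAVELET_BANDS:
        solo = dict(zeros)
        solo[b] = bands[b]
        rec = wavelet_reconstruct_3d(solo, wavelet)
        out[b] = rec[tuple(slice(0, s) for s in image.shape)]
    return out
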