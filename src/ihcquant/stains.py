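"""H-DAB stain separation by optical-density color deconvolution.

Brightfield IHC images are a multiplicative mixture of absorbing dyes:
in optical density (OD = -log10 of transmittance) the contributions of
hematoxylin (blue nuclear counterstain) and DAB (brown chromogen) add
linearly along fixed unit color vectors (Beer-Lambert).  Deconvolution
inverts that mixture per pixel, yielding one grayscale concentration map
per stain.  Maps are normalized so that 0 means unstained and 1 means a
fixed saturation ceiling, which keeps intensity values comparable across
images (a per-image normalization would not be).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "StainMatrix",
    "StainChannels",
    "SATURATION_OD",
    "rgb_to_od",
    "separate_stains",
    "recombine",
    "estimate_white_point",
]

#: Concentration (in OD units) mapped to channel value 1.0.  Fixed so the
#: "maximum staining" ceiling is reproducible across images and scanners.
SATURATION_OD = 2.0

# Ruifrok & Johnston unit OD vectors for hematoxylin and DAB (R, G, B).
_HEMATOXYLIN = (0.650, 0.704, 0.286)
_DAB = (0.268, 0.570, 0.776)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("stain vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class StainMatrix:
    """Three unit-length stain OD vectors (rows: hematoxylin, DAB, residual).

    The residual row completes the basis so the 3x3 system is invertible;
    by default it is the normalized cross product of the first two rows.
    """

    rows: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {rows.shape}")
        norms = np.linalg.norm(rows, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain matrix rows must be unit length")
        if abs(np.linalg.det(rows)) < 1e-8:
            raise ValueError("stain matrix is singular")
        object.__setattr__(self, "rows", rows)

    @classmethod
    def hdab(cls) -> "StainMatrix":
        """Default hematoxylin/DAB basis (Ruifrok-Johnston vectors)."""
        h = _unit(np.asarray(_HEMATOXYLIN, dtype=float))
        d = _unit(np.asarray(_DAB, dtype=float))
        r = _unit(np.cross(h, d))
        return cls(rows=np.stack([h, d, r]))

    @classmethod
    def from_flat(cls, values) -> "StainMatrix":
        """Build from nine floats, row-major (H, DAB, residual); rows are
        normalized to unit length."""
        rows = np.asarray(values, dtype=float).reshape(3, 3)
        rows = rows / np.linalg.norm(rows, axis=1, keepdims=True)
        return cls(rows=rows)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.rows)


class StainChannels(NamedTuple):
    """Per-pixel stain maps in [0, 1]; higher value = stronger staining."""

    hematoxylin: np.ndarray
    dab: np.ndarray


def _resolve_white_point(pixels: np.ndarray, white_point) -> np.ndarray:
    if white_point is None:
        if np.issubdtype(pixels.dtype, np.integer):
            white_point = np.iinfo(pixels.dtype).max
        else:
            white_point = 1.0
    wp = np.atleast_1d(np.asarray(white_point, dtype=float))
    if wp.size == 1:
        wp = np.repeat(wp, 3)
    if wp.size != 3 or np.any(wp <= 0):
        raise ValueError("white_point must be a positive scalar or length-3")
    return wp


def estimate_white_point(pixels: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Per-channel background intensity estimated from bright pixels.

    Uses the given luminance percentile to pick near-background pixels and
    returns their per-channel median.  Optional alternative to the dtype
    maximum when scanner backgrounds are not fully white.
    """
    pixels = np.asarray(pixels, dtype=float)
    lum = pixels.mean(axis=-1)
    cut = np.percentile(lum, percentile)
    bright = pixels[lum >= cut]
    return np.median(bright.reshape(-1, 3), axis=0)


def rgb_to_od(pixels: np.ndarray, white_point=None) -> np.ndarray:
    """Convert an RGB image to optical density per channel.

    OD = -log10((I + eps) / (I0 + eps)) with eps = 1/I0 guarding log(0);
    the result is clipped at 0 so noise above the white point does not
    produce negative absorbance.

    Parameters
    ----------
    pixels : (H, W, 3) array
        Integer or float intensities in [0, white_point].
    white_point : scalar or length-3, optional
        Background (unstained) intensity per channel.  Defaults to the
        dtype maximum for integer images, 1.0 for float images.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {pixels.shape}")
    wp = _resolve_white_point(pixels, white_point)
    eps = 1.0 / wp
    od = -np.log10((pixels.astype(float) + eps) / (wp + eps))
    return np.clip(od, 0.0, None)


def separate_stains(
    pixels: np.ndarray,
    stains: StainMatrix | None = None,
    *,
    white_point=None,
    saturation_od: float = SATURATION_OD,
) -> StainChannels:
    """Unmix an RGB IHC image into hematoxylin and DAB channels.

    Per-pixel OD is multiplied by the inverse stain matrix to obtain stain
    concentrations; negative concentrations (deconvolution noise) are
    clipped to 0 and values are rescaled by ``saturation_od`` then clipped
    to [0, 1].  An unstained (white) pixel maps to 0 in both channels.
    """
    if stains is None:
        stains = StainMatrix.hdab()
    od = rgb_to_od(pixels, white_point=white_point)
    conc = od.reshape(-1, 3) @ stains.inverse
    conc = np.clip(conc, 0.0, None) / float(saturation_od)
    conc = np.clip(conc, 0.0, 1.0).reshape(od.shape)
    return StainChannels(hematoxylin=conc[..., 0], dab=conc[..., 1])


def recombine(
    channels: StainChannels,
    stains: StainMatrix | None = None,
    *,
    white_point: float = 255.0,
    saturation_od: float = SATURATION_OD,
    dtype=np.uint8,
) -> np.ndarray:
    """Forward Beer-Lambert synthesis of an RGB image from stain channels.

    The inverse of :func:`separate_stains` (away from clipping): channel
    values in [0, 1] are scaled back to OD, projected through the stain
    matrix, and exponentiated to transmitted intensities.
    """
    if stains is None:
        stains = StainMatrix.hdab()
    h = np.asarray(channels.hematoxylin, dtype=float)
    d = np.asarray(channels.dab, dtype=float)
    if h.shape != d.shape:
        raise ValueError("channel maps must share a shape")
    conc = np.stack([h, d, np.zeros_like(h)], axis=-1) * float(saturation_od)
    od = conc.reshape(-1, 3) @ stains.rows
    wp = _resolve_white_point(np.empty(0, dtype=dtype), white_point)
    pixels = wp * np.power(10.0, -od).reshape(h.shape + (3,))
    pixels = np.clip(pixels, 0.0, wp)
    if np.issubdtype(np.dtype(dtype), np.integer):
        return np.round(pixels).astype(dtype)
    return pixels.astype(dtype)
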