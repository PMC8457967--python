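"""Chroma-plane extraction for plumage/background separation.

Yellow-brown plumage, achromatic litter and reddish feeder plastic occupy
well-separated positions on three chroma axes:

* ``Cb`` — the blue-difference chroma of YCbCr.  Yellow objects sit well
  below the achromatic value of 128; black/white litter sits at ~128.
* ``b`` — the CIELAB yellow-blue axis ``b*``.  Strongly positive for
  plumage, near zero for achromatic material.
* ``Q`` — the NTSC YIQ quadrature axis.  Splits plumage from the similarly
  yellow feeders and drinkers, which carry a redder cast.

Conventions (fixed so that learned thresholds are portable):

* YCbCr is full-range BT.601: ``Cb = 128 - 0.168736 R - 0.331264 G + 0.5 B``
  with R, G, B in [0, 255].
* CIELAB assumes sRGB primaries and the D65 illuminant.
* YIQ uses the NTSC matrix on RGB normalised to [0, 1]; Q stays on the
  native [-0.5226, 0.5226] scale.

All conversions are computed in floating point; no quantisation is applied
before thresholding.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

__all__ = ["CHANNELS", "CHANNEL_RANGES", "extract_component", "load_image"]

#: Recognised chroma channel identifiers.
CHANNELS = ("Cb", "b", "Q")

#: Declared value range per channel (inclusive).
CHANNEL_RANGES = {
    "Cb": (0.5, 255.5),  # full-range BT.601 extremes on 8-bit RGB
    "b": (-128.0, 127.0),
    "Q": (-0.5226, 0.5226),
}

# Full-range BT.601 Cb row applied to 8-bit RGB.
_CB_ROW = np.array([-0.168736, -0.331264, 0.5])
# NTSC Q row on RGB in [0, 1]; coefficients sum to zero so grays map to
# exactly (up to float rounding) zero chroma
_Q_ROW = np.array([0.211456, -0.522591, 0.311135])


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must contain at least one pixel")
    if np.issubdtype(image.dtype, np.floating):
        if image.min() < 0 or image.max() > 255:
            raise ValueError("RGB values must lie in [0, 255]")
    return image


def extract_component(image: np.ndarray, channel_id: str) -> np.ndarray:
    """Convert an RGB image to one diagnostic chroma plane.

    Parameters
    ----------
    image : ndarray, shape (H, W, 3)
        8-bit RGB image (values in [0, 255], channel order R, G, B).
    channel_id : {"Cb", "b", "Q"}
        Which chroma plane to compute.

    Returns
    -------
    ndarray, shape (H, W)
        Floating-point component plane.  Gray pixels map to 128 (Cb) or
        ~0 (b*, Q); the conversion is deterministic.
    """
    image = _validate_image(image)
    if channel_id == "Cb":
        return 128.0 + image.astype(np.float64) @ _CB_ROW
    rgb01 = image.astype(np.float64) / 255.0
    if channel_id == "b":
        return _skcolor.rgb2lab(rgb01)[..., 2]
    if channel_id == "Q":
        return rgb01 @ _Q_ROW
    raise ValueError(f"unknown channel_id {channel_id!r}; expected one of {CHANNELS}")


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG frame as an HxWx3 uint8 RGB array (alpha dropped)."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    return np.ascontiguousarray(arr[..., :3], dtype=np.uint8)
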