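"""Occupancy accumulation and the band-ratio activity index.

Summing the per-minute body masks of an analysis hour gives a per-pixel
occupancy count in 0..60: how many frames showed a bird at that spot.
The activity index is the fraction of pixels whose count falls in a band
(default 10..49 inclusive).  The band deliberately excludes pixels that
were never visited and pixels occupied nearly the whole hour — the
latter correspond to birds huddling or lying in place, which is rest,
not activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OccupancyAccumulator", "ActivityResult", "accumulate", "activity_index",
           "heatmap_array", "render_heatmap"]

DEFAULT_BAND = (10, 49)


@dataclass
class OccupancyAccumulator:
    """Per-pixel count of foreground frames over an analysis period."""

    counts: np.ndarray
    n_frames: int

    def add(self, mask: np.ndarray) -> "OccupancyAccumulator":
        """Fold one more mask into the accumulator (in place)."""
        mask = np.asarray(mask)
        if mask.shape != self.counts.shape:
            raise ValueError(f"mask shape {mask.shape} != {self.counts.shape}")
        self.counts += mask.astype(self.counts.dtype)
        self.n_frames += 1
        return self


@dataclass(frozen=True)
class ActivityResult:
    index: float
    band_lo: int
    band_hi: int
    n_pixels_in_band: int
    total_pixels: int


def accumulate(masks, shape=None) -> OccupancyAccumulator:
    """Sum a sequence of binary masks into an occupancy accumulator.

    ``shape`` is only needed when the sequence is empty.
    """
    masks = list(masks)
    if not masks:
        if shape is None:
            raise ValueError("shape required for an empty mask sequence")
        return OccupancyAccumulator(np.zeros(shape, dtype=np.int64), 0)
    first = np.asarray(masks[0])
    acc = OccupancyAccumulator(np.zeros(first.shape, dtype=np.int64), 0)
    for m in masks:
        acc.add(m)
    return acc


def activity_index(
    acc: OccupancyAccumulator, band_lo: int = DEFAULT_BAND[0], band_hi: int = DEFAULT_BAND[1]
) -> ActivityResult:
    """Fraction of pixels with occupancy count in [band_lo, band_hi]."""
    if band_lo > band_hi:
        raise ValueError(f"band_lo={band_lo} exceeds band_hi={band_hi}")
    in_band = int(((acc.counts >= band_lo) & (acc.counts <= band_hi)).sum())
    total = int(acc.counts.size)
    return ActivityResult(
        index=in_band / total,
        band_lo=band_lo,
        band_hi=band_hi,
        n_pixels_in_band=in_band,
        total_pixels=total,
    )


def heatmap_array(acc: OccupancyAccumulator, cmap: str = "jet") -> np.ndarray:
    """Map counts to RGB on a fixed 0..n_frames scale.

    Returns an (H, W, 3) uint8 array.  The mapping is pure array
    arithmetic, so re-rendering the same accumulator is byte-identical.
    """
    import matplotlib

    vmax = max(acc.n_frames, 1)
    norm = np.clip(acc.counts / vmax, 0.0, 1.0)
    rgba = matplotlib.colormaps[cmap](norm)
    return (rgba[..., :3] * 255).round().astype(np.uint8)


def render_heatmap(acc: OccupancyAccumulator, out_path, cmap: str = "jet") -> np.ndarray:
    """Write the occupancy heat map as a PNG with a colour-bar strip.

    The main panel uses the fixed 0..n_frames scale of
    :func:`heatmap_array`; a vertical gradient bar (top = n_frames) is
    appended on the right, separated by a white gutter.  Returns the
    composed RGB array that was written.
    """
    import imageio.v3 as iio
    import matplotlib

    panel = heatmap_array(acc, cmap)
    h = panel.shape[0]
    bar_ramp = np.linspace(1.0, 0.0, h)[:, None].repeat(max(8, h // 12), axis=1)
    bar = (matplotlib.colormaps[cmap](bar_ramp)[..., :3] * 255).round().astype(np.uint8)
    gutter = np.full((h, 4, 3), 255, dtype=np.uint8)
    composed = np.concatenate([panel, gutter, bar], axis=1)
    iio.imwrite(out_path, composed)
    return composed
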