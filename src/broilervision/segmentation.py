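"""Per-frame broiler-body masks: three-channel thresholding plus morphology.

A pixel is broiler body when it passes all three chroma tests
(``Cb < T_Cb``, ``b* > T_b``, ``Q < T_Q``): the first two reject the
achromatic litter and walls, the third rejects the similarly coloured
feeders and drinkers.  The raw mask is then refined by, in order,
small-object removal, morphological closing, opening, and small-hole
filling — the refinement chain that turns speckled per-pixel decisions
into solid bird blobs.

An alternative reading of the thresholding rule with the Cb and b*
inequalities inverted is available via ``eq2_verbatim=True`` for audit
purposes; under the standard orientations it selects litter rather than
birds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .colorspace import extract_component
from .thresholds import ThresholdSet

__all__ = ["MorphParams", "apply_thresholds", "refine_mask", "save_mask", "load_mask"]


@dataclass(frozen=True)
class MorphParams:
    """Sizes for the mask-refinement chain, in pixels at working resolution.

    Defaults are sized for birds of roughly 20x12 px at 384x216; scale
    areas quadratically (and the radius linearly) with resolution.
    """

    se_radius: int = 3
    min_object_area: int = 50
    max_hole_area: int = 200

    def __post_init__(self):
        if self.se_radius < 0 or self.min_object_area < 0 or self.max_hole_area < 0:
            raise ValueError("morphology parameters must be >= 0")

    @classmethod
    def scaled(cls, shape, base_shape=(216, 384)) -> "MorphParams":
        """Defaults rescaled for an image of the given (H, W)."""
        base = cls()
        s = np.sqrt((shape[0] * shape[1]) / (base_shape[0] * base_shape[1]))
        return cls(
            se_radius=max(1, round(base.se_radius * s)),
            min_object_area=max(1, round(base.min_object_area * s * s)),
            max_hole_area=max(1, round(base.max_hole_area * s * s)),
        )


def apply_thresholds(
    image: np.ndarray, thresholds: ThresholdSet, eq2_verbatim: bool = False
) -> np.ndarray:
    """Classify every pixel with the three learned cuts.

    Returns a uint8 mask, 1 = broiler body.  Purely per-pixel and
    deterministic.  With ``eq2_verbatim`` the Cb and b* comparisons are
    inverted (auditing switch; see module docstring).
    """
    cb = extract_component(image, "Cb")
    b = extract_component(image, "b")
    q = extract_component(image, "Q")
    if eq2_verbatim:
        mask = (cb > thresholds.t_cb) & (b < thresholds.t_b) & (q < thresholds.t_q)
    else:
        mask = (cb < thresholds.t_cb) & (b > thresholds.t_b) & (q < thresholds.t_q)
    return mask.astype(np.uint8)


def _fill_small_holes(mask: np.ndarray, max_hole_area: int) -> np.ndarray:
    # Holes: background components (4-connected) not touching the border.
    inv = ~mask
    lab, n = ndi.label(inv, structure=ndi.generate_binary_structure(2, 1))
    if n == 0:
        return mask
    border = np.zeros_like(mask, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = np.unique(lab[border & inv])
    areas = np.bincount(lab.ravel(), minlength=n + 1)
    fill = np.zeros(n + 1, dtype=bool)
    for lbl in range(1, n + 1):
        fill[lbl] = areas[lbl] <= max_hole_area and lbl not in border_labels
    return mask | fill[lab]


def refine_mask(mask: np.ndarray, params: MorphParams = MorphParams()) -> np.ndarray:
    """Refine a raw binary mask into solid bird blobs.

    Applies in order: removal of 8-connected components smaller than
    ``min_object_area``; closing then opening with a disk of
    ``se_radius``; filling of enclosed holes of area at most
    ``max_hole_area``.  A parameter of 0 makes its stage the identity.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    out = mask.astype(bool)
    if params.min_object_area > 0:
        # drop 8-connected components of area strictly below min_object_area
        out = morphology.remove_small_objects(
            out, max_size=params.min_object_area - 1, connectivity=2
        )
    if params.se_radius > 0:
        se = morphology.disk(params.se_radius)
        out = morphology.closing(out, se)
        out = morphology.opening(out, se)
    if params.max_hole_area > 0:
        out = _fill_small_holes(out, params.max_hole_area)
    return out.astype(np.uint8)


def save_mask(mask: np.ndarray, path) -> None:
    """Persist a binary mask as a single-channel 0/255 PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def load_mask(path) -> np.ndarray:
    """Read a 0/255 single-channel PNG back into a 0/1 uint8 mask."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)
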