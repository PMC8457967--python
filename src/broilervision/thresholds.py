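"""Learning per-channel cut values from labelled pixel patches.

The segmentation rule is three scalar thresholds, one per chroma plane.
Each is learned as a two-class problem: given component values sampled
from patches of the two materials, choose the cut ``T`` that maximises
the number of correctly classified samples,

    score(T) = #{v in lower class : v < T} + #{v in upper class : v > T}.

The score is piecewise constant between data values, so the search is
over midpoints of consecutive distinct pooled values, plus one candidate
below the minimum and one above the maximum.  Ties between equally good
cuts are broken toward the widest run of maximal candidates (the
largest-margin cut) and then toward the lowest-valued run, which makes
the result deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import extract_component

__all__ = [
    "ThresholdSet",
    "extract_patch_samples",
    "learn_threshold",
    "learn_threshold_set",
]


@dataclass(frozen=True)
class ThresholdSet:
    """The three learned cut values and their fixed class orientations.

    Orientations: broiler body has ``Cb < t_cb`` (litter above), ``b > t_b``
    (litter below) and ``Q < t_q`` (feeder/drinker above).
    """

    t_b: float
    t_cb: float
    t_q: float

    def as_dict(self) -> dict:
        return {"t_b": self.t_b, "t_cb": self.t_cb, "t_q": self.t_q}


def extract_patch_samples(
    image: np.ndarray,
    patch_origins,
    patch_size: int,
    channel_id: str,
    n_samples: int,
    seed: int,
) -> np.ndarray:
    """Draw component values uniformly without replacement from patches.

    Parameters
    ----------
    image : ndarray (H, W, 3)
        Source RGB frame.
    patch_origins : sequence of (row, col)
        Top-left corners of square patches; every patch must lie inside
        the image.
    patch_size : int
        Side length of each patch in pixels.
    channel_id : {"Cb", "b", "Q"}
        Chroma plane to sample.
    n_samples : int
        Number of pixel values to draw from the pooled patch pixels.
    seed : int
        Seed for the (reproducible) draw.

    Returns
    -------
    ndarray of float, shape (n_samples,)
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    origins = [(int(r), int(c)) for r, c in patch_origins]
    for r, c in origins:
        if r < 0 or c < 0 or r + patch_size > h or c + patch_size > w:
            raise IndexError(
                f"patch at ({r}, {c}) size {patch_size} exceeds image bounds {h}x{w}"
            )
    plane = extract_component(image, channel_id)
    pool = np.concatenate(
        [plane[r : r + patch_size, c : c + patch_size].ravel() for r, c in origins]
    )
    if n_samples > pool.size:
        raise ValueError(f"n_samples={n_samples} exceeds {pool.size} pooled patch pixels")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pool.size, size=n_samples, replace=False)
    return pool[idx]


def _score_candidates(lo: np.ndarray, hi: np.ndarray, cands: np.ndarray) -> np.ndarray:
    # vectorised: for each cut, count lo-values strictly below and hi-values strictly above
    lo_sorted = np.sort(lo)
    hi_sorted = np.sort(hi)
    below = np.searchsorted(lo_sorted, cands, side="left")
    above = hi_sorted.size - np.searchsorted(hi_sorted, cands, side="right")
    return below + above


def learn_threshold(class_lo, class_hi) -> float:
    """Learn the cut maximising correctly classified samples.

    ``class_lo`` holds the values expected *below* the cut, ``class_hi``
    those expected *above*.  Returns the deterministic optimal cut; its
    score equals the brute-force maximum over all candidate midpoints.
    """
    lo = np.asarray(class_lo, dtype=np.float64).ravel()
    hi = np.asarray(class_hi, dtype=np.float64).ravel()
    if lo.size == 0 or hi.size == 0:
        raise ValueError("both sample sets must be nonempty")
    if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
        raise ValueError("sample values must be finite")

    pooled = np.unique(np.concatenate([lo, hi]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else np.empty(0)
    cands = np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])
    scores = _score_candidates(lo, hi, cands)
    best = scores.max()

    # Each candidate sits in the open interval (left_i, right_i) bounded by
    # adjacent pooled values (the edge candidates bound themselves); the
    # score is constant on that interval but dips at pooled values, so each
    # maximal candidate is its own run.  Pick the widest run, then the
    # lowest-valued one.
    left = np.concatenate([[cands[0]], pooled])
    right = np.concatenate([pooled, [cands[-1]]])
    widths = right - left
    best_idx = np.flatnonzero(scores == best)
    winner = best_idx[np.argmax(widths[best_idx])]  # argmax keeps the lowest on ties
    return float((left[winner] + right[winner]) / 2.0)


def learn_threshold_set(
    litter_b, body_b, litter_cb, body_cb, body_q, feeder_q
) -> ThresholdSet:
    """Learn the three cuts with the standard class orientations.

    litter sits below the b* cut and above the Cb cut; the broiler body
    sits below the Q cut with feeders/drinkers above.
    """
    return ThresholdSet(
        t_b=learn_threshold(litter_b, body_b),
        t_cb=learn_threshold(body_cb, litter_cb),
        t_q=learn_threshold(body_q, feeder_q),
    )
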