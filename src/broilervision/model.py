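"""Scikit-learn style estimator wrapping the whole segmentation model.

`ChromaThresholdSegmenter` is a three-class-to-binary pixel classifier:
it is fitted on labelled RGB pixel samples (litter / body / feeder) and
predicts, per pixel, whether it belongs to a broiler body.  Internally it
learns one scalar cut per chroma plane (Cb, b*, Q) by maximising the
count of correctly classified training samples, and applies them jointly
at prediction time.  It composes with sklearn pipelines and model
selection (`get_params`/`set_params`, `fit`/`predict`/`score`).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .colorspace import extract_component
from .segmentation import MorphParams, apply_thresholds, refine_mask
from .thresholds import ThresholdSet, extract_patch_samples, learn_threshold_set

__all__ = ["ChromaThresholdSegmenter", "CLASS_LABELS"]

CLASS_LABELS = ("litter", "body", "feeder")


class ChromaThresholdSegmenter(BaseEstimator, ClassifierMixin):
    """Threshold-based broiler-body pixel classifier.

    Parameters
    ----------
    eq2_verbatim : bool, default False
        Audit switch inverting the Cb and b* comparisons (see
        :mod:`broilervision.segmentation`).
    se_radius, min_object_area, max_hole_area : int
        Morphological refinement sizes used by :meth:`segment`; ``None``
        for the area parameters means "scale the defaults to the frame".

    Attributes
    ----------
    thresholds_ : ThresholdSet
        The learned cuts ``t_b``, ``t_cb``, ``t_q``.
    classes_ : ndarray
        ``[0, 1]`` — background vs broiler body.
    """

    def __init__(
        self,
        eq2_verbatim: bool = False,
        se_radius: int = 3,
        min_object_area: int | None = None,
        max_hole_area: int | None = None,
    ):
        self.eq2_verbatim = eq2_verbatim
        self.se_radius = se_radius
        self.min_object_area = min_object_area
        self.max_hole_area = max_hole_area

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        """Learn the three cuts from labelled RGB pixels.

        Parameters
        ----------
        X : array-like, shape (n_samples, 3)
            RGB pixel values in [0, 255].
        y : array-like of str, shape (n_samples,)
            Material labels, from {"litter", "body", "feeder"}.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n_samples, 3) RGB values")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        unknown = set(np.unique(y)) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels {sorted(unknown)}")
        for need in ("litter", "body", "feeder"):
            if not (y == need).any():
                raise ValueError(f"no samples for class {need!r}")

        pix = X.reshape(-1, 1, 3)
        planes = {ch: extract_component(pix, ch).ravel() for ch in ("Cb", "b", "Q")}
        lit, bod, fee = (y == "litter", y == "body", y == "feeder")
        self.thresholds_ = learn_threshold_set(
            litter_b=planes["b"][lit],
            body_b=planes["b"][bod],
            litter_cb=planes["Cb"][lit],
            body_cb=planes["Cb"][bod],
            body_q=planes["Q"][bod],
            feeder_q=planes["Q"][fee],
        )
        self.classes_ = np.array([0, 1])
        return self

    @classmethod
    def fit_from_patches(
        cls,
        image: np.ndarray,
        patches: dict,
        patch_size: int = 20,
        n_samples: int = 100,
        seed: int = 0,
        **params,
    ) -> "ChromaThresholdSegmenter":
        """Fit from labelled square patches on a frame.

        ``patches`` maps each class label to a list of (row, col) patch
        origins; ``n_samples`` component values per class and channel are
        drawn without replacement (seeded) from the pooled patch pixels.
        """
        est = cls(**params)
        samples = {
            (lbl, ch): extract_patch_samples(
                image, origins, patch_size, ch, n_samples, seed=seed + k
            )
            for k, (lbl, origins) in enumerate(sorted(patches.items()))
            for ch in ("Cb", "b", "Q")
        }
        est.thresholds_ = learn_threshold_set(
            litter_b=samples[("litter", "b")],
            body_b=samples[("body", "b")],
            litter_cb=samples[("litter", "Cb")],
            body_cb=samples[("body", "Cb")],
            body_q=samples[("body", "Q")],
            feeder_q=samples[("feeder", "Q")],
        )
        est.classes_ = np.array([0, 1])
        return est

    # -------------------------------------------------------------- predict
    def predict(self, X):
        """Predict 1 (broiler body) / 0 per RGB pixel row."""
        check_is_fitted(self, "thresholds_")
        X = np.asarray(X, dtype=np.float64)
        img = X.reshape(-1, 1, 3)
        return apply_thresholds(img, self.thresholds_, self.eq2_verbatim).ravel()

    def segment(self, image: np.ndarray, refine: bool = True) -> np.ndarray:
        """Segment a full frame into a 0/1 broiler-body mask."""
        check_is_fitted(self, "thresholds_")
        raw = apply_thresholds(image, self.thresholds_, self.eq2_verbatim)
        if not refine:
            return raw
        return refine_mask(raw, self.morph_params(image.shape[:2]))

    def morph_params(self, shape) -> MorphParams:
        """Resolve morphology parameters for a frame of the given shape."""
        scaled = MorphParams.scaled(shape)
        return MorphParams(
            se_radius=self.se_radius,
            min_object_area=(
                scaled.min_object_area
                if self.min_object_area is None
                else self.min_object_area
            ),
            max_hole_area=(
                scaled.max_hole_area
                if self.max_hole_area is None
                else self.max_hole_area
            ),
        )

    def set_thresholds(self, thresholds: ThresholdSet) -> "ChromaThresholdSegmenter":
        """Install externally learned cuts (e.g. loaded from disk)."""
        self.thresholds_ = thresholds
        self.classes_ = np.array([0, 1])
        return self
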