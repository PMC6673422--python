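"""Informative-frame filtering.

Long procedure videos contain many frames with no usable visual content —
motion blur, excessive darkness or brightness, other non-observable screens —
and such frames degrade everything downstream, so only informative frames
enter the flow/classification chain.  Each frame is summarised by seven
statistics: the intensity mean, variance and skewness; the correlation and
contrast of a gray-level co-occurrence matrix (32 levels, offset (0, 1),
symmetric, normalised); and two canonical focus measures, the energy of the
4-neighbour Laplacian and the energy of the first-difference gradient (both
mean squared response per pixel).  A support-vector classifier with an RBF
kernel, grid-searched under 5-fold cross-validation on standardized
features, separates informative from non-informative frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.feature import graycomatrix, graycoprops

from .ingest import FrameImage

FEATURE_NAMES = (
    "mean",
    "variance",
    "skewness",
    "correlation",
    "contrast",
    "energy_of_laplacian",
    "energy_of_gradient",
)

_GLCM_LEVELS = 32
_LAPLACE_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)


@dataclass(frozen=True)
class InformativeFeatures:
    """The seven per-frame statistics, in :data:`FEATURE_NAMES` order."""

    mean: float
    variance: float
    skewness: float
    correlation: float
    contrast: float
    energy_of_laplacian: float
    energy_of_gradient: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def _quantize(gray: np.ndarray) -> np.ndarray:
    """Map intensities onto the GLCM's 32 gray levels."""
    if gray.dtype == np.uint8:
        return (gray // (256 // _GLCM_LEVELS)).astype(np.uint8)
    lo, hi = float(gray.min()), float(gray.max())
    if hi == lo:
        return np.zeros_like(gray, dtype=np.uint8)
    scaled = (gray - lo) / (hi - lo) * (_GLCM_LEVELS - 1)
    return np.round(scaled).astype(np.uint8)


def compute_features(frame: FrameImage | np.ndarray) -> InformativeFeatures:
    """The seven statistics over all pixels of a grayscale frame.

    Degenerate constant frames get skewness and correlation 0 by convention
    (the underlying moments vanish) rather than raising.
    """
    pixels = frame.pixels if isinstance(frame, FrameImage) else np.asarray(frame)
    if pixels.ndim != 2:
        raise ValueError("features are defined on grayscale frames; convert first")
    gray = pixels.astype(float)
    flat = gray.ravel()
    variance = float(flat.var())
    constant = variance == 0.0
    skewness = 0.0 if constant else float(stats.skew(flat))
    if constant:
        correlation, contrast = 0.0, 0.0
    else:
        glcm = graycomatrix(
            _quantize(pixels if pixels.ndim == 2 else gray),
            distances=[1],
            angles=[0.0],  # offset (0, 1): one step along the row
            levels=_GLCM_LEVELS,
            symmetric=True,
            normed=True,
        )
        contrast = float(graycoprops(glcm, "contrast")[0, 0])
        correlation = float(graycoprops(glcm, "correlation")[0, 0])
    lap = ndimage.correlate(gray, _LAPLACE_KERNEL, mode="nearest")
    gx = np.diff(gray, axis=1)
    gy = np.diff(gray, axis=0)
    return InformativeFeatures(
        mean=float(flat.mean()),
        variance=variance,
        skewness=skewness,
        correlation=correlation,
        contrast=contrast,
        energy_of_laplacian=float((lap**2).mean()),
        energy_of_gradient=float((gx**2).sum() + (gy**2).sum()) / gray.size,
    )


@dataclass
class InformativeModel:
    """Fitted informative-vs-non-informative classifier.

    Wraps a standardizing SVC pipeline; ``cv_accuracy`` is the 5-fold
    cross-validated accuracy achieved by the selected hyperparameters.
    """

    pipeline: object
    cv_accuracy: float
    version: str = "1"

    def save(self, path: str | Path) -> None:
        import joblib

        joblib.dump({"version": self.version, "pipeline": self.pipeline,
                     "cv_accuracy": self.cv_accuracy}, path)

    @classmethod
    def load(cls, path: str | Path) -> "InformativeModel":
        import joblib

        payload = joblib.load(path)
        return cls(pipeline=payload["pipeline"], cv_accuracy=payload["cv_accuracy"],
                   version=payload["version"])


def train_informative(
    features: Sequence[InformativeFeatures], labels: Sequence[bool]
) -> InformativeModel:
    """Fit the RBF-SVC on standardized features with grid-searched C and gamma.

    Hyperparameters are selected by 5-fold cross-validation (fewer folds only
    if a class has fewer than five members); requires both classes present
    with at least two samples each.
    """
    from sklearn.model_selection import GridSearchCV
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    x = np.stack([f.to_array() for f in features])
    y = np.asarray(labels, dtype=bool)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("training needs at least two samples of each class")
    cv = int(min(5, counts.min()))
    search = GridSearchCV(
        Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))]),
        param_grid={"svc__C": [0.1, 1.0, 10.0, 100.0],
                    "svc__gamma": ["scale", 0.01, 0.1]},
        cv=cv,
        scoring="accuracy",
    )
    search.fit(x, y)
    return InformativeModel(
        pipeline=search.best_estimator_, cv_accuracy=float(search.best_score_)
    )


def classify_informative(frame: FrameImage | np.ndarray, model: InformativeModel) -> bool:
    """Deterministic informative flag for one frame."""
    if model.pipeline is None:
        raise RuntimeError("informative model is not trained")
    features = compute_features(frame)
    return bool(model.pipeline.predict(features.to_array()[None, :])[0])
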