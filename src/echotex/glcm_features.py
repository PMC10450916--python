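"""Gray-level co-occurrence matrices and scalar texture features.

A gray-level co-occurrence matrix (GLCM) tabulates, for a fixed pixel
offset, how often a reference pixel with gray level ``i`` has a neighbor
with gray level ``j``.  For an 8-bit image with 256 gray levels the matrix
is 256 x 256.  Normalized to probabilities, the matrix supports the classic
Haralick-style scalar texture features used throughout quantitative
ultrasound and radiomics work: contrast, dissimilarity, homogeneity,
angular second moment (ASM), energy, entropy and correlation.

Conventions
-----------
* Angle 0 degrees means the neighbor lies ``distance`` pixels to the
  *right* of the reference; 45/90/135 degrees rotate counter-clockwise
  (45 = up-right, 90 = up, 135 = up-left).  Pairs are counted only when
  both pixels lie inside the image; there is no padding.
* ``symmetric=True`` also counts every pair in the reversed order, so the
  matrix equals its transpose.
* Entropy uses the natural logarithm with the ``0 * ln 0 = 0`` convention.
* ``energy = sqrt(ASM)``.
* Correlation of a constant image (zero marginal variance) is defined as 1:
  a constant image is perfectly self-similar.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FEATURE_NAMES",
    "ANGLES",
    "GlcmParams",
    "GLCM",
    "FeatureVector",
    "quantize_image",
    "compute_glcm",
    "compute_features",
    "image_features",
    "GLCMFeaturizer",
]

#: Canonical feature order used in tables and CSV output.
FEATURE_NAMES = (
    "entropy",
    "asm",
    "energy",
    "contrast",
    "dissimilarity",
    "homogeneity",
    "correlation",
)

#: Unit (row, col) offsets per supported angle, 0 deg = right neighbor,
#: rotating counter-clockwise (row axis points down, so "up" is -1).
ANGLES = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GlcmParams:
    """Parameters of a single-offset GLCM.

    distance : offset length in pixels (>= 1)
    angle    : one of 0, 45, 90, 135 degrees (see module docstring)
    levels   : number of gray levels (>= 2); pixels must lie in
               ``[0, levels - 1]``
    symmetric : count each pair in both orders
    normalized : divide counts by the number of pairs so entries sum to 1
    """

    distance: int = 5
    angle: int = 0
    levels: int = 256
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")
        if self.angle not in ANGLES:
            raise ValueError(
                f"angle must be one of {sorted(ANGLES)}, got {self.angle}"
            )
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")

    @property
    def offset(self) -> tuple[int, int]:
        """(row, col) displacement from reference to neighbor."""
        dr, dc = ANGLES[self.angle]
        return dr * self.distance, dc * self.distance


@dataclass(frozen=True)
class GLCM:
    """A co-occurrence matrix plus the parameters that produced it.

    ``p`` holds probabilities when ``params.normalized`` else raw integer
    counts; ``n_pairs`` is the total number of pairs counted (transposed
    pairs included when symmetric).
    """

    p: np.ndarray
    params: GlcmParams
    n_pairs: int


@dataclass(frozen=True)
class FeatureVector:
    """The seven GLCM texture features, in no particular units."""

    entropy: float
    asm: float
    energy: float
    contrast: float
    dissimilarity: float
    homogeneity: float
    correlation: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def _as_image(raw) -> np.ndarray:
    a = np.asarray(raw)
    if a.size == 0:
        raise ValueError("empty image")
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    return a


def quantize_image(raw, levels: int = 256) -> np.ndarray:
    """Map an arbitrary 2-D intensity array onto integer gray levels.

    Inputs that are already integer-valued and within ``[0, levels - 1]``
    pass through unchanged (so 8-bit images are not re-stretched).  Anything
    else is linearly rescaled from ``[min, max]`` onto ``[0, levels - 1]``
    and rounded half toward zero; a constant input maps to all zeros.
    """
    a = _as_image(raw)
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    vals = a.astype(np.float64, copy=False)
    if np.allclose(vals, np.round(vals)) and vals.min() >= 0 and vals.max() <= levels - 1:
        return np.round(vals).astype(np.int64)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return np.zeros(a.shape, dtype=np.int64)
    scaled = (vals - lo) * (levels - 1) / (hi - lo)
    # round half toward zero: 1.5 -> 1 (values are non-negative here)
    return np.ceil(scaled - 0.5).astype(np.int64)


def compute_glcm(image, params: GlcmParams | None = None, **kwargs) -> GLCM:
    """Build the co-occurrence matrix of ``image`` for one offset.

    ``image`` is a 2-D integer array with values in ``[0, params.levels)``.
    Keyword arguments (``distance``, ``angle``, ...) may be given instead of
    a :class:`GlcmParams`.
    """
    if params is None:
        params = GlcmParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either params or keyword arguments, not both")
    img = _as_image(image)
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError("image must contain integer gray levels; quantize first")
    L = params.levels
    if img.min() < 0 or img.max() >= L:
        raise ValueError(
            f"pixel exceeds gray-level range: values in [{img.min()}, {img.max()}]"
            f" but levels={L}"
        )
    dr, dc = params.offset
    h, w = img.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(
            f"ROI too small for offset: image {h}x{w}, offset ({dr}, {dc})"
        )
    ref = img[r0:r1, c0:c1].astype(np.int64)
    nb = img[r0 + dr : r1 + dr, c0 + dc : c1 + dc].astype(np.int64)
    counts = np.bincount((ref * L + nb).ravel(), minlength=L * L).reshape(L, L)
    n_pairs = ref.size
    if params.symmetric:
        counts = counts + counts.T
        n_pairs *= 2
    if params.normalized:
        p = counts / n_pairs
    else:
        p = counts
    return GLCM(p=p, params=params, n_pairs=n_pairs)


def _glcm_matrix(glcm) -> np.ndarray:
    p = glcm.p if isinstance(glcm, GLCM) else np.asarray(glcm, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError(f"GLCM must be square, got shape {p.shape}")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("GLCM must be normalized (entries must sum to 1)")
    return np.asarray(p, dtype=np.float64)


def compute_features(glcm) -> FeatureVector:
    """Compute the seven texture features of a normalized GLCM.

    With ``p(i, j)`` the matrix entries and ``mu``/``sigma`` the means and
    standard deviations of the row and column marginals:

    * contrast       = sum p(i,j) (i - j)^2
    * dissimilarity  = sum p(i,j) |i - j|
    * homogeneity    = sum p(i,j) / (1 + (i - j)^2)
    * ASM            = sum p(i,j)^2
    * energy         = sqrt(ASM)
    * entropy        = -sum_{p>0} p(i,j) ln p(i,j)
    * correlation    = sum p(i,j)(i - mu_i)(j - mu_j) / (sigma_i sigma_j),
      defined as 1 when sigma_i sigma_j = 0.
    """
    p = _glcm_matrix(glcm)
    L = p.shape[0]
    idx = np.arange(L, dtype=np.float64)
    d = idx[:, None] - idx[None, :]
    contrast = float((p * d**2).sum())
    dissimilarity = float((p * np.abs(d)).sum())
    homogeneity = float((p / (1.0 + d**2)).sum())
    asm = float((p**2).sum())
    energy = float(np.sqrt(asm))
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    mu_i, mu_j = float(idx @ pi), float(idx @ pj)
    var_i = float(((idx - mu_i) ** 2) @ pi)
    var_j = float(((idx - mu_j) ** 2) @ pj)
    denom = np.sqrt(var_i * var_j)
    if denom == 0.0:
        correlation = 1.0
    else:
        cov = float(((idx - mu_i)[:, None] * (idx - mu_j)[None, :] * p).sum())
        correlation = float(cov / denom)
    return FeatureVector(
        entropy=entropy,
        asm=asm,
        energy=energy,
        contrast=contrast,
        dissimilarity=dissimilarity,
        homogeneity=homogeneity,
        correlation=correlation,
    )


def image_features(
    image,
    params: GlcmParams | None = None,
    average_angles: bool = False,
    **kwargs,
) -> FeatureVector:
    """Quantize-free convenience: GLCM + features for one integer image.

    With ``average_angles=True`` the features (not the matrices) are
    averaged over the four supported angles at the given distance.
    """
    if params is None:
        params = GlcmParams(**kwargs)
    if not params.normalized:
        params = GlcmParams(
            distance=params.distance,
            angle=params.angle,
            levels=params.levels,
            symmetric=params.symmetric,
            normalized=True,
        )
    if not average_angles:
        return compute_features(compute_glcm(image, params))
    vecs = []
    for ang in ANGLES:
        p = GlcmParams(
            distance=params.distance,
            angle=ang,
            levels=params.levels,
            symmetric=params.symmetric,
            normalized=True,
        )
        vecs.append(compute_features(compute_glcm(image, p)).as_array())
    mean = np.mean(vecs, axis=0)
    return FeatureVector(**dict(zip(FEATURE_NAMES, map(float, mean))))


class GLCMFeaturizer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: gray-level images -> texture feature matrix.

    ``transform`` accepts a sequence of 2-D integer arrays (gray levels in
    ``[0, levels - 1]``) and returns an ``(n_images, 7)`` float array in
    :data:`FEATURE_NAMES` order.  Stateless apart from validation, so
    ``fit`` only records the parameters; it composes with sklearn pipelines
    feeding e.g. :class:`~echotex.pca_explore.TexturePCA`.

    Parameters
    ----------
    distance, angle, levels, symmetric
        See :class:`GlcmParams`.
    average_angles
        Average features over the four angles instead of using ``angle``.
    """

    def __init__(
        self,
        distance: int = 5,
        angle: int = 0,
        levels: int = 256,
        symmetric: bool = True,
        average_angles: bool = False,
    ):
        self.distance = distance
        self.angle = angle
        self.levels = levels
        self.symmetric = symmetric
        self.average_angles = average_angles

    def _params(self) -> GlcmParams:
        return GlcmParams(
            distance=self.distance,
            angle=self.angle,
            levels=self.levels,
            symmetric=self.symmetric,
            normalized=True,
        )

    def fit(self, X: Iterable[np.ndarray], y=None) -> "GLCMFeaturizer":
        self._params()  # validate
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X: Iterable[np.ndarray]) -> np.ndarray:
        params = self._params()
        rows = [
            image_features(img, params, average_angles=self.average_angles).as_array()
            for img in X
        ]
        if not rows:
            return np.empty((0, len(FEATURE_NAMES)))
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES, dtype=object)
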