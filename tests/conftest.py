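"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from echotex import CohortSpec, FEATURE_NAMES, make_cohort

#: unit offsets mirrored from the documented angle convention, but used by
#: a deliberately naive double-loop oracle below
_UNIT = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(img, distance, angle, levels, symmetric, normalized):
    """Explicit pixel-pair enumeration; the oracle for compute_glcm.

    Walks every pixel, checks whether its offset neighbor is inside the
    image, and increments one cell at a time.  Intentionally O(H*W) python
    loops with no shared code with the implementation.
    """
    dr, dc = _UNIT[angle]
    dr, dc = dr * distance, dc * distance
    h, w = img.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    n = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[img[r, c], img[r2, c2]] += 1
                n += 1
    if symmetric:
        counts = counts + counts.T
        n *= 2
    if normalized:
        return counts / n, n
    return counts, n


def correlation_pca_oracle(X):
    """Eigendecomposition of the sample correlation matrix.

    Returns (variance fractions, loading matrix) with components ordered by
    decreasing eigenvalue; signs are NOT fixed (compare magnitudes).
    """
    R = np.corrcoef(np.asarray(X, dtype=float), rowvar=False)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    return w / w.sum(), V


def random_feature_table(n=40, seed=0):
    """A synthetic feature table with plausible correlation structure."""
    from echotex.roi_io import CSV_COLUMNS

    rng = np.random.default_rng(seed)
    t = rng.standard_normal(n)  # latent "texture roughness"
    noise = lambda s: rng.standard_normal(n) * s  # noqa: E731
    asm = 1 / (1 + np.exp(t + noise(0.3)))
    feats = pd.DataFrame(
        {
            "entropy": 4 + t + noise(0.3),
            "asm": asm,
            "energy": np.sqrt(asm),
            "contrast": np.exp(2 + 0.8 * t + noise(0.2)),
            "dissimilarity": np.exp(1 + 0.8 * t + noise(0.2)),
            "homogeneity": 1 / (1 + np.exp(0.5 * t + noise(0.2))),
            "correlation": np.tanh(0.5 + noise(0.5)),
        }
    )
    meta = pd.DataFrame(
        {
            "image_id": [f"img_{i:03d}.png" for i in range(n)],
            "x0": 0,
            "y0": 0,
            "x1": 64,
            "y1": 64,
            "plane": ["sagittal", "transverse"] * (n // 2) + ["sagittal"] * (n % 2),
            "side": "left",
            "mineralization": False,
            "nodule": False,
            "lesion_label": "normal",
        }
    )
    df = pd.concat([meta, feats], axis=1)[CSV_COLUMNS]
    from echotex import FeatureTable

    return FeatureTable(df)


@pytest.fixture(scope="session")
def lesion_cohort():
    """Seeded 40 normal + 40 microlith phantom cohort with features.

    Session-scoped: several tests examine the same cohort (group feature
    directions, PCA separation, correlation signs).
    """
    from echotex import GLCMFeaturizer

    spec = CohortSpec(n_normal=40, n_microlith=40, n_other=0, seed=20240901)
    images, rois = make_cohort(spec)
    X = GLCMFeaturizer(distance=5, levels=256, symmetric=True).fit_transform(images)
    feats = pd.DataFrame(X, columns=FEATURE_NAMES)
    feats["lesion_label"] = rois["lesion_label"].to_numpy()
    return feats
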