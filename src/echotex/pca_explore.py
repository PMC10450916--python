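"""PCA exploration of texture-feature tables: scores, loadings, biplots.

Features live on wildly different scales (GLCM contrast can be in the
thousands while ASM is below 1), so the analysis standardizes each feature
to zero mean and unit variance before the decomposition — i.e. PCA of the
sample correlation matrix.  Component signs are made deterministic by
flipping each loading column so its largest-magnitude entry is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .glcm_features import FEATURE_NAMES

__all__ = [
    "TexturePCA",
    "PCAResult",
    "run_pca",
    "biplot_data",
    "save_biplot",
    "feature_correlations",
]


def _as_matrix(table) -> tuple[np.ndarray, list[str]]:
    """Accept a FeatureTable, DataFrame or ndarray; return (X, names)."""
    if hasattr(table, "feature_matrix"):  # FeatureTable
        return table.feature_matrix(), list(table.feature_names)
    if isinstance(table, pd.DataFrame):
        cols = [c for c in FEATURE_NAMES if c in table.columns]
        if len(cols) == len(FEATURE_NAMES):
            return table[cols].to_numpy(dtype=np.float64), cols
        num = table.select_dtypes(include=[np.number])
        return num.to_numpy(dtype=np.float64), list(num.columns)
    X = np.asarray(table, dtype=np.float64)
    return X, [f"f{i}" for i in range(X.shape[1])]


class TexturePCA(TransformerMixin, BaseEstimator):
    """Standardized (correlation-matrix) PCA with a fixed sign convention.

    Parameters
    ----------
    n_components : int or None
        Number of components to keep; ``None`` keeps all features.

    Attributes (after ``fit``)
    --------------------------
    mean_, scale_ : per-feature centering and scaling vectors (ddof=1 std)
    loadings_ : (n_features, k) orthonormal loading columns; within each
        column the entry of largest magnitude is positive
    explained_variance_ : per-component variance of the scores
    explained_variance_ratio_ : fractions of total variance; sums to 1
        when all components are kept
    feature_names_in_ : names of the input features when available
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None) -> "TexturePCA":
        M, names = _as_matrix(X)
        if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
            raise ValueError(
                f"need at least 2 records and 2 features, got shape {M.shape}"
            )
        if np.isnan(M).any():
            raise ValueError("feature matrix contains missing values")
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.mean_ = M.mean(axis=0)
        self.scale_ = M.std(axis=0, ddof=1)
        dead = np.flatnonzero(self.scale_ == 0)
        if dead.size:
            raise ValueError(
                f"zero-variance feature(s) cannot be standardized: "
                f"{[names[i] for i in dead]}"
            )
        Z = (M - self.mean_) / self.scale_
        # all retainable components by default (rank-limited when n < p)
        k = self.n_components or min(M.shape)
        if k > M.shape[1]:
            raise ValueError(f"n_components={k} exceeds feature count {M.shape[1]}")
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(Z)
        loadings = pca.components_.T  # (p, k), orthonormal columns
        # deterministic signs: largest-magnitude entry of each column positive
        flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        self.loadings_ = loadings * flip
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.n_components_ = k
        return self

    def transform(self, X) -> np.ndarray:
        M, _ = _as_matrix(X)
        Z = (M - self.mean_) / self.scale_
        return Z @ self.loadings_

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(
            [f"PC{i + 1}" for i in range(self.n_components_)], dtype=object
        )


@dataclass(frozen=True)
class PCAResult:
    """Loadings, scores and variance fractions of one fitted PCA."""

    loadings: pd.DataFrame  # features x components
    scores: pd.DataFrame  # records x components
    variance_explained: np.ndarray  # fractions, one per kept component
    center: np.ndarray
    scale: np.ndarray

    @property
    def component_names(self) -> list[str]:
        return list(self.loadings.columns)


def run_pca(table, k: int | None = None) -> PCAResult:
    """Fit a standardized PCA to a feature table and package the result."""
    est = TexturePCA(n_components=k).fit(table)
    M, names = _as_matrix(table)
    comps = [f"PC{i + 1}" for i in range(est.n_components_)]
    scores = est.transform(table)
    return PCAResult(
        loadings=pd.DataFrame(est.loadings_, index=names, columns=comps),
        scores=pd.DataFrame(scores, columns=comps),
        variance_explained=np.asarray(est.explained_variance_ratio_),
        center=est.mean_,
        scale=est.scale_,
    )


def feature_correlations(table) -> pd.DataFrame:
    """Pearson correlation matrix between features.

    Zero-variance features yield NaN in their row/column (undefined, never
    silently zero).  Requires at least 3 records.
    """
    M, names = _as_matrix(table)
    if M.shape[0] < 3:
        raise ValueError(f"need at least 3 records, got {M.shape[0]}")
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(M, rowvar=False)
    return pd.DataFrame(C, index=names, columns=names)


def biplot_data(
    result: PCAResult,
    table,
    label_column: str | None = None,
    pcs: tuple[int, int] = (1, 2),
) -> dict:
    """Assemble the plot-ready scores and loading arrows for a biplot.

    ``pcs`` are 1-based component indices.  Returns a dict with
    ``scores`` (score_x, score_y, label per record), ``loadings``
    (loading_x, loading_y, arrow_x, arrow_y, name per feature — arrows are
    loadings scaled by the component standard deviation for display) and
    ``variance`` (the two components' variance fractions).
    """
    names = result.component_names
    for pc in pcs:
        if not 1 <= pc <= len(names):
            raise ValueError(f"component {pc} not available; have {names}")
    cx, cy = f"PC{pcs[0]}", f"PC{pcs[1]}"
    if label_column is None:
        labels = pd.Series(["all"] * len(result.scores))
    else:
        df = table.df if hasattr(table, "df") else pd.DataFrame(table)
        if label_column not in df.columns:
            raise ValueError(
                f"unknown label column {label_column!r}; available: "
                f"{sorted(df.columns)}"
            )
        labels = df[label_column].reset_index(drop=True)
    scores = pd.DataFrame(
        {
            "score_x": result.scores[cx],
            "score_y": result.scores[cy],
            "label": labels.astype(str),
        }
    )
    ix, iy = pcs[0] - 1, pcs[1] - 1
    # component std: total variance of standardized data equals the feature
    # count, so var(PC_i) = ratio_i * n_features
    p = len(result.loadings)
    sx = np.sqrt(result.variance_explained[ix] * p)
    sy = np.sqrt(result.variance_explained[iy] * p)
    loadings = pd.DataFrame(
        {
            "name": result.loadings.index,
            "loading_x": result.loadings[cx].to_numpy(),
            "loading_y": result.loadings[cy].to_numpy(),
            "arrow_x": result.loadings[cx].to_numpy() * sx,
            "arrow_y": result.loadings[cy].to_numpy() * sy,
        }
    )
    return {
        "scores": scores,
        "loadings": loadings,
        "variance": (
            float(result.variance_explained[ix]),
            float(result.variance_explained[iy]),
        ),
        "pcs": (cx, cy),
    }


def save_biplot(data: dict, path) -> None:
    """Render the biplot_data structure to an image file (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    scores = data["scores"]
    for label, grp in scores.groupby("label", sort=True):
        ax.scatter(grp["score_x"], grp["score_y"], s=14, alpha=0.7, label=str(label))
    span = max(
        float(np.abs(scores[["score_x", "score_y"]].to_numpy()).max()), 1e-9
    )
    arrows = data["loadings"]
    amax = max(float(np.abs(arrows[["arrow_x", "arrow_y"]].to_numpy()).max()), 1e-9)
    k = 0.8 * span / amax
    for _, row in arrows.iterrows():
        ax.annotate(
            "",
            xy=(row["arrow_x"] * k, row["arrow_y"] * k),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="red", lw=1.2),
        )
        ax.text(
            row["arrow_x"] * k * 1.07,
            row["arrow_y"] * k * 1.07,
            row["name"],
            color="red",
            fontsize=9,
            ha="center",
        )
    vx, vy = data["variance"]
    cx, cy = data["pcs"]
    ax.set_xlabel(f"{cx} ({vx * 100:.1f}% of variance)")
    ax.set_ylabel(f"{cy} ({vy * 100:.1f}% of variance)")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
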