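"""Image loading, rectangular ROI cropping, batch extraction and CSV I/O.

The on-disk interchange format is a flat CSV with one row per analyzed ROI.
Column order is fixed::

    image_id, x0, y0, x1, y1, plane, side, mineralization, nodule,
    lesion_label, entropy, asm, energy, contrast, dissimilarity,
    homogeneity, correlation[, extra metadata columns...]

Coordinates are 0-based and half-open, with x = column and y = row, so the
ROI covers pixels ``[y0, y1) x [x0, x1)``.  Feature values round-trip
through the CSV at full double precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .glcm_features import (
    FEATURE_NAMES,
    FeatureVector,
    GlcmParams,
    compute_features,
    compute_glcm,
    quantize_image,
)

__all__ = [
    "RoiSpec",
    "FeatureRecord",
    "FeatureTable",
    "CSV_COLUMNS",
    "ROI_COLUMNS",
    "LESION_LABELS",
    "load_grayscale_image",
    "crop_roi",
    "extract_record",
    "extract_batch",
    "read_roi_csv",
    "write_feature_csv",
    "read_feature_csv",
]

LESION_LABELS = ("normal", "microlith", "other")

ROI_COLUMNS = [
    "image_id",
    "x0",
    "y0",
    "x1",
    "y1",
    "plane",
    "side",
    "mineralization",
    "nodule",
    "lesion_label",
]

CSV_COLUMNS = ROI_COLUMNS + list(FEATURE_NAMES)


@dataclass(frozen=True)
class RoiSpec:
    """A rectangular region of interest inside a named image."""

    image_id: str
    x0: int
    y0: int
    x1: int
    y1: int
    plane: str | None = None  # sagittal | transverse
    side: str | None = None  # left | right

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ValueError(
                f"invalid ROI rectangle [{self.x0},{self.x1})x[{self.y0},{self.y1})"
                f" for image {self.image_id!r}"
            )

    @property
    def key(self) -> tuple:
        return (self.image_id, self.x0, self.y0, self.x1, self.y1)


@dataclass(frozen=True)
class FeatureRecord:
    """One ROI's texture features plus its lesion annotations."""

    image_id: str
    roi: RoiSpec
    features: FeatureVector
    mineralization: bool = False
    nodule: bool = False
    lesion_label: str = "normal"
    metadata: dict | None = None

    def __post_init__(self) -> None:
        if self.lesion_label not in LESION_LABELS:
            raise ValueError(
                f"lesion_label must be one of {LESION_LABELS}, got {self.lesion_label!r}"
            )
        if self.lesion_label == "microlith" and not self.mineralization:
            raise ValueError("lesion_label 'microlith' requires mineralization=True")
        if self.lesion_label == "other" and not self.nodule:
            raise ValueError("lesion_label 'other' requires nodule=True")


class FeatureTable:
    """Ordered collection of :class:`FeatureRecord` backed by a DataFrame.

    Equality, CSV round-tripping and PCA all operate on the DataFrame view;
    ``records()`` reconstructs the dataclass view on demand.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        dup = df.duplicated(subset=["image_id", "x0", "y0", "x1", "y1"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValueError(
                f"duplicate (image_id, roi) key at row {row}: "
                f"{df.iloc[row][['image_id', 'x0', 'y0', 'x1', 'y1']].to_dict()}"
            )
        extra = [c for c in df.columns if c not in CSV_COLUMNS]
        self.df = df[CSV_COLUMNS + extra].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[FeatureRecord]) -> "FeatureTable":
        if not records:
            raise ValueError("feature table must contain at least one record")
        rows = []
        for rec in records:
            row = {
                "image_id": rec.image_id,
                "x0": rec.roi.x0,
                "y0": rec.roi.y0,
                "x1": rec.roi.x1,
                "y1": rec.roi.y1,
                "plane": rec.roi.plane,
                "side": rec.roi.side,
                "mineralization": bool(rec.mineralization),
                "nodule": bool(rec.nodule),
                "lesion_label": rec.lesion_label,
            }
            row.update(rec.features.as_dict())
            if rec.metadata:
                row.update(rec.metadata)
            rows.append(row)
        return cls(pd.DataFrame(rows))

    def records(self) -> list[FeatureRecord]:
        out = []
        extra = [c for c in self.df.columns if c not in CSV_COLUMNS]
        for _, row in self.df.iterrows():
            roi = RoiSpec(
                image_id=row["image_id"],
                x0=int(row["x0"]),
                y0=int(row["y0"]),
                x1=int(row["x1"]),
                y1=int(row["y1"]),
                plane=None if pd.isna(row["plane"]) else row["plane"],
                side=None if pd.isna(row["side"]) else row["side"],
            )
            fv = FeatureVector(**{n: float(row[n]) for n in FEATURE_NAMES})
            out.append(
                FeatureRecord(
                    image_id=row["image_id"],
                    roi=roi,
                    features=fv,
                    mineralization=bool(row["mineralization"]),
                    nodule=bool(row["nodule"]),
                    lesion_label=row["lesion_label"],
                    metadata={c: row[c] for c in extra} or None,
                )
            )
        return out

    def feature_matrix(self) -> np.ndarray:
        return self.df[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return FEATURE_NAMES

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.df, other.df, check_dtype=False)
        except AssertionError:
            return False
        return True


def load_grayscale_image(path, levels: int = 256) -> np.ndarray:
    """Load a PNG/TIFF image as a 2-D integer gray-level array.

    8-bit grayscale images pass through unchanged.  RGB(A) images with
    identical channels collapse to one channel; true-color images are
    converted with the Rec. 601 luminance (0.299 R + 0.587 G + 0.114 B)
    and then quantized.  16-bit images are linearly rescaled onto
    ``[0, levels - 1]``.  Other sample types raise rather than silently
    truncate.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise ValueError(f"could not read image file {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(
                f"unsupported channel count {arr.shape[2]} in {path}"
            )
        r, g, b = arr[:, :, 0], arr[:, :, 1], arr[:, :, 2]
        if np.array_equal(r, g) and np.array_equal(r, b):
            arr = r
        else:
            arr = 0.299 * r.astype(np.float64) + 0.587 * g + 0.114 * b
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    if arr.dtype.kind == "u" and arr.dtype.itemsize <= 2:
        return quantize_image(arr, levels=levels)
    if arr.dtype.kind == "f":
        return quantize_image(arr, levels=levels)
    raise ValueError(
        f"unsupported bit depth/dtype {arr.dtype} in {path}; expected 8- or 16-bit"
    )


def load_dicom_image(path, levels: int = 256) -> np.ndarray:
    """Optional single-frame monochrome DICOM reader (requires pydicom)."""
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError("DICOM support requires the 'pydicom' extra") from exc
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ValueError(f"only single-frame monochrome DICOM is supported: {path}")
    return quantize_image(arr, levels=levels)


def crop_roi(image: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Extract the rectangle ``[y0, y1) x [x0, x1)`` from ``image``."""
    img = np.asarray(image)
    h, w = img.shape
    if roi.x1 > w or roi.y1 > h:
        raise ValueError(
            f"ROI [{roi.x0},{roi.x1})x[{roi.y0},{roi.y1}) exceeds "
            f"image bounds {w}x{h} for {roi.image_id!r}"
        )
    return img[roi.y0 : roi.y1, roi.x0 : roi.x1]


def extract_record(
    image: np.ndarray,
    roi: RoiSpec,
    params: GlcmParams | None = None,
    *,
    mineralization: bool = False,
    nodule: bool = False,
    lesion_label: str = "normal",
    metadata: dict | None = None,
) -> FeatureRecord:
    """Crop, compute the GLCM and features, and package one record."""
    params = params or GlcmParams()
    crop = crop_roi(image, roi)
    try:
        glcm = compute_glcm(crop, params)
    except ValueError as exc:
        raise ValueError(f"ROI {roi.key}: {exc}") from exc
    return FeatureRecord(
        image_id=roi.image_id,
        roi=roi,
        features=compute_features(glcm),
        mineralization=mineralization,
        nodule=nodule,
        lesion_label=lesion_label,
        metadata=metadata,
    )


def read_roi_csv(path) -> pd.DataFrame:
    """Read a ROI/label table (the CSV schema minus the feature columns)."""
    df = pd.read_csv(path)
    missing = [c for c in ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ROI table {path} is missing columns: {missing}")
    return df


def extract_batch(
    image_dir,
    rois: pd.DataFrame,
    params: GlcmParams | None = None,
    levels: int = 256,
) -> FeatureTable:
    """Run feature extraction for every row of a ROI table.

    Each record depends only on its own row, so row order is preserved and
    results are independent of processing order.  Any columns beyond the
    ROI schema are carried through as metadata.
    """
    params = params or GlcmParams(levels=levels)
    image_dir = Path(image_dir)
    extra_cols = [c for c in rois.columns if c not in ROI_COLUMNS]
    records = []
    cache: dict[str, np.ndarray] = {}
    for _, row in rois.iterrows():
        image_id = str(row["image_id"])
        if image_id not in cache:
            cache[image_id] = load_grayscale_image(image_dir / image_id, levels=params.levels)
        roi = RoiSpec(
            image_id=image_id,
            x0=int(row["x0"]),
            y0=int(row["y0"]),
            x1=int(row["x1"]),
            y1=int(row["y1"]),
            plane=None if pd.isna(row["plane"]) else str(row["plane"]),
            side=None if pd.isna(row["side"]) else str(row["side"]),
        )
        records.append(
            extract_record(
                cache[image_id],
                roi,
                params,
                mineralization=bool(row["mineralization"]),
                nodule=bool(row["nodule"]),
                lesion_label=str(row["lesion_label"]),
                metadata={c: row[c] for c in extra_cols} or None,
            )
        )
    return FeatureTable.from_records(records)


def write_feature_csv(table: FeatureTable, path) -> None:
    """Write a feature table; floats keep full round-trip precision."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    table.df.to_csv(path, index=False, float_format="%.17g")


def read_feature_csv(path) -> FeatureTable:
    """Read a feature table CSV, validating schema and key uniqueness."""
    # round_trip parsing so written doubles come back bit-identical
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV {path} is missing columns: {missing}")
    bad = ~df["lesion_label"].isin(LESION_LABELS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown lesion_label {df.iloc[row]['lesion_label']!r} at row {row}"
        )
    return FeatureTable(df)
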