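"""Seeded synthetic ultrasound-like phantoms with ground-truth labels.

B-mode speckle is emulated as a Rayleigh-distributed envelope, spatially
smoothed to set the speckle correlation length and rescaled so the
parenchyma sits at a target mean gray level.  Log compression and
beam/attenuation physics are deliberately omitted: the phantoms are texture
stand-ins, not acoustic simulations.  On that background three lesion
archetypes can be painted, each echoing a pattern seen in clinical
testicular ultrasound:

* **microliths** — pinpoint-to-small, well-defined hyperechoic foci
  (bright disks of radius 1-3 px, no acoustic shadow),
* **septated cysts** — a near-anechoic ellipse crossed by thin bright
  septa,
* **heterogeneous parenchyma** — a smooth multiplicative gain field that
  modulates the speckle on a coarse patch scale.

Every generator is a pure function of its parameters and seed, so cohorts
regenerate byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, ellipse, line

from .roi_io import ROI_COLUMNS

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "rayleigh_envelope",
    "make_speckle",
    "insert_microliths",
    "insert_cyst",
    "make_heterogeneous",
    "make_phantom",
    "make_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic texture patch.

    shape : (height, width) in pixels
    speckle_mean : target mean gray level of the parenchyma (8-bit units)
    speckle_scale : Rayleigh scale sigma of the raw envelope (arbitrary
        units; only the shape of the distribution matters after rescaling)
    smoothing_radius : Gaussian sigma in pixels setting the speckle
        correlation length (0 disables smoothing)
    lesion : one of None, "microliths", "cyst", "heterogeneous"
    lesion_params : keyword arguments for the matching insert function
    seed : RNG seed; identical spec + seed gives an identical image
    """

    shape: tuple[int, int] = (128, 128)
    speckle_mean: float = 120.0
    speckle_scale: float = 1.0
    smoothing_radius: float = 1.5
    lesion: str | None = None
    lesion_params: dict = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class CohortSpec:
    """A labeled cohort of phantoms: group sizes plus per-group templates.

    Default sizes follow a realistic screening mix in which most fields of
    view are normal parenchyma and a small minority carry lesions.
    """

    n_normal: int = 245
    n_microlith: int = 16
    n_other: int = 19
    shape: tuple[int, int] = (128, 128)
    speckle_mean: float = 120.0
    speckle_scale: float = 1.0
    smoothing_radius: float = 1.5
    seed: int = 0

    @property
    def total(self) -> int:
        return self.n_normal + self.n_microlith + self.n_other


def rayleigh_envelope(
    shape: tuple[int, int], scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Raw per-pixel Rayleigh envelope (mean = scale * sqrt(pi/2))."""
    if scale <= 0:
        raise ValueError(f"speckle_scale must be positive, got {scale}")
    if shape[0] < 1 or shape[1] < 1:
        raise ValueError(f"invalid phantom shape {shape}")
    return rng.rayleigh(scale=scale, size=shape)


def make_speckle(spec: PhantomSpec) -> np.ndarray:
    """Generate homogeneous speckle as an 8-bit gray-level image."""
    rng = np.random.default_rng(spec.seed)
    env = rayleigh_envelope(spec.shape, spec.speckle_scale, rng)
    if spec.smoothing_radius > 0:
        env = gaussian_filter(env, sigma=spec.smoothing_radius)
    img = env * (spec.speckle_mean / env.mean())
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def insert_microliths(
    image: np.ndarray,
    count: int,
    radius_px: tuple[int, int] = (1, 3),
    intensity_gain: float = 120.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Paint ``count`` non-overlapping hyperechoic foci; return their centers.

    Foci are bright disks clipped at 255; no acoustic shadow is drawn.
    Raises if the requested number of non-overlapping foci cannot be placed.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    rng = np.random.default_rng(seed)
    img = np.asarray(image).astype(np.int64)
    h, w = img.shape
    rmax = int(max(radius_px))
    margin = rmax + 1
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError(f"image {h}x{w} too small for foci of radius {rmax}")
    centers: list[tuple[int, int]] = []
    radii: list[int] = []
    attempts = 0
    while len(centers) < count:
        attempts += 1
        if attempts > 1000 * count:
            raise ValueError(
                f"could not place {count} non-overlapping foci in {h}x{w};"
                " try fewer foci or a larger image"
            )
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        rad = int(rng.integers(radius_px[0], radius_px[1] + 1))
        if all(
            (r - rr) ** 2 + (c - cc) ** 2 > (rad + prad + 1) ** 2
            for (rr, cc), prad in zip(centers, radii)
        ):
            centers.append((r, c))
            radii.append(rad)
    out = img.copy()
    for (r, c), rad in zip(centers, radii):
        rr, cc = disk((r, c), rad + 0.5, shape=img.shape)
        out[rr, cc] = out[rr, cc] + int(round(intensity_gain))
    return np.clip(out, 0, 255).astype(np.uint8), centers


def insert_cyst(
    image: np.ndarray,
    center: tuple[int, int],
    axes: tuple[float, float],
    septa_count: int = 2,
    septa_intensity: float = 220.0,
    seed: int = 0,
) -> np.ndarray:
    """Paint a near-anechoic ellipse crossed by thin bright septa."""
    img = np.asarray(image).astype(np.int64)
    h, w = img.shape
    r0, c0 = center
    ar, ac = axes
    if r0 - ar < 0 or r0 + ar >= h or c0 - ac < 0 or c0 + ac >= w:
        raise ValueError(
            f"cyst ellipse center={center} axes={axes} exceeds image bounds {h}x{w}"
        )
    rng = np.random.default_rng(seed)
    out = img.copy()
    rr, cc = ellipse(r0, c0, ar, ac, shape=img.shape)
    # near-anechoic interior: strong attenuation of the local speckle
    out[rr, cc] = np.round(out[rr, cc] * 0.12).astype(np.int64)
    mask = np.zeros(img.shape, dtype=bool)
    mask[rr, cc] = True
    for _ in range(septa_count):
        theta = rng.uniform(0, np.pi)
        dr, dc = np.sin(theta), np.cos(theta)
        p0 = (int(round(r0 - dr * ar)), int(round(c0 - dc * ac)))
        p1 = (int(round(r0 + dr * ar)), int(round(c0 + dc * ac)))
        lr, lc = line(*p0, *p1)
        inside = mask[np.clip(lr, 0, h - 1), np.clip(lc, 0, w - 1)]
        out[lr[inside], lc[inside]] = int(round(septa_intensity))
    return np.clip(out, 0, 255).astype(np.uint8)


def make_heterogeneous(
    image: np.ndarray,
    patch_scale: float = 12.0,
    gain_range: tuple[float, float] = (0.55, 1.45),
    seed: int = 0,
) -> np.ndarray:
    """Modulate speckle with a smooth random gain field (coarse patches)."""
    if patch_scale <= 0:
        raise ValueError(f"patch_scale must be positive, got {patch_scale}")
    rng = np.random.default_rng(seed)
    img = np.asarray(image).astype(np.float64)
    g = gaussian_filter(rng.standard_normal(img.shape), sigma=patch_scale)
    lo, hi = g.min(), g.max()
    gain = gain_range[0] + (g - lo) / (hi - lo) * (gain_range[1] - gain_range[0])
    return np.clip(np.round(img * gain), 0, 255).astype(np.uint8)


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, dict]:
    """Generate one phantom; returns (image, ground-truth metadata)."""
    img = make_speckle(spec)
    meta: dict = {"lesion": spec.lesion}
    if spec.lesion is None:
        return img, meta
    lesion_seed = spec.seed + 1_000_003  # decouple lesion RNG from speckle
    if spec.lesion == "microliths":
        kw = {"count": 12, "radius_px": (1, 3), "intensity_gain": 120.0}
        kw.update(spec.lesion_params)
        img, centers = insert_microliths(img, seed=lesion_seed, **kw)
        meta["foci"] = centers
    elif spec.lesion == "cyst":
        h, w = spec.shape
        kw = {
            "center": (h // 2, w // 2),
            "axes": (h / 5, w / 4),
            "septa_count": 2,
            "septa_intensity": 220.0,
        }
        kw.update(spec.lesion_params)
        img = insert_cyst(img, seed=lesion_seed, **kw)
        meta.update(center=kw["center"], axes=kw["axes"])
    elif spec.lesion == "heterogeneous":
        kw = {"patch_scale": 12.0, "gain_range": (0.55, 1.45)}
        kw.update(spec.lesion_params)
        img = make_heterogeneous(img, seed=lesion_seed, **kw)
    else:
        raise ValueError(f"unknown lesion type {spec.lesion!r}")
    return img, meta


def _cohort_rows(spec: CohortSpec):
    """Yield (index, lesion_label, PhantomSpec) for every cohort member."""
    master = np.random.default_rng(spec.seed)
    idx = 0
    for label, n in (
        ("normal", spec.n_normal),
        ("microlith", spec.n_microlith),
        ("other", spec.n_other),
    ):
        for j in range(n):
            img_seed = int(master.integers(2**31))
            # mild per-image variation: realistic cohorts are not clones
            mean = float(master.uniform(0.92, 1.08)) * spec.speckle_mean
            smooth = float(master.uniform(0.85, 1.15)) * spec.smoothing_radius
            if label == "normal":
                lesion, lp = None, {}
            elif label == "microlith":
                lesion = "microliths"
                lp = {"count": int(master.integers(5, 21))}
            else:  # alternate the two "other" archetypes deterministically
                if j % 2 == 0:
                    lesion = "cyst"
                    h, w = spec.shape
                    lp = {
                        "center": (
                            int(master.integers(h // 3, 2 * h // 3)),
                            int(master.integers(w // 3, 2 * w // 3)),
                        ),
                        "axes": (
                            float(master.uniform(h / 8, h / 5)),
                            float(master.uniform(w / 8, w / 4)),
                        ),
                        "septa_count": int(master.integers(0, 4)),
                    }
                else:
                    lesion = "heterogeneous"
                    lp = {"patch_scale": float(master.uniform(8, 16))}
            yield idx, label, PhantomSpec(
                shape=spec.shape,
                speckle_mean=mean,
                speckle_scale=spec.speckle_scale,
                smoothing_radius=smooth,
                lesion=lesion,
                lesion_params=lp,
                seed=img_seed,
            )
            idx += 1


def make_cohort(
    spec: CohortSpec, out_dir=None
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Generate the full cohort; optionally write PNGs plus a ROI table.

    Returns the images and a ROI/label DataFrame covering each full image
    as one ROI (columns: image_id, x0, y0, x1, y1, plane, side,
    mineralization, nodule, lesion_label).  With ``out_dir`` the images are
    written as ``phantom_0000.png`` ... and the table as ``rois.csv``;
    reruns with the same spec are byte-identical.
    """
    images: list[np.ndarray] = []
    rows: list[dict] = []
    h, w = spec.shape
    for idx, label, pspec in _cohort_rows(spec):
        img, _ = make_phantom(pspec)
        images.append(img)
        rows.append(
            {
                "image_id": f"phantom_{idx:04d}.png",
                "x0": 0,
                "y0": 0,
                "x1": w,
                "y1": h,
                "plane": "sagittal" if idx % 2 == 0 else "transverse",
                "side": "left" if (idx // 2) % 2 == 0 else "right",
                "mineralization": label == "microlith",
                "nodule": label == "other",
                "lesion_label": label,
            }
        )
    rois = pd.DataFrame(rows, columns=ROI_COLUMNS)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for row, img in zip(rows, images):
            iio.imwrite(out / row["image_id"], img)
        rois.to_csv(out / "rois.csv", index=False)
    return images, rois
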