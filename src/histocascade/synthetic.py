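"""Synthetic H&E-like whole-slide images with known tumor masks.

The generator emulates the structure the pipeline cares about rather than
photorealistic histology: a near-white background, one or more smooth
tissue blobs with pink (eosin-like) stroma, purple (hematoxylin-like)
nuclear speckles, occasional low-saturation fat vacuoles, and a contiguous
tumor sub-region with denser nuclear speckling.  Tissue and tumor area
fractions are drawn from configured ranges and enforced by quantile
thresholding of smooth random fields, so the ground-truth mask is exact by
construction.  Everything is a pure function of the spec's seed.

Each synthetic slide is written as a tiled pyramidal TIFF through
:mod:`histocascade.wsi_io`; the ground-truth annotation is exported as a
single-channel pyramid at a configurable downsample factor (default 4)
using per-block majority voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, zoom as nd_zoom

from .errors import GenerationError
from .wsi_io import PyramidImage, open_pyramid, write_pyramid

__all__ = [
    "CohortSpec",
    "SyntheticWsi",
    "render_wsi",
    "generate_wsi",
    "generate_cohort",
    "export_annotation",
]

GRADES = ("I", "II", "III")

# H&E-ish base colors (uint8 RGB)
_BACKGROUND = np.array([245.0, 243.0, 244.0])
_STROMA = np.array([214.0, 137.0, 168.0])   # eosin pink
_NUCLEI = np.array([104.0, 58.0, 140.0])    # hematoxylin purple
_FAT = np.array([238.0, 233.0, 235.0])      # low-saturation vacuole

# nuclear speckle density inside/outside tumor, by grade (higher grade =
# denser, more pleomorphic-looking speckling)
_TUMOR_DENSITY = {"I": 0.22, "II": 0.28, "III": 0.34}
_STROMA_DENSITY = 0.07


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_wsi: int = 16
    grade_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    base_size_px: tuple[int, int] = (2048, 2048)  # (width, height)
    base_magnification: float = 100.0
    tissue_fraction_range: tuple[float, float] = (0.30, 0.55)
    tumor_of_tissue_range: tuple[float, float] = (0.25, 0.55)
    color_jitter: float = 0.04
    seed: int = 0
    n_levels: int = 4
    tile_size: int = 256

    def validate(self) -> None:
        if self.n_wsi < 1:
            raise ValueError("n_wsi must be >= 1")
        lo, hi = self.tissue_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("tissue_fraction_range must be ordered in (0, 1]")
        lo, hi = self.tumor_of_tissue_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("tumor_of_tissue_range must be ordered in [0, 1]")
        if abs(sum(self.grade_weights) - 1.0) > 1e-9 or min(self.grade_weights) < 0:
            raise ValueError("grade_weights must be nonnegative and sum to 1")


@dataclass
class SyntheticWsi:
    pyramid: PyramidImage
    tumor_mask_level0: np.ndarray
    grade: str
    provenance: dict = field(default_factory=dict)


def _smooth_field(rng: np.random.Generator, shape_hw: tuple[int, int],
                  coarse: int = 8, sigma: float = 3.0) -> np.ndarray:
    """Smooth random field at full resolution via coarse noise + blur + zoom."""
    h, w = shape_hw
    ch, cw = max(4, h // (coarse * 8)), max(4, w // (coarse * 8))
    noise = gaussian_filter(rng.standard_normal((ch, cw)), sigma)
    field = nd_zoom(noise, (h / ch, w / cw), order=1)
    return field[:h, :w]


def _blob_mask(field: np.ndarray, fraction: float) -> np.ndarray:
    """Threshold a continuous field at the quantile giving `fraction` area."""
    thr = np.quantile(field, 1.0 - fraction)
    return field > thr


def render_wsi(spec: CohortSpec, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray, str]:
    """Render one slide; returns (RGB uint8 level-0 image, tumor mask, grade)."""
    spec.validate()
    w, h = spec.base_size_px
    grade = rng.choice(GRADES, p=np.asarray(spec.grade_weights, dtype=float))
    grade = str(grade)

    t_lo, t_hi = spec.tissue_fraction_range
    tissue_target = rng.uniform(t_lo, t_hi)
    tissue_field = _smooth_field(rng, (h, w))
    tissue = _blob_mask(tissue_field, tissue_target)

    m_lo, m_hi = spec.tumor_of_tissue_range
    tumor_target = rng.uniform(m_lo, m_hi)
    tumor = None
    ys, xs = np.nonzero(tissue)
    yy = np.arange(h, dtype=np.float32)[:, None]
    xx = np.arange(w, dtype=np.float32)[None, :]
    for _ in range(100):
        # a single bump centred inside the tissue plus smooth noise keeps the
        # tumor contiguous in practice
        ci = rng.integers(len(ys))
        cy, cx = ys[ci], xs[ci]
        r2 = ((yy - cy) / (0.35 * h)) ** 2 + ((xx - cx) / (0.35 * w)) ** 2
        bump = np.exp(-r2) + 0.35 * _smooth_field(rng, (h, w)).astype(np.float32)
        vals = bump[tissue]
        thr = np.quantile(vals, 1.0 - tumor_target)
        cand = tissue & (bump > thr)
        frac = cand.sum() / max(1, tissue.sum())
        if m_lo - 1e-9 <= frac <= m_hi + 1e-9 and (tumor_target == 0 or cand.any()):
            tumor = cand
            break
    if tumor is None:
        raise GenerationError(
            "could not realise tumor_of_tissue_range after 100 attempts"
        )

    jit = spec.color_jitter * 255.0
    shift = rng.uniform(-jit, jit, size=3)

    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = (_BACKGROUND + rng.uniform(-2, 2, size=3)).astype(np.float32)

    stroma_col = np.clip(_STROMA + shift, 0, 255).astype(np.float32)
    nuclei_col = np.clip(_NUCLEI + shift, 0, 255).astype(np.float32)
    # mild pink texture inside tissue
    tex = _smooth_field(rng, (h, w), coarse=2, sigma=1.5).astype(np.float32)
    tex = (tex - tex.mean()) * 10.0
    img[tissue] = stroma_col + tex[tissue, None]

    # fat vacuoles: small low-saturation patches, kept rare (<~3% of tissue)
    fat_field = _smooth_field(rng, (h, w), coarse=1, sigma=1.0)
    fat = tissue & (fat_field > np.quantile(fat_field, 0.985))
    img[fat] = _FAT.astype(np.float32)

    # nuclear speckles: per-pixel noise thresholded by local density
    u = rng.random((h, w), dtype=np.float32)
    density = np.where(tumor.astype(bool), np.float32(_TUMOR_DENSITY[grade]),
                       np.float32(_STROMA_DENSITY))
    speckle = tissue & ~fat & (u < density)
    img[speckle] = nuclei_col + rng.uniform(
        -8, 8, size=(int(speckle.sum()), 3)
    ).astype(np.float32)

    img += 2.0 * rng.standard_normal(img.shape, dtype=np.float32)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return img, tumor.astype(np.uint8), grade


def generate_wsi(spec: CohortSpec, rng: np.random.Generator, path) -> SyntheticWsi:
    """Render a slide, write it as a pyramidal TIFF, and open it."""
    img, mask, grade = render_wsi(spec, rng)
    write_pyramid(img, spec.tile_size, spec.n_levels, path,
                  base_magnification=spec.base_magnification)
    return SyntheticWsi(
        pyramid=open_pyramid(path),
        tumor_mask_level0=mask,
        grade=grade,
        provenance={"seed": spec.seed, "spec": spec},
    )


def export_annotation(mask_level0: np.ndarray, factor: int, path,
                      n_levels: int = 3, tile_size: int = 256,
                      base_magnification: float | None = None) -> np.ndarray:
    """Write a mask downsampled by `factor` as a 1-channel pyramidal TIFF.

    Downsampling uses per-block majority voting (ties count as foreground),
    which approximately conserves area for smooth blob masks.  Returns the
    downsampled grid that was written.
    """
    uniq = np.unique(mask_level0)
    if not np.all(np.isin(uniq, (0, 1))):
        raise TypeError("annotation mask must be binary {0,1}")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    mask = mask_level0.astype(np.uint8)
    if factor == 1:
        grid = mask.copy()
    else:
        h, w = mask.shape
        ih = np.arange(0, h, factor)
        iw = np.arange(0, w, factor)
        sums = np.add.reduceat(mask.astype(np.int64), ih, axis=0)
        sums = np.add.reduceat(sums, iw, axis=1)
        ch = np.minimum(ih + factor, h) - ih
        cw = np.minimum(iw + factor, w) - iw
        counts = np.outer(ch, cw)
        grid = (2 * sums >= counts).astype(np.uint8)
    write_pyramid(grid, tile_size, n_levels, path,
                  base_magnification=base_magnification)
    return grid


def generate_cohort(spec: CohortSpec, out_dir,
                    annotation_factor: int = 4,
                    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                    ) -> tuple[list[SyntheticWsi], pd.DataFrame]:
    """Generate a cohort of slides with annotations and a manifest.

    The manifest (``manifest.csv``) has columns ``wsi_path``,
    ``annotation_path``, ``grade``, ``split``; rows match the files written.
    Splits are assigned by a seeded shuffle at the given fractions.
    """
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(spec.seed)
    rows = []
    wsis = []
    for i in range(spec.n_wsi):
        rng = np.random.default_rng(master.integers(2**31))
        wsi_path = out / f"wsi_{i:03d}.tiff"
        anno_path = out / f"anno_{i:03d}.tiff"
        sw = generate_wsi(spec, rng, wsi_path)
        export_annotation(
            sw.tumor_mask_level0, annotation_factor, anno_path,
            base_magnification=spec.base_magnification / annotation_factor,
        )
        wsis.append(sw)
        rows.append({"wsi_path": str(wsi_path), "annotation_path": str(anno_path),
                     "grade": sw.grade})
    n = spec.n_wsi
    n_train = int(round(split_fractions[0] * n))
    n_val = int(round(split_fractions[1] * n))
    order = master.permutation(n)
    split = np.empty(n, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train:n_train + n_val]] = "val"
    split[order[n_train + n_val:]] = "test"
    manifest = pd.DataFrame(rows)
    manifest["split"] = split
    manifest.to_csv(out / "manifest.csv", index=False)
    return wsis, manifest
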