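"""Cascade inference: heatmap stitching, refinement, and baselines.

Stage one tiles the detected tissue into non-overlapping 256 px patches at
x100 magnification, classifies each patch once, and stitches the tumor
softmax probabilities into a coarse heatmap (one value per grid cell;
cells that are not tissue stay at probability 0).  Stage two concatenates
the bilinearly resized low-resolution image and heatmap into a 4-channel
input for the refinement network, whose tumor softmax channel is the final
probability map, thresholded at 0.5 (ties count as tumor).

The Otsu baseline segments *all* tissue (saturation channel thresholded by
Otsu's method on the low-resolution plane); any tumor-specific method
should beat its precision-limited Dice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.transform import resize as _sk_resize

from .errors import ModelError
from .models import PatchClassifier, Refiner
from .preprocess import (
    BinaryMask,
    detect_tissue,
    index_patches,
    saturation_8bit,
)
from .wsi_io import PyramidImage, read_patch_at_magnification

__all__ = [
    "Heatmap",
    "SegmentationResult",
    "predict_heatmap",
    "threshold_heatmap",
    "refine_segmentation",
    "otsu_baseline",
    "run_cascade",
]


@dataclass
class Heatmap:
    """Patch-grid tumor probabilities; cell (r, c) covers the level-0 square
    ``[c*cell, (c+1)*cell) x [r*cell, (r+1)*cell)``."""

    grid: np.ndarray            # n_rows x n_cols float32 in [0, 1]
    cell_size_level0: float
    level0_width: int
    level0_height: int


@dataclass
class SegmentationResult:
    prob: np.ndarray     # S x S float32 in [0, 1]
    binary: np.ndarray   # S x S uint8
    geometry: dict       # {"level0_width": ..., "level0_height": ...}
    method_tag: str


def predict_heatmap(
    pyr: PyramidImage,
    classifier: PatchClassifier,
    tissue: BinaryMask,
    batch_size: int = 32,
) -> Heatmap:
    """Classify every accepted tissue patch once and stitch the tumor
    probabilities into the patch grid.  Output is independent of batch
    size and patch order (inference mode, no dropout/batch statistics)."""
    spec = classifier.spec
    table = index_patches(
        pyr, tissue, annotation=None,
        patch_size=spec.patch_size,
        patch_magnification=spec.patch_magnification,
    )
    delta = spec.patch_size * pyr.base_magnification / spec.patch_magnification
    n_cols = int(pyr.width // delta)
    n_rows = int(pyr.height // delta)
    grid = np.zeros((n_rows, n_cols), dtype=np.float32)
    recs = table.records
    for start in range(0, len(recs), batch_size):
        chunk = recs[start:start + batch_size]
        imgs = np.stack([
            read_patch_at_magnification(
                pyr, r.x0, r.y0, spec.patch_size, spec.patch_magnification
            )
            for r in chunk
        ]).astype(np.float32) / np.float32(255.0)
        probs = classifier.predict_proba(imgs)
        for rec, p in zip(chunk, probs):
            grid[int(round(rec.y0 / delta)), int(round(rec.x0 / delta))] = p[1]
    return Heatmap(
        grid=grid,
        cell_size_level0=delta,
        level0_width=pyr.width,
        level0_height=pyr.height,
    )


def _nearest_cell_upsample(hm: Heatmap, out_shape: tuple[int, int]) -> np.ndarray:
    """Sample the cell grid at output-pixel centers (nearest neighbour)."""
    oh, ow = out_shape
    ys = np.floor(((np.arange(oh) + 0.5) * hm.level0_height / oh)
                  / hm.cell_size_level0).astype(int)
    xs = np.floor(((np.arange(ow) + 0.5) * hm.level0_width / ow)
                  / hm.cell_size_level0).astype(int)
    padded = np.zeros((hm.grid.shape[0] + 1, hm.grid.shape[1] + 1),
                      dtype=np.float32)
    padded[:hm.grid.shape[0], :hm.grid.shape[1]] = hm.grid
    ys = np.clip(ys, 0, padded.shape[0] - 1)
    xs = np.clip(xs, 0, padded.shape[1] - 1)
    return padded[np.ix_(ys, xs)]


def threshold_heatmap(hm: Heatmap, t: float = 0.5,
                      out_size: int = 1024) -> SegmentationResult:
    """Nearest-neighbour upsample of the heatmap grid, binarized at ``t``."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold {t} outside [0, 1]")
    prob = _nearest_cell_upsample(hm, (out_size, out_size))
    binary = (prob >= t).astype(np.uint8)
    return SegmentationResult(
        prob=prob,
        binary=binary,
        geometry={"level0_width": hm.level0_width,
                  "level0_height": hm.level0_height},
        method_tag="patchwise_threshold",
    )


def _lowres_plane(pyr: PyramidImage, input_size: int) -> np.ndarray:
    """Smallest stored plane with both dims >= input_size (level 0 if none)."""
    best = 0
    for i, lv in enumerate(pyr.levels):
        if lv.width >= input_size and lv.height >= input_size:
            best = i
    return pyr._level_array(best)


def _bilinear(arr: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    if arr.shape[:2] == out_shape:
        return arr.astype(np.float32, copy=True)
    return _sk_resize(arr.astype(np.float64), out_shape + arr.shape[2:],
                      order=1, anti_aliasing=False, preserve_range=True,
                      mode="edge").astype(np.float32)


def refiner_input(pyr: PyramidImage, hm: Heatmap, input_size: int
                  ) -> np.ndarray:
    """Build the 4-channel (R, G, B, heatmap) refiner input at `input_size`."""
    img = _lowres_plane(pyr, input_size).astype(np.float32) / np.float32(255.0)
    img = _bilinear(img, (input_size, input_size))
    # pad the cell grid to cover the full extent before resizing
    n_rows_full = int(np.ceil(hm.level0_height / hm.cell_size_level0))
    n_cols_full = int(np.ceil(hm.level0_width / hm.cell_size_level0))
    full = np.zeros((n_rows_full, n_cols_full), dtype=np.float32)
    full[:hm.grid.shape[0], :hm.grid.shape[1]] = hm.grid
    heat = _bilinear(full, (input_size, input_size))
    return np.concatenate([img, heat[..., None]], axis=-1)


def refine_segmentation(pyr: PyramidImage, hm: Heatmap, refiner: Refiner,
                        t: float = 0.5) -> SegmentationResult:
    """Run the refinement network on the (low-res image, heatmap) pair."""
    if not isinstance(refiner, Refiner):
        raise ModelError("refine_segmentation needs a trained Refiner")
    size = refiner.spec.input_size
    x = refiner_input(pyr, hm, size)[None]
    probs = refiner.forward_probs(x, train=False)
    prob = probs[0, :, :, 1].astype(np.float32)
    return SegmentationResult(
        prob=prob,
        binary=(prob >= t).astype(np.uint8),
        geometry={"level0_width": pyr.width, "level0_height": pyr.height},
        method_tag="refined_cascade",
    )


def otsu_baseline(pyr: PyramidImage, out_size: int = 1024) -> SegmentationResult:
    """Tissue segmentation baseline: Otsu threshold on the saturation image
    of the low-resolution plane (256-bin between-class-variance rule)."""
    img = _lowres_plane(pyr, out_size)
    img = _bilinear(img.astype(np.float64), (out_size, out_size))
    sat = np.clip(np.floor(saturation_8bit(img / 255.0) + 0.5),
                  0, 255).astype(np.uint8)
    if sat.min() == sat.max():
        binary = np.zeros_like(sat, dtype=np.uint8)
    else:
        t = threshold_otsu(sat, nbins=256)
        binary = (sat > t).astype(np.uint8)
    return SegmentationResult(
        prob=binary.astype(np.float32),
        binary=binary,
        geometry={"level0_width": pyr.width, "level0_height": pyr.height},
        method_tag="otsu",
    )


def run_cascade(pyr: PyramidImage, classifier: PatchClassifier,
                refiner: Refiner, save_intermediates: bool = False):
    """Full pipeline: tissue detection -> heatmap -> refinement.

    Returns the final :class:`SegmentationResult`; with
    ``save_intermediates`` returns ``(result, {"tissue": ..., "heatmap": ...})``.
    """
    tissue = detect_tissue(pyr)
    hm = predict_heatmap(pyr, classifier, tissue)
    result = refine_segmentation(pyr, hm, refiner)
    if save_intermediates:
        return result, {"tissue": tissue, "heatmap": hm}
    return result
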