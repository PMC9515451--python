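"""Tissue detection and construction of the labeled patch index.

Tissue is detected on the x1.25 magnification plane: the image is converted
to HSV, the saturation channel (8-bit scale, 0-255) is thresholded at
S > 20, and the result is closed morphologically with a 5x5 and then a 3x3
square kernel.  Stained tissue is saturated (pink/purple) while the glass
background is near-white, so a fixed saturation threshold separates them.

Patch indexing lays a non-overlapping grid of 256 px patches at x100
magnification over the slide, starting at the level-0 origin; partial edge
cells are discarded.  A cell is kept when more than 25% of its footprint is
tissue.  With an annotation, cells with more than 25% tumor are labeled
tumor, cells with exactly zero tumor are labeled non-tumor, and cells in
the (0, 25]% band are discarded as ambiguous.  Both 25% thresholds are
strict.  Fractions are computed on the coarse mask grids (tissue at the
x1.25 plane's downsample, annotation at its own downsample) restricted to
the patch footprint, each mask pixel weighted equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.morphology import closing, footprint_rectangle

from .errors import ChannelError, GeometryError
from .wsi_io import PyramidImage, plane_at_magnification

__all__ = [
    "BinaryMask",
    "PatchRecord",
    "PatchIndexTable",
    "detect_tissue",
    "index_patches",
    "saturation_8bit",
]

TISSUE_PLANE_MAG = 1.25
SATURATION_THRESHOLD = 20
PATCH_SIZE = 256
PATCH_MAGNIFICATION = 100.0
FRACTION_THRESHOLD = 0.25

LABEL_NON_TUMOR = 0
LABEL_TUMOR = 1


@dataclass
class BinaryMask:
    """A {0,1} grid aligned to level 0 at a given downsample, origin (0,0)."""

    grid: np.ndarray
    downsample: float


@dataclass(frozen=True)
class PatchRecord:
    wsi_id: str
    x0: int
    y0: int
    label: int | None
    tissue_fraction: float
    tumor_fraction: float | None
    cluster_id: int | None = None


@dataclass
class PatchIndexTable:
    records: list[PatchRecord]
    wsi_id: str
    grade: str | None = None
    patch_size: int = PATCH_SIZE
    patch_magnification: float = PATCH_MAGNIFICATION

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "x0": r.x0,
                    "y0": r.y0,
                    "label": r.label,
                    "tissue_fraction": r.tissue_fraction,
                    "tumor_fraction": r.tumor_fraction,
                }
                for r in self.records
            ]
        )


def saturation_8bit(rgb: np.ndarray) -> np.ndarray:
    """HSV saturation of an 8-bit RGB image on the 0-255 scale."""
    return rgb2hsv(rgb)[..., 1] * 255.0


def detect_tissue(pyr: PyramidImage) -> BinaryMask:
    """Segment tissue on the x1.25 plane by saturation threshold + closing."""
    if pyr.channels != 3:
        raise ChannelError("tissue detection requires an RGB pyramid")
    plane, downsample = plane_at_magnification(pyr, TISSUE_PLANE_MAG)
    sat = saturation_8bit(plane)
    mask = sat > SATURATION_THRESHOLD
    mask = closing(mask, footprint_rectangle((5, 5)))
    mask = closing(mask, footprint_rectangle((3, 3)))
    return BinaryMask(grid=mask.astype(np.uint8), downsample=downsample)


def _check_mask_geometry(pyr: PyramidImage, mask: BinaryMask, name: str) -> None:
    gh, gw = mask.grid.shape
    eh = round(pyr.height / mask.downsample)
    ew = round(pyr.width / mask.downsample)
    if abs(gh - eh) > 1 or abs(gw - ew) > 1:
        raise GeometryError(
            f"{name} mask grid {gh}x{gw} does not match level-0 "
            f"{pyr.height}x{pyr.width} at downsample {mask.downsample}"
        )


def _fraction_in_footprint(
    integral: np.ndarray, ds: float, x0: float, y0: float, delta: float
) -> float:
    """Mean mask value over a level-0 footprint, via the mask integral image.

    Footprint boundaries are mapped to the mask grid and rounded to the
    nearest pixel edge; each mask pixel inside counts equally.
    """
    gh, gw = integral.shape[0] - 1, integral.shape[1] - 1
    r0 = min(max(int(round(y0 / ds)), 0), gh)
    r1 = min(max(int(round((y0 + delta) / ds)), 0), gh)
    c0 = min(max(int(round(x0 / ds)), 0), gw)
    c1 = min(max(int(round((x0 + delta) / ds)), 0), gw)
    area = (r1 - r0) * (c1 - c0)
    if area <= 0:
        return 0.0
    s = (
        integral[r1, c1]
        - integral[r0, c1]
        - integral[r1, c0]
        + integral[r0, c0]
    )
    return float(s) / float(area)


def _integral(mask: np.ndarray) -> np.ndarray:
    out = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=out[1:, 1:])
    return out


def index_patches(
    pyr: PyramidImage,
    tissue: BinaryMask,
    annotation: BinaryMask | None = None,
    grade: str | None = None,
    wsi_id: str = "",
    patch_size: int = PATCH_SIZE,
    patch_magnification: float = PATCH_MAGNIFICATION,
) -> PatchIndexTable:
    """Build the accepted-patch index for one slide.

    Without an annotation the table is built in unlabeled (inference) mode:
    every cell passing the tissue rule is kept with ``label=None``.
    """
    _check_mask_geometry(pyr, tissue, "tissue")
    if annotation is not None:
        _check_mask_geometry(pyr, annotation, "annotation")

    delta = patch_size * pyr.base_magnification / patch_magnification
    n_cols = int(pyr.width // delta)
    n_rows = int(pyr.height // delta)

    tis_int = _integral(tissue.grid)
    ann_int = _integral(annotation.grid) if annotation is not None else None

    records: list[PatchRecord] = []
    for r in range(n_rows):
        for c in range(n_cols):
            x0 = c * delta
            y0 = r * delta
            tf = _fraction_in_footprint(tis_int, tissue.downsample, x0, y0, delta)
            if not tf > FRACTION_THRESHOLD:
                continue
            if annotation is None:
                label, mf = None, None
            else:
                mf = _fraction_in_footprint(
                    ann_int, annotation.downsample, x0, y0, delta
                )
                if mf > FRACTION_THRESHOLD:
                    label = LABEL_TUMOR
                elif mf == 0.0:
                    label = LABEL_NON_TUMOR
                else:
                    continue  # ambiguous (0, 25]% band is discarded
            records.append(
                PatchRecord(
                    wsi_id=wsi_id,
                    x0=int(round(x0)),
                    y0=int(round(y0)),
                    label=label,
                    tissue_fraction=tf,
                    tumor_fraction=mf,
                )
            )
    return PatchIndexTable(
        records=records,
        wsi_id=wsi_id,
        grade=grade,
        patch_size=patch_size,
        patch_magnification=patch_magnification,
    )
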