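"""Reading and writing multi-resolution tiled pyramidal images.

All coordinate conventions of the package live here: ``(x0, y0)`` are given
in the level-0 pixel frame (top-left origin, x rightward, y downward,
0-based), while region extents (``width``, ``height``) are expressed in
pixels of the *target* level.  Extents are half-open.

A pyramid level ``L`` stores the image at ``downsample`` times lower
resolution than level 0.  Optical magnification of a level is
``base_magnification / downsample`` (a slide scanned at x400 exposes its
x1.25 plane at downsample 320).

Pyramids written by :func:`write_pyramid` use 2x box-mean downsampling with
round-half-up integer rounding; this rule is part of the public contract so
tests can predict downsampled pixel values exactly.
"""

from __future__ import annotations

import json
import math
import threading
from dataclasses import dataclass, field

import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize

from .errors import (
    BoundsError,
    FormatError,
    MetadataError,
    ResolutionError,
)

__all__ = [
    "Level",
    "PyramidImage",
    "RegionRequest",
    "open_pyramid",
    "read_region",
    "plane_at_magnification",
    "read_patch_at_magnification",
    "write_pyramid",
    "box_mean_downsample",
]

_MAG_EPS = 1e-6


@dataclass(frozen=True)
class Level:
    width: int
    height: int
    downsample: float


@dataclass
class PyramidImage:
    """Metadata handle for a pyramidal image; pixel data is read lazily."""

    path: str
    levels: list[Level]
    base_magnification: float
    channels: int
    tile_size: int
    _cache: dict = field(default_factory=dict, repr=False)
    _lock: threading.Lock = field(default_factory=threading.Lock, repr=False)

    @property
    def width(self) -> int:
        return self.levels[0].width

    @property
    def height(self) -> int:
        return self.levels[0].height

    def level_magnification(self, level: int) -> float:
        return self.base_magnification / self.levels[level].downsample

    def _level_array(self, level: int) -> np.ndarray:
        """Decode and cache a stored level (thread-safe)."""
        with self._lock:
            if level not in self._cache:
                with tifffile.TiffFile(self.path) as tf:
                    arr = tf.series[0].levels[level].asarray()
                if arr.ndim == 2:
                    arr = arr[:, :, None]
                self._cache[level] = np.ascontiguousarray(arr)
            return self._cache[level]


@dataclass(frozen=True)
class RegionRequest:
    """A rectangular read: origin in the level-0 frame, extent at `level`."""

    level: int
    x0: int
    y0: int
    width: int
    height: int


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def box_mean_downsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Box-mean downsample by an integer factor with round-half-up.

    Partial edge blocks are averaged over the pixels actually present, so
    output dims are ``ceil(dim / factor)``.
    """
    if factor == 1:
        return image.copy()
    arr = image if image.ndim == 3 else image[:, :, None]
    h, w = arr.shape[:2]
    ih = np.arange(0, h, factor)
    iw = np.arange(0, w, factor)
    sums = np.add.reduceat(arr.astype(np.float64), ih, axis=0)
    sums = np.add.reduceat(sums, iw, axis=1)
    ch = np.minimum(ih + factor, h) - ih
    cw = np.minimum(iw + factor, w) - iw
    counts = np.outer(ch, cw)[:, :, None]
    out = _round_half_up(sums / counts).astype(image.dtype)
    return out if image.ndim == 3 else out[:, :, 0]


def write_pyramid(
    image: np.ndarray,
    tile_size: int,
    n_levels: int,
    path,
    base_magnification: float | None = None,
    compression: str | None = "zlib",
) -> None:
    """Write a tiled pyramidal TIFF; level L is the 2^L box-mean of level 0.

    Compression is lossless (deflate by default); level 0 round-trips
    bit-identically.  ``base_magnification`` is stored in the image
    description so :func:`open_pyramid` can recover it without a manifest.
    """
    if image.dtype != np.uint8:
        raise TypeError(f"pyramid image must be uint8, got {image.dtype}")
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3 or image.shape[2] not in (1, 3):
        raise TypeError("image must have 1 or 3 channels")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")

    meta = {"channels": int(image.shape[2]), "tile_size": int(tile_size)}
    if base_magnification is not None:
        meta["base_magnification"] = float(base_magnification)

    def _squeeze(a):
        return a[:, :, 0] if a.shape[2] == 1 else a

    with tifffile.TiffWriter(str(path)) as tw:
        tw.write(
            _squeeze(image),
            tile=(tile_size, tile_size),
            compression=compression,
            subifds=n_levels - 1,
            description=json.dumps(meta),
        )
        for lvl in range(1, n_levels):
            sub = box_mean_downsample(image, 2**lvl)
            tw.write(
                _squeeze(sub),
                tile=(tile_size, tile_size),
                compression=compression,
                subfiletype=1,
            )


def open_pyramid(path, base_magnification: float | None = None) -> PyramidImage:
    """Open a pyramidal tiled TIFF and populate metadata (no pixel decode).

    Base magnification is read from the embedded JSON description when
    present; otherwise the caller must supply it (e.g. from a cohort
    manifest).
    """
    try:
        tf = tifffile.TiffFile(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap reader errors
        raise FormatError(f"cannot read {path!s} as TIFF: {exc}") from exc

    with tf:
        try:
            series = tf.series[0]
            stored = series.levels
            page0 = stored[0].pages[0] if hasattr(stored[0], "pages") else stored[0]
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"{path!s} has no readable image series") from exc

        desc_meta = {}
        desc = getattr(page0, "description", "") or ""
        if desc.startswith("{"):
            try:
                desc_meta = json.loads(desc)
            except json.JSONDecodeError:
                desc_meta = {}

        shapes = []
        for lv in stored:
            shp = lv.shape
            if len(shp) == 2:
                h, w, c = shp[0], shp[1], 1
            elif len(shp) == 3:
                h, w, c = shp[0], shp[1], shp[2]
            else:
                raise FormatError(f"unsupported level shape {shp} in {path!s}")
            shapes.append((w, h, c))

    w0, h0, c0 = shapes[0]
    if c0 not in (1, 3):
        raise FormatError(f"{path!s}: expected 1 or 3 channels, got {c0}")
    levels = []
    for w, h, _ in shapes:
        ds = ((w0 / w) + (h0 / h)) / 2.0
        levels.append(Level(width=w, height=h, downsample=ds))
    if any(levels[i].downsample >= levels[i + 1].downsample for i in range(len(levels) - 1)):
        raise FormatError(f"{path!s}: level downsamples are not strictly increasing")

    mag = desc_meta.get("base_magnification", base_magnification)
    if mag is None:
        raise MetadataError(
            f"{path!s} has no base magnification metadata and none was supplied"
        )
    tile = int(desc_meta.get("tile_size", getattr(page0, "tilewidth", 0) or 0))
    return PyramidImage(
        path=str(path),
        levels=levels,
        base_magnification=float(mag),
        channels=c0,
        tile_size=tile,
    )


def read_region(pyr: PyramidImage, req: RegionRequest) -> np.ndarray:
    """Read exactly the requested pixels of a stored level.

    Out-of-bounds requests raise :class:`BoundsError`; there is no silent
    clamping.  Concurrent calls are safe and observe identical data.
    """
    if not (0 <= req.level < len(pyr.levels)):
        raise BoundsError(f"level {req.level} outside [0, {len(pyr.levels)})")
    if req.width < 1 or req.height < 1:
        raise BoundsError("region extent must be >= 1 px")
    lv = pyr.levels[req.level]
    ds = lv.downsample
    if req.x0 < 0 or req.y0 < 0:
        raise BoundsError("negative region origin")
    if req.x0 + req.width * ds > pyr.width + _MAG_EPS:
        raise BoundsError(
            f"x extent {req.x0}+{req.width}*{ds} exceeds level-0 width {pyr.width}"
        )
    if req.y0 + req.height * ds > pyr.height + _MAG_EPS:
        raise BoundsError(
            f"y extent {req.y0}+{req.height}*{ds} exceeds level-0 height {pyr.height}"
        )
    xs = int(math.floor(req.x0 / ds + 0.5))
    ys = int(math.floor(req.y0 / ds + 0.5))
    xs = min(xs, lv.width - req.width)
    ys = min(ys, lv.height - req.height)
    arr = pyr._level_array(req.level)
    return arr[ys : ys + req.height, xs : xs + req.width].copy()


def _resize_u8(arr: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an 8-bit array, returned as 8-bit (round-half-up)."""
    if arr.shape[:2] == out_hw:
        return arr.copy()
    res = _sk_resize(
        arr.astype(np.float64),
        out_hw + arr.shape[2:],
        order=1,
        anti_aliasing=False,
        preserve_range=True,
        mode="edge",
    )
    return np.clip(_round_half_up(res), 0, 255).astype(np.uint8)


def _finest_level_at_or_above(pyr: PyramidImage, target_mag: float) -> int:
    """Index of the stored level with the smallest magnification >= target."""
    if target_mag > pyr.base_magnification * (1 + _MAG_EPS):
        raise ResolutionError(
            f"requested x{target_mag} exceeds base x{pyr.base_magnification}"
        )
    best = 0
    for i, lv in enumerate(pyr.levels):
        mag = pyr.base_magnification / lv.downsample
        if mag >= target_mag * (1 - _MAG_EPS):
            best = i
    return best


def plane_at_magnification(
    pyr: PyramidImage, target_mag: float
) -> tuple[np.ndarray, float]:
    """Return the full image plane at an exact optical magnification.

    Selects the stored level with the smallest magnification >= target, then
    bilinearly resizes to the exact target dimensions
    ``round(level0_dims * target_mag / base_mag)``.  Never upsamples beyond
    the base plane.  Returns ``(image, effective_downsample)`` where the
    effective downsample is ``base_magnification / target_mag``.
    """
    lvl = _finest_level_at_or_above(pyr, target_mag)
    scale = target_mag / pyr.base_magnification
    out_hw = (
        int(round(pyr.height * scale)),
        int(round(pyr.width * scale)),
    )
    arr = pyr._level_array(lvl)
    return _resize_u8(arr, out_hw), pyr.base_magnification / target_mag


def read_patch_at_magnification(
    pyr: PyramidImage, x0: int, y0: int, size: int, target_mag: float
) -> np.ndarray:
    """Read a square ``size x size`` patch at an exact magnification.

    ``(x0, y0)`` is the patch top-left in the level-0 frame.  Pixels come
    from the nearest finer stored level and are resized, so the patch is
    exact at ``target_mag`` regardless of which levels the file stores.
    """
    lvl = _finest_level_at_or_above(pyr, target_mag)
    ds_total = pyr.base_magnification / target_mag
    ds_stored = pyr.levels[lvl].downsample
    w_stored = int(round(size * ds_total / ds_stored))
    region = read_region(
        pyr, RegionRequest(level=lvl, x0=x0, y0=y0, width=w_stored, height=w_stored)
    )
    return _resize_u8(region, (size, size))
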