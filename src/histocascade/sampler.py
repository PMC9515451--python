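"""Hierarchical balanced batch generation.

Training patches are drawn down a grade -> WSI -> class -> patch tree with
a uniform choice at each stage, so rare grades, small slides and the
minority class are all equally represented regardless of how many patches
each branch holds.  Sampling is with replacement; an epoch is a fixed
number of batches, not a permutation of the index.  Branches that do not
exist (a tumor-free slide, a grade with no slides) are pruned rather than
erroring, keeping the remaining outcomes equally probable.

Pixels are streamed straight from the pyramidal files at x100
magnification; the sampler never writes patch pixels to disk.  Reads may
be parallelised across a thread pool; random draws stay serial, so the
produced batches are identical to single-worker execution.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
import queue as _queue
import threading

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, HistoError
from .preprocess import PatchIndexTable, PatchRecord
from .wsi_io import PyramidImage, open_pyramid, read_patch_at_magnification

__all__ = [
    "SamplingTree",
    "PatchBatch",
    "CohortReader",
    "build_tree",
    "draw_patch",
    "generate_batch",
    "iter_batches",
    "SamplerConfig",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Per-epoch batch volumes and prefetch settings."""

    batches_per_epoch_train: int = 500
    batches_per_epoch_val: int = 200
    batch_size: int = 64
    workers: int = 8
    queue: int = 20
    seed: int = 0


@dataclass
class _WsiNode:
    wsi_id: str
    classes: dict[int, list[PatchRecord]]


@dataclass
class SamplingTree:
    grades: dict[str, list[_WsiNode]]
    patch_size: int
    patch_magnification: float
    n_classes: int = 2


class CohortReader:
    """Maps wsi_id to an open pyramid and serves patch pixel reads."""

    def __init__(self, paths: dict[str, str],
                 magnifications: dict[str, float] | None = None):
        self._paths = dict(paths)
        self._mags = magnifications or {}
        self._pyramids: dict[str, PyramidImage] = {}
        self._lock = threading.Lock()

    @classmethod
    def from_manifest(cls, manifest: pd.DataFrame) -> "CohortReader":
        return cls({str(p): str(p) for p in manifest["wsi_path"]})

    def pyramid(self, wsi_id: str) -> PyramidImage:
        with self._lock:
            if wsi_id not in self._pyramids:
                if wsi_id not in self._paths:
                    raise HistoError(f"unknown wsi_id {wsi_id!r}")
                self._pyramids[wsi_id] = open_pyramid(
                    self._paths[wsi_id], self._mags.get(wsi_id)
                )
            return self._pyramids[wsi_id]

    def read_patch(self, rec: PatchRecord, size: int, mag: float) -> np.ndarray:
        try:
            pyr = self.pyramid(rec.wsi_id)
            return read_patch_at_magnification(pyr, rec.x0, rec.y0, size, mag)
        except HistoError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise HistoError(
                f"failed reading patch at ({rec.x0},{rec.y0}) of {rec.wsi_id!r}: {exc}"
            ) from exc


@dataclass
class PatchBatch:
    images: np.ndarray            # B x S x S x 3 float32 in [0, 1]
    labels_onehot: np.ndarray     # B x C
    cluster_ids: np.ndarray | None
    sources: list[PatchRecord]


def build_tree(tables: list[PatchIndexTable]) -> SamplingTree:
    """Group patch records by grade -> WSI -> class, pruning empty branches."""
    grades: dict[str, list[_WsiNode]] = {}
    patch_size = patch_mag = None
    for tab in tables:
        if not tab.records:
            continue
        patch_size = tab.patch_size
        patch_mag = tab.patch_magnification
        classes: dict[int, list[PatchRecord]] = {}
        for rec in tab.records:
            if rec.label is None:
                continue
            classes.setdefault(rec.label, []).append(rec)
        if not classes:
            continue
        grade = tab.grade if tab.grade is not None else "?"
        grades.setdefault(grade, []).append(
            _WsiNode(wsi_id=tab.wsi_id, classes=classes)
        )
    if not grades:
        raise EmptyCohortError("no labeled patches in any table")
    return SamplingTree(
        grades=grades, patch_size=patch_size, patch_magnification=patch_mag
    )


def draw_patch(tree: SamplingTree, rng: np.random.Generator) -> PatchRecord:
    """One uniform draw per stage: grade, WSI, class, patch."""
    grade_keys = sorted(tree.grades)
    grade = grade_keys[rng.integers(len(grade_keys))]
    wsis = tree.grades[grade]
    node = wsis[rng.integers(len(wsis))]
    class_keys = sorted(node.classes)
    label = class_keys[rng.integers(len(class_keys))]
    recs = node.classes[label]
    return recs[rng.integers(len(recs))]


def generate_batch(
    tree: SamplingTree,
    rng: np.random.Generator,
    reader: CohortReader,
    batch_size: int,
    cluster_model=None,
    workers: int = 1,
) -> PatchBatch:
    """Draw a batch and stream its pixels from the pyramids at x100.

    Draws are serial (so the batch is a pure function of the rng state);
    only the pixel reads fan out over ``workers`` threads.
    """
    recs = [draw_patch(tree, rng) for _ in range(batch_size)]
    size, mag = tree.patch_size, tree.patch_magnification

    def _read(rec):
        return reader.read_patch(rec, size, mag)

    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as ex:
            imgs = list(ex.map(_read, recs))
    else:
        imgs = [_read(r) for r in recs]
    images = np.stack(imgs).astype(np.float32) / np.float32(255.0)

    labels = np.zeros((batch_size, tree.n_classes), dtype=np.float32)
    for i, rec in enumerate(recs):
        labels[i, rec.label] = 1.0

    cluster_ids = None
    if cluster_model is not None:
        from .cluster import assign_clusters, extract_features

        feats = extract_features(images, cluster_model.extractor_id)
        cluster_ids = assign_clusters(feats, cluster_model)
    return PatchBatch(
        images=images, labels_onehot=labels, cluster_ids=cluster_ids, sources=recs
    )


def iter_batches(
    tree: SamplingTree,
    rng: np.random.Generator,
    reader: CohortReader,
    n_batches: int,
    batch_size: int,
    cluster_model=None,
    workers: int = 1,
    queue_size: int = 20,
):
    """Yield ``n_batches`` batches, optionally prefetching in a background
    thread through a bounded queue.  Draw order is serial either way, so the
    stream is identical to unprefetched execution."""
    if workers <= 1:
        for _ in range(n_batches):
            yield generate_batch(tree, rng, reader, batch_size, cluster_model)
        return

    q: _queue.Queue = _queue.Queue(maxsize=queue_size)
    stop = object()

    def _producer():
        try:
            for _ in range(n_batches):
                q.put(
                    generate_batch(
                        tree, rng, reader, batch_size, cluster_model, workers
                    )
                )
        finally:
            q.put(stop)

    t = threading.Thread(target=_producer, daemon=True)
    t.start()
    while True:
        item = q.get()
        if item is stop:
            break
        yield item
    t.join()
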