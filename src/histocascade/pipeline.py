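"""Desk-scale end-to-end experiment on a synthetic cohort.

This module wires the whole cascade together at sizes a single CPU handles
in minutes: generate a synthetic cohort, detect tissue and index patches,
train the patch classifier with hierarchical balanced sampling, stitch
heatmaps, train the refinement network, and score the refined cascade, the
thresholded heatmap and the Otsu tissue baseline on held-out slides.

The defaults reproduce the qualitative ordering of the full-scale design -
refined cascade >= patch-wise thresholding >= tissue-only baseline - not
its absolute numbers, which require a large annotated cohort and heavier
backbones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cluster import ClusterModel
from .evaluate import aggregate, resample_mask, wsi_metrics
from .infer import (
    otsu_baseline,
    predict_heatmap,
    refine_segmentation,
    refiner_input,
    threshold_heatmap,
)
from .models import ClassifierSpec, RefinerSpec
from .preprocess import BinaryMask, detect_tissue, index_patches
from .sampler import CohortReader, build_tree
from .synthetic import CohortSpec, generate_cohort
from .train import AugmentConfig, TrainConfig, train_patch_classifier, train_refiner
from .wsi_io import open_pyramid

__all__ = ["ExperimentConfig", "run_synthetic_experiment"]

REDUCED_REFINER_FILTERS = (4, 8, 16, 16, 32, 32, 64)


@dataclass(frozen=True)
class ExperimentConfig:
    """Scaled-down study conditions for the synthetic end-to-end run."""

    n_wsi: int = 16
    n_heldout: int = 4
    seed: int = 0
    clf_epochs: int = 5
    clf_batches_per_epoch: tuple[int, int] = (20, 5)
    clf_batch_size: int = 32
    clf_lr: float = 1e-4
    refiner_size: int = 256
    refiner_depth: int = 7
    refiner_filters: tuple[int, ...] = REDUCED_REFINER_FILTERS
    refiner_epochs: int = 60
    refiner_patience: int = 10
    refiner_lr: float = 1e-3
    refiner_batch_size: int = 4
    refiner_accumulation: int = 1
    n_refiner_val: int = 3
    use_cluster_model: bool = False
    cohort: CohortSpec | None = None


def _load_annotation(path: str, wsi) -> BinaryMask:
    anno = open_pyramid(path)
    ds = wsi.width / anno.width
    return BinaryMask(grid=anno._level_array(0)[:, :, 0], downsample=ds)


def run_synthetic_experiment(cfg: ExperimentConfig, work_dir) -> dict:
    """Run the full cascade on a synthetic cohort; returns a results dict.

    Keys: ``report_refined`` / ``report_patchwise`` / ``report_otsu``
    (:class:`CohortReport` over the held-out slides), per-method mean DSC
    shortcuts, training histories, and the cohort manifest.
    """
    work = Path(work_dir)
    work.mkdir(parents=True, exist_ok=True)
    cohort_spec = cfg.cohort or CohortSpec(n_wsi=cfg.n_wsi, seed=cfg.seed)
    wsis, manifest = generate_cohort(cohort_spec, work / "cohort")

    n_train = cfg.n_wsi - cfg.n_heldout
    train_idx = list(range(n_train))
    held_idx = list(range(n_train, cfg.n_wsi))

    # --- preprocessing: tissue masks, annotations, patch indices
    tissues, annos, tables = {}, {}, []
    for i in train_idx:
        wsi = wsis[i]
        wsi_id = manifest.loc[i, "wsi_path"]
        tis = detect_tissue(wsi.pyramid)
        ann = _load_annotation(manifest.loc[i, "annotation_path"], wsi.pyramid)
        tissues[i], annos[i] = tis, ann
        tables.append(
            index_patches(wsi.pyramid, tis, ann, grade=wsi.grade, wsi_id=wsi_id)
        )
    tree = build_tree(tables)
    reader = CohortReader({str(p): str(p) for p in manifest["wsi_path"]})

    # --- stage 1: patch classifier
    cluster_model: ClusterModel | None = None
    if cfg.use_cluster_model:
        from .cluster import collect_features, fit_cluster_model

        feats = collect_features(
            tree, np.random.default_rng(cfg.seed + 1), reader,
            n_batches=20, batch_size=32,
        )
        cluster_model = fit_cluster_model(feats, seed=cfg.seed)

    clf_cfg = TrainConfig(
        lr=cfg.clf_lr,
        epochs=cfg.clf_epochs,
        batches_per_epoch=cfg.clf_batches_per_epoch,
        batch_size=cfg.clf_batch_size,
        seed=cfg.seed,
        aug=AugmentConfig.classifier_default(),
    )
    clf_spec = ClassifierSpec(seed=cfg.seed)
    classifier, clf_history = train_patch_classifier(
        tree, reader, cluster_model, clf_spec, clf_cfg
    )

    # --- stage 2: refiner trained on train-set heatmaps
    size = cfg.refiner_size
    triples = []
    for i in train_idx:
        pyr = wsis[i].pyramid
        hm = predict_heatmap(pyr, classifier, tissues[i])
        x4 = refiner_input(pyr, hm, size)
        gt = resample_mask(annos[i].grid, (size, size)).astype(np.float32)
        triples.append((x4[..., :3], x4[..., 3], gt))
    rng = np.random.default_rng(cfg.seed + 2)
    order = rng.permutation(len(triples))
    val = [triples[j] for j in order[: cfg.n_refiner_val]]
    fit = [triples[j] for j in order[cfg.n_refiner_val :]]

    ref_spec = RefinerSpec(
        input_size=size, depth=cfg.refiner_depth,
        filters=cfg.refiner_filters, seed=cfg.seed,
    )
    ref_cfg = TrainConfig(
        lr=cfg.refiner_lr,
        epochs=cfg.refiner_epochs,
        batch_size=cfg.refiner_batch_size,
        accumulation_steps=cfg.refiner_accumulation,
        early_stop_patience=cfg.refiner_patience,
        seed=cfg.seed,
        loss="dice",
        aug=AugmentConfig.refiner_default(),
    )
    refiner, ref_history = train_refiner(fit, val, ref_spec, ref_cfg)

    # --- held-out evaluation, all three designs
    rows = {"refined": [], "patchwise": [], "otsu": []}
    for i in held_idx:
        wsi = wsis[i]
        pyr = wsi.pyramid
        wsi_id = manifest.loc[i, "wsi_path"]
        gt_grid = _load_annotation(manifest.loc[i, "annotation_path"], pyr).grid
        tis = detect_tissue(pyr)
        hm = predict_heatmap(pyr, classifier, tis)
        seg_ref = refine_segmentation(pyr, hm, refiner)
        seg_pw = threshold_heatmap(hm, out_size=size)
        seg_otsu = otsu_baseline(pyr, out_size=size)
        for tag, seg in (("refined", seg_ref), ("patchwise", seg_pw),
                         ("otsu", seg_otsu)):
            gt = resample_mask(gt_grid, seg.binary.shape)
            rows[tag].append(
                wsi_metrics(seg.binary, gt, wsi_id=wsi_id, grade=wsi.grade)
            )

    reports = {tag: aggregate(ms) for tag, ms in rows.items()}
    return {
        "manifest": manifest,
        "classifier": classifier,
        "refiner": refiner,
        "cluster_model": cluster_model,
        "clf_history": clf_history,
        "ref_history": ref_history,
        "metrics": rows,
        "report_refined": reports["refined"],
        "report_patchwise": reports["patchwise"],
        "report_otsu": reports["otsu"],
        "dsc_refined": reports["refined"].overall["dsc"][0],
        "dsc_patchwise": reports["patchwise"].overall["dsc"][0],
        "dsc_otsu": reports["otsu"].overall["dsc"][0],
    }
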