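"""Losses, augmentation operators, and the two training loops.

Cluster-weighted categorical cross-entropy (CWCE)
-------------------------------------------------
For a batch of softmax predictions p_{i,c} with one-hot labels y_{i,c} and
hard cluster assignments q_i, the per-cluster cross-entropy is averaged
within each cluster represented in the batch, and the loss is the
unweighted (macro) mean over those represented clusters:

    L = (1/K_b) * sum_k  mean_{i : q_i = k}  ( -sum_c y_{i,c} log p_{i,c} )

With a single represented cluster this reduces exactly to the plain mean
categorical cross-entropy, which is also the no-clustering code path.
Probabilities are clipped at 1e-7 before the log.

Augmentation
------------
Patch-stage operators: horizontal/vertical flips, lossless 90-degree
rotations, HSV shifts (integers in [-20, 20] on the 8-bit scale) and
multiplicative brightness ([0.8, 1.2]); each applied independently with
probability 0.5.  Segmentation-stage operators add random zoom
([0.8, 1.2]) and Macenko stain augmentation, with geometric transforms
applied identically to image, heatmap and mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize as _sk_resize

from . import _nn as nn
from .errors import GeometryError
from .models import (
    ClassifierSpec,
    PatchClassifier,
    Refiner,
    RefinerSpec,
    build_patch_classifier,
    build_refiner,
)
from .sampler import CohortReader, SamplingTree, generate_batch

__all__ = [
    "PredictionBatch",
    "TrainConfig",
    "AugmentConfig",
    "cwce_loss",
    "augment_patch",
    "macenko_stain_augment",
    "estimate_stain_matrix",
    "augment_seg_pair",
    "train_patch_classifier",
    "train_refiner",
    "soft_dice_loss",
]

_LOG_CLIP = 1e-7


@dataclass
class PredictionBatch:
    probs: np.ndarray          # B x C softmax outputs
    labels_onehot: np.ndarray  # B x C
    cluster_ids: np.ndarray    # B ints in {0..k-1}


def cwce_loss(batch: PredictionBatch) -> float:
    """Cluster-weighted categorical cross-entropy (macro over clusters)."""
    p = np.clip(np.asarray(batch.probs, dtype=np.float64), _LOG_CLIP, 1.0)
    y = np.asarray(batch.labels_onehot, dtype=np.float64)
    if p.shape[0] == 0:
        raise ValueError("empty batch")
    ce = -(y * np.log(p)).sum(axis=1)
    q = np.asarray(batch.cluster_ids)
    total = 0.0
    present = np.unique(q)
    for k in present:
        total += ce[q == k].mean()
    return float(total / len(present))


def _cwce_weights(cluster_ids: np.ndarray) -> np.ndarray:
    """Per-sample weights realizing CWCE as a weighted sum of sample CEs."""
    q = np.asarray(cluster_ids)
    present, counts = np.unique(q, return_counts=True)
    kb = len(present)
    w = np.empty(len(q), dtype=np.float64)
    for k, c in zip(present, counts):
        w[q == k] = 1.0 / (kb * c)
    return w


# ---------------------------------------------------------------------------
# augmentation configuration


@dataclass(frozen=True)
class AugmentConfig:
    p_apply: float = 0.5
    hsv_shift: tuple[int, int] = (-20, 20)
    brightness: tuple[float, float] = (0.8, 1.2)
    zoom: tuple[float, float] = (0.8, 1.2)
    stain_sigma: float = 0.1
    operators: tuple[str, ...] = ("flip", "rot90", "hsv", "brightness")

    @staticmethod
    def classifier_default() -> "AugmentConfig":
        return AugmentConfig()

    @staticmethod
    def refiner_default() -> "AugmentConfig":
        return AugmentConfig(operators=("flip", "rot90", "zoom", "stain"))


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 100
    batches_per_epoch: tuple[int, int] = (500, 200)  # (train, val)
    batch_size: int = 64
    accumulation_steps: int = 1
    early_stop_patience: int | None = None
    seed: int = 0
    loss: str = "dice"  # refiner loss: "dice" or "ce"
    aug: AugmentConfig = field(default_factory=AugmentConfig)


# ---------------------------------------------------------------------------
# patch-stage augmentation


def _apply_hsv_shift(img: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    hsv = rgb2hsv(np.clip(img, 0.0, 1.0))
    hsv = np.clip(hsv + shifts.astype(np.float64) / 255.0, 0.0, 1.0)
    return hsv2rgb(hsv)


def augment_patch(img: np.ndarray, rng: np.random.Generator,
                  cfg: AugmentConfig) -> np.ndarray:
    """Photometric/flip augmentation of a single [0,1] RGB patch."""
    out = img
    ops = cfg.operators
    p = cfg.p_apply
    if "flip" in ops:
        if rng.random() < p:
            out = out[:, ::-1]
        if rng.random() < p:
            out = out[::-1, :]
    if "rot90" in ops and rng.random() < p:
        out = np.rot90(out, k=int(rng.integers(4)))
    if "hsv" in ops and rng.random() < p:
        lo, hi = cfg.hsv_shift
        shifts = rng.integers(lo, hi + 1, size=3)
        out = _apply_hsv_shift(out, shifts)
    if "brightness" in ops and rng.random() < p:
        lo, hi = cfg.brightness
        out = np.clip(out * rng.uniform(lo, hi), 0.0, 1.0)
    return np.ascontiguousarray(out, dtype=np.float32)


# ---------------------------------------------------------------------------
# Macenko stain estimation and augmentation

_OD_EPS = 1e-6
_OD_BETA = 0.15
_ANGLE_ALPHA = 1.0


def _to_od(img: np.ndarray) -> np.ndarray:
    return -np.log10(np.maximum(img.astype(np.float64), _OD_EPS))


def estimate_stain_matrix(img: np.ndarray, beta: float = _OD_BETA,
                          alpha: float = _ANGLE_ALPHA) -> np.ndarray | None:
    """Estimate a 3x2 stain matrix by the Macenko extreme-angle procedure.

    Returns ``None`` when too few pixels exceed the optical-density
    threshold (pure background).  Columns are unit stain vectors ordered by
    their first (red-channel OD) coordinate.
    """
    od = _to_od(img).reshape(-1, 3)
    odh = od[~np.any(od < beta, axis=1)]
    if odh.shape[0] < 10:
        return None
    cov = np.cov(odh.T)
    evals, evecs = np.linalg.eigh(cov)
    basis = evecs[:, [2, 1]]  # top-2 eigenvectors of the OD scatter
    # rotate the in-plane basis so the mean OD direction sits at angle 0;
    # the stain wedge is < 90 deg wide, so percentile angles cannot wrap
    m = basis.T @ odh.mean(axis=0)
    norm_m = np.linalg.norm(m)
    if norm_m > 0:
        e1 = m / norm_m
        basis = np.stack([basis @ e1, basis @ [-e1[1], e1[0]]], axis=1)
    proj = odh @ basis
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(phi, alpha)
    hi = np.percentile(phi, 100 - alpha)
    v1 = basis @ np.array([np.cos(lo), np.sin(lo)])
    v2 = basis @ np.array([np.cos(hi), np.sin(hi)])
    if v1[0] < 0:
        v1 = -v1
    if v2[0] < 0:
        v2 = -v2
    he = np.stack([v1, v2], axis=1)
    if he[0, 0] < he[0, 1]:
        he = he[:, ::-1]
    norms = np.linalg.norm(he, axis=0)
    return he / norms


def macenko_stain_augment(img: np.ndarray, rng: np.random.Generator,
                          sigma1: float = 0.1, sigma2: float = 0.1
                          ) -> np.ndarray:
    """Perturb stain concentrations after Macenko stain estimation.

    OD is decomposed onto the two estimated stain vectors; each stain's
    concentration is scaled by ``1 + U(-sigma1, sigma1)`` and offset by
    ``U(-sigma2, sigma2)``.  The residual of the two-stain fit is kept, so
    zero-sigma augmentation is an identity up to the OD round-trip.
    Background-only images are returned unchanged.
    """
    he = estimate_stain_matrix(img)
    if he is None:
        return img.astype(np.float32, copy=True)
    shape = img.shape
    od = _to_od(img).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(he, od.T, rcond=None)  # 2 x n
    scale = 1.0 + rng.uniform(-sigma1, sigma1, size=2)
    offset = rng.uniform(-sigma2, sigma2, size=2)
    conc_new = conc * scale[:, None] + offset[:, None]
    od_new = od + (he @ (conc_new - conc)).T
    out = np.power(10.0, -od_new).reshape(shape)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# segmentation-stage augmentation


def _zoom_to(arr: np.ndarray, factor: float, order: int, pad_value: float
             ) -> np.ndarray:
    """Zoom by `factor`, then center-crop or pad back to the input size."""
    h, w = arr.shape[:2]
    nh, nw = max(1, int(round(h * factor))), max(1, int(round(w * factor)))
    res = _sk_resize(arr.astype(np.float64), (nh, nw) + arr.shape[2:],
                     order=order, anti_aliasing=False, preserve_range=True,
                     mode="edge")
    out = np.full(arr.shape, pad_value, dtype=np.float64)
    if factor >= 1.0:
        y0, x0 = (nh - h) // 2, (nw - w) // 2
        out[...] = res[y0:y0 + h, x0:x0 + w]
    else:
        y0, x0 = (h - nh) // 2, (w - nw) // 2
        out[y0:y0 + nh, x0:x0 + nw] = res
    return out.astype(np.float32)


def augment_seg_pair(img: np.ndarray, heatmap: np.ndarray, gt_mask: np.ndarray,
                     rng: np.random.Generator, cfg: AugmentConfig
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Co-transform (image, heatmap, mask) for refiner training.

    Flips/rotations/zoom use one shared draw; interpolation is bilinear for
    image and heatmap, nearest for the mask; zoom-out pads the image with
    white (1.0) and heatmap/mask with 0.  Stain augmentation touches the
    image only.
    """
    if img.shape[:2] != heatmap.shape[:2] or img.shape[:2] != gt_mask.shape[:2]:
        raise GeometryError("image, heatmap and mask must be aligned")
    ops = cfg.operators
    p = cfg.p_apply
    im, hm, gt = img, heatmap, gt_mask
    if "flip" in ops:
        if rng.random() < p:
            im, hm, gt = im[:, ::-1], hm[:, ::-1], gt[:, ::-1]
        if rng.random() < p:
            im, hm, gt = im[::-1], hm[::-1], gt[::-1]
    if "rot90" in ops and rng.random() < p:
        k = int(rng.integers(4))
        im, hm, gt = np.rot90(im, k), np.rot90(hm, k), np.rot90(gt, k)
    if "zoom" in ops and rng.random() < p:
        f = float(rng.uniform(*cfg.zoom))
        if abs(f - 1.0) > 1e-12:
            im = _zoom_to(im, f, order=1, pad_value=1.0)
            hm = _zoom_to(hm, f, order=1, pad_value=0.0)
            gt = _zoom_to(gt, f, order=0, pad_value=0.0)
    if "stain" in ops and rng.random() < p:
        im = macenko_stain_augment(np.ascontiguousarray(im), rng,
                                   cfg.stain_sigma, cfg.stain_sigma)
    return (np.ascontiguousarray(im, dtype=np.float32),
            np.ascontiguousarray(hm, dtype=np.float32),
            np.ascontiguousarray(gt, dtype=np.float32))


# ---------------------------------------------------------------------------
# losses used by the loops


def _weighted_ce_and_grad(probs: np.ndarray, y: np.ndarray, w: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Weighted-sum cross-entropy with gradient w.r.t. the softmax logits."""
    p = np.clip(probs.astype(np.float64), _LOG_CLIP, 1.0)
    loss = float((w * -(y * np.log(p)).sum(axis=1)).sum())
    dlogits = (probs - y) * w[:, None]
    return loss, dlogits.astype(nn.F32)


def soft_dice_loss(probs_fg: np.ndarray, target: np.ndarray,
                   eps: float = 1.0) -> tuple[float, np.ndarray]:
    """Per-sample soft Dice on the foreground channel, averaged over the
    batch; returns (loss, dloss/dprobs_fg).  Decomposable over samples, so
    gradient accumulation is exact."""
    p = probs_fg.astype(np.float64)
    t = target.astype(np.float64)
    b = p.shape[0]
    axes = tuple(range(1, p.ndim))
    inter = (p * t).sum(axis=axes)
    psum = p.sum(axes)
    tsum = t.sum(axes)
    denom = psum + tsum + eps
    dice = (2 * inter + eps) / denom
    loss = float(1.0 - dice.mean())
    shape_ones = (b,) + (1,) * (p.ndim - 1)
    num_grad = 2 * t * denom.reshape(shape_ones) - (2 * inter + eps).reshape(shape_ones)
    dp = -(num_grad / (denom ** 2).reshape(shape_ones)) / b
    return loss, dp.astype(nn.F32)


# ---------------------------------------------------------------------------
# training loops


def train_patch_classifier(
    tree: SamplingTree,
    reader: CohortReader,
    cluster_model=None,
    spec: ClassifierSpec | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[PatchClassifier, pd.DataFrame]:
    """Train the patch classifier with hierarchical balanced batches.

    The loss is CWCE when a cluster model is supplied; without one every
    sample shares a single implicit cluster and the identical code path
    computes plain mean categorical cross-entropy.  The best epoch is
    selected by validation loss.
    """
    cfg = cfg or TrainConfig()
    model = build_patch_classifier(spec)
    opt = nn.Adam(model.params(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    n_train, n_val = cfg.batches_per_epoch
    history = []
    best = (math.inf, None, None)
    for epoch in range(cfg.epochs):
        tr_loss = tr_acc = 0.0
        for _ in range(n_train):
            batch = generate_batch(tree, rng, reader, cfg.batch_size,
                                   cluster_model)
            imgs = np.stack([
                augment_patch(im, rng, cfg.aug) for im in batch.images
            ])
            q = (batch.cluster_ids if batch.cluster_ids is not None
                 else np.zeros(len(imgs), dtype=int))
            w = _cwce_weights(q)
            logits = model.forward_logits(imgs, train=True, rng=rng)
            probs = nn.softmax(logits)
            loss, dlogits = _weighted_ce_and_grad(probs, batch.labels_onehot, w)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            opt.zero_grad()
            model.backward_logits(dlogits)
            opt.step()
            tr_loss += loss
            tr_acc += float(
                (probs.argmax(1) == batch.labels_onehot.argmax(1)).mean()
            )
        va_loss = va_acc = 0.0
        for _ in range(n_val):
            batch = generate_batch(tree, rng, reader, cfg.batch_size,
                                   cluster_model)
            probs = model.predict_proba(batch.images)
            q = (batch.cluster_ids if batch.cluster_ids is not None
                 else np.zeros(len(probs), dtype=int))
            va_loss += cwce_loss(PredictionBatch(probs, batch.labels_onehot, q))
            va_acc += float(
                (probs.argmax(1) == batch.labels_onehot.argmax(1)).mean()
            )
        row = {
            "epoch": epoch,
            "train_loss": tr_loss / n_train,
            "train_acc": tr_acc / n_train,
            "val_loss": va_loss / max(1, n_val),
            "val_acc": va_acc / max(1, n_val),
        }
        history.append(row)
        if row["val_loss"] < best[0]:
            from .models import _bn_stats

            best = (row["val_loss"], nn.get_state(model.params()),
                    _bn_stats(model))
    if best[1] is not None:
        from .models import _bn_layers

        nn.set_state(model.params(), best[1])
        for bn, (m, v) in zip(_bn_layers(model), best[2]):
            bn.run_mean[...] = m
            bn.run_var[...] = v
    return model, pd.DataFrame(history)


def _refiner_step(model: Refiner, xs: list[np.ndarray], ys: list[np.ndarray],
                  opt: nn.Adam, loss_kind: str, rng) -> float:
    """One optimiser step over len(xs) accumulation micro-batches."""
    opt.zero_grad()
    total = 0.0
    n_acc = len(xs)
    for x, t in zip(xs, ys):
        probs = model.forward_probs(x, train=True, rng=rng)
        if loss_kind == "dice":
            loss, dfg = soft_dice_loss(probs[..., 1], t)
            dprobs = np.zeros_like(probs)
            dprobs[..., 1] = dfg
            dprobs /= n_acc
            model.backward_probs(dprobs.astype(nn.F32))
        else:
            y = np.stack([1.0 - t, t], axis=-1).astype(np.float64)
            npix = t[0].size
            w = np.full(x.shape[0], 1.0 / (x.shape[0] * npix))
            p2 = probs.reshape(-1, 2)
            y2 = y.reshape(-1, 2)
            wpix = np.repeat(w, npix)
            loss, dlog = _weighted_ce_and_grad(p2, y2, wpix)
            model._probs = None
            model.backward_logits((dlog / n_acc).reshape(probs.shape))
        if not math.isfinite(loss):
            raise RuntimeError("non-finite refiner loss")
        total += loss
    opt.step()
    return total / n_acc


def _refiner_eval(model: Refiner, data, loss_kind: str) -> float:
    total = 0.0
    for img, hm, gt in data:
        x = np.concatenate([img, hm[..., None]], axis=-1)[None]
        probs = model.forward_probs(x, train=False)
        if loss_kind == "dice":
            loss, _ = soft_dice_loss(probs[..., 1], gt[None])
        else:
            p = np.clip(probs[..., 1], _LOG_CLIP, 1 - _LOG_CLIP)
            loss = float(-(gt * np.log(p) + (1 - gt) * np.log(1 - p)).mean())
        total += loss
    return total / max(1, len(data))


def train_refiner(
    train_data: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    val_data: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    spec: RefinerSpec | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[Refiner, pd.DataFrame]:
    """Train the refinement network on (low-res image, heatmap, mask) triples.

    Uses soft Dice (configurable to cross-entropy) with gradient
    accumulation (effective batch = batch_size * accumulation_steps) and
    early stopping on validation loss.  The best epoch's weights are kept.
    """
    cfg = cfg or TrainConfig(lr=1e-3, batch_size=4, accumulation_steps=6,
                             early_stop_patience=100)
    model = build_refiner(spec)
    opt = nn.Adam(model.params(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    history = []
    best = (math.inf, None, None, -1)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_data))
        tr_losses = []
        i = 0
        group = cfg.batch_size * cfg.accumulation_steps
        while i < len(order):
            idx = order[i:i + group]
            i += group
            xs, ys = [], []
            for j0 in range(0, len(idx), cfg.batch_size):
                sel = idx[j0:j0 + cfg.batch_size]
                ims, hms, gts = [], [], []
                for j in sel:
                    im, hm, gt = train_data[j]
                    im, hm, gt = augment_seg_pair(im, hm, gt, rng, cfg.aug)
                    ims.append(np.concatenate([im, hm[..., None]], axis=-1))
                    gts.append(gt)
                xs.append(np.stack(ims))
                ys.append(np.stack(gts))
            tr_losses.append(
                _refiner_step(model, xs, ys, opt, cfg.loss, rng)
            )
        va = _refiner_eval(model, val_data, cfg.loss)
        history.append({"epoch": epoch, "train_loss": float(np.mean(tr_losses)),
                        "val_loss": va})
        if va < best[0] - 1e-6:
            from .models import _bn_stats

            best = (va, nn.get_state(model.params()), _bn_stats(model), epoch)
        elif (cfg.early_stop_patience is not None
              and epoch - best[3] >= cfg.early_stop_patience):
            break
    if best[1] is not None:
        from .models import _bn_layers

        nn.set_state(model.params(), best[1])
        for bn, (m, v) in zip(_bn_layers(model), best[2]):
            bn.run_mean[...] = m
            bn.run_var[...] = v
    return model, pd.DataFrame(history)
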