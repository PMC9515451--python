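"""Heatmap stitching oracle, thresholding rules, Otsu baseline, cascade."""

import numpy as np
import pytest

from histocascade.infer import (
    Heatmap,
    otsu_baseline,
    predict_heatmap,
    refine_segmentation,
    run_cascade,
    threshold_heatmap,
)
from histocascade.preprocess import BinaryMask, detect_tissue
from histocascade.wsi_io import open_pyramid, write_pyramid


class _StubClassifier:
    """Lookup-table classifier: tumor probability depends only on the
    patch's grid cell, read from a table set at construction."""

    class spec:
        patch_size = 256
        patch_magnification = 100.0

    def __init__(self, table, delta=256):
        self.table = table
        self.delta = delta
        self.seen = []

    def predict_proba(self, imgs):
        # identify the cell by the marker value painted into pixel (0,0)
        out = []
        for im in imgs:
            key = int(round(im[0, 0, 0] * 255))
            p1 = self.table[key]
            out.append([1 - p1, p1])
        return np.array(out)


@pytest.fixture()
def cellcoded_wsi(tmp_path):
    """1024 px x100 slide whose cell (r, c) has marker value 16*(4r+c)+1
    stamped in its top-left pixel; saturated pink elsewhere."""
    img = np.zeros((1024, 1024, 3), dtype=np.uint8)
    img[...] = (230, 180, 190)
    for r in range(4):
        for c in range(4):
            v = 16 * (4 * r + c) + 1
            img[r * 256, c * 256] = (v, 0, 0)
    path = tmp_path / "cells.tiff"
    write_pyramid(img, 256, 1, path, base_magnification=100.0)
    return open_pyramid(path)


class TestPredictHeatmap:
    def test_stitched_grid_equals_stub_table(self, cellcoded_wsi):
        rng = np.random.default_rng(0)
        table = {16 * k + 1: float(rng.random()) for k in range(16)}
        clf = _StubClassifier(table)
        tissue = BinaryMask(np.ones((256, 256), dtype=np.uint8), 4.0)
        hm = predict_heatmap(cellcoded_wsi, clf, tissue)
        assert hm.grid.shape == (4, 4)
        for r in range(4):
            for c in range(4):
                v = 16 * (4 * r + c) + 1
                assert hm.grid[r, c] == pytest.approx(table[v], abs=1e-6)

    def test_invariant_to_batch_size(self, cellcoded_wsi):
        table = {16 * k + 1: (k + 1) / 20 for k in range(16)}
        tissue = BinaryMask(np.ones((256, 256), dtype=np.uint8), 4.0)
        grids = [
            predict_heatmap(cellcoded_wsi, _StubClassifier(table), tissue,
                            batch_size=bs).grid
            for bs in (1, 5, 16, 64)
        ]
        for g in grids[1:]:
            assert np.array_equal(g, grids[0])

    def test_non_tissue_cells_stay_zero(self, cellcoded_wsi):
        table = {16 * k + 1: 1.0 for k in range(16)}
        tissue_grid = np.zeros((256, 256), dtype=np.uint8)
        tissue_grid[:64, :64] = 1  # only cell (0,0) is tissue
        tissue = BinaryMask(tissue_grid, 4.0)
        hm = predict_heatmap(cellcoded_wsi, _StubClassifier(table), tissue)
        assert hm.grid[0, 0] == 1.0
        assert hm.grid.sum() == 1.0


class TestThresholdHeatmap:
    def _hm(self, grid):
        g = np.asarray(grid, dtype=np.float32)
        return Heatmap(grid=g, cell_size_level0=256.0,
                       level0_width=256 * g.shape[1],
                       level0_height=256 * g.shape[0])

    def test_all_below_threshold_empty(self):
        seg = threshold_heatmap(self._hm(np.full((4, 4), 0.4)), out_size=64)
        assert seg.binary.sum() == 0

    def test_exact_half_is_foreground(self):
        seg = threshold_heatmap(self._hm([[0.5]]), out_size=8)
        assert np.all(seg.binary == 1)

    def test_zero_threshold_full_frame(self):
        seg = threshold_heatmap(self._hm(np.zeros((2, 2))), t=0.0,
                                out_size=16)
        assert np.all(seg.binary == 1)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_heatmap(self._hm([[0.5]]), t=1.5)

    def test_nearest_neighbour_cell_geometry(self):
        grid = np.array([[1.0, 0.0], [0.0, 1.0]], dtype=np.float32)
        seg = threshold_heatmap(self._hm(grid), out_size=8)
        expect = np.kron(grid >= 0.5, np.ones((4, 4), dtype=bool))
        assert np.array_equal(seg.binary.astype(bool), expect)


class TestOtsuBaseline:
    def test_recovers_synthetic_tissue_region(self, small_cohort):
        from skimage.color import rgb2hsv

        _, wsis, _ = small_cohort
        wsi = wsis[0]
        seg = otsu_baseline(wsi.pyramid, out_size=256)
        full = wsi.pyramid._level_array(0)
        truth = rgb2hsv(full)[..., 1] * 255 > 20
        from histocascade.evaluate import resample_mask

        truth_small = resample_mask(truth.astype(np.uint8), (256, 256))
        disagree = (seg.binary != truth_small).mean()
        assert disagree < 0.01

    def test_otsu_threshold_matches_exhaustive_search(self, rng):
        """Between-class-variance maximization vs a 256-threshold sweep."""
        from skimage.filters import threshold_otsu

        vals = np.concatenate([
            rng.normal(60, 10, 5000), rng.normal(190, 15, 5000)
        ])
        img = np.clip(vals, 0, 255).astype(np.uint8)
        t_lib = threshold_otsu(img, nbins=256)

        hist = np.bincount(img, minlength=256).astype(float)
        p = hist / hist.sum()
        best_t, best_v = 0, -1.0
        for t in range(255):
            w0 = p[: t + 1].sum()
            w1 = 1 - w0
            if w0 == 0 or w1 == 0:
                continue
            mu0 = (np.arange(t + 1) * p[: t + 1]).sum() / w0
            mu1 = (np.arange(t + 1, 256) * p[t + 1:]).sum() / w1
            v = w0 * w1 * (mu0 - mu1) ** 2
            if v > best_v:
                best_v, best_t = v, t
        assert abs(float(t_lib) - best_t) <= 1

    def test_two_delta_histogram_separates_classes(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[:32] = 10
        img[32:] = 200
        from skimage.filters import threshold_otsu

        t = threshold_otsu(img, nbins=256)
        assert 10 <= t < 200
        assert np.array_equal(img > t, img == 200)

    def test_constant_image_empty_mask(self, tmp_path):
        img = np.full((512, 512, 3), 200, dtype=np.uint8)
        path = tmp_path / "c.tiff"
        write_pyramid(img, 256, 1, path, base_magnification=100.0)
        seg = otsu_baseline(open_pyramid(path), out_size=64)
        assert seg.binary.sum() == 0


@pytest.fixture(scope="module")
def trained_pair():
    """A tiny refiner trained to pass the heatmap channel through."""
    from histocascade.models import RefinerSpec
    from histocascade.train import AugmentConfig, TrainConfig, train_refiner

    rng = np.random.default_rng(0)
    triples = []
    for _ in range(8):
        gt = np.zeros((64, 64), dtype=np.float32)
        r0, c0 = rng.integers(8, 32, 2)
        h, w = rng.integers(16, 32, 2)
        gt[r0:r0 + h, c0:c0 + w] = 1
        img = np.repeat(
            np.where(gt[..., None] > 0, 0.55, 0.95), 3, axis=-1
        ).astype(np.float32)
        hm = np.clip(gt + rng.normal(0, 0.15, gt.shape), 0, 1)
        triples.append((img, hm.astype(np.float32), gt))
    spec = RefinerSpec(input_size=64, depth=4, filters=(4, 8, 8, 16), seed=1)
    cfg = TrainConfig(lr=1e-3, epochs=60, batch_size=4,
                      early_stop_patience=15, seed=1, loss="dice",
                      aug=AugmentConfig(operators=("flip",)))
    model, history = train_refiner(triples[:6], triples[6:], spec, cfg)
    return model, history


class TestCascade:
    def test_refiner_learns_identity_like_mapping(self, trained_pair):
        from histocascade.train import soft_dice_loss

        model, history = trained_pair
        rng = np.random.default_rng(42)
        gt = np.zeros((64, 64), dtype=np.float32)
        gt[20:44, 12:40] = 1
        img = np.where(gt[..., None] > 0, [0.55, 0.55, 0.55],
                       [0.95, 0.95, 0.95]).astype(np.float32)
        hm = np.clip(gt + rng.normal(0, 0.15, gt.shape), 0, 1)
        x = np.concatenate([img, hm[..., None]], -1)[None].astype(np.float32)
        probs = model.forward_probs(x)
        pred = probs[0, :, :, 1] >= 0.5
        inter = (pred & (gt > 0)).sum()
        dice = 2 * inter / (pred.sum() + gt.sum())
        assert dice > 0.9

    def test_history_and_early_stop_contract(self, trained_pair):
        _, history = trained_pair
        assert len(history) <= 60
        assert {"epoch", "train_loss", "val_loss"} <= set(history.columns)

    def test_zero_heatmap_negative_image_near_empty(self, trained_pair):
        model, _ = trained_pair
        img = np.full((64, 64, 3), 0.95, dtype=np.float32)  # background-only
        hm = np.zeros((64, 64), dtype=np.float32)
        x = np.concatenate([img, hm[..., None]], -1)[None]
        probs = model.forward_probs(x.astype(np.float32))
        assert (probs[0, :, :, 1] >= 0.5).mean() < 0.05

    def test_run_cascade_composition_bitwise(self, tmp_path, cellcoded_wsi):
        """run_cascade == detect_tissue -> predict_heatmap ->
        refine_segmentation, bit for bit."""
        from histocascade.models import RefinerSpec, build_refiner

        ref = build_refiner(RefinerSpec(input_size=64, depth=4,
                                        filters=(4, 8, 8, 16), seed=5))
        table = {16 * k + 1: (k % 3) / 2 for k in range(16)}
        clf = _StubClassifier(table)
        result = run_cascade(cellcoded_wsi, clf, ref)
        tissue = detect_tissue(cellcoded_wsi)
        hm = predict_heatmap(cellcoded_wsi, clf, tissue)
        direct = refine_segmentation(cellcoded_wsi, hm, ref)
        assert np.array_equal(result.prob, direct.prob)
        assert np.array_equal(result.binary, direct.binary)

    def test_background_only_slide_degenerates_cleanly(self, tmp_path):
        from histocascade.models import RefinerSpec, build_refiner

        img = np.full((1024, 1024, 3), 252, dtype=np.uint8)
        path = tmp_path / "blank.tiff"
        write_pyramid(img, 256, 2, path, base_magnification=100.0)
        pyr = open_pyramid(path)
        tissue = detect_tissue(pyr)
        assert tissue.grid.sum() == 0
        clf = _StubClassifier({})
        hm = predict_heatmap(pyr, clf, tissue)
        assert hm.grid.sum() == 0


def test_geometry_roundtrip_blob_mask_stable():
    """Mapping a blob mask from the segmentation frame to level 0 and back
    changes fewer than 0.5% of pixels."""
    from histocascade.evaluate import resample_mask

    yy, xx = np.mgrid[0:256, 0:256]
    blob = (((yy - 120) / 70.0) ** 2 + ((xx - 140) / 90.0) ** 2 < 1.0)
    blob = blob.astype(np.uint8)
    up = resample_mask(blob, (2048, 2048))
    back = resample_mask(up, (256, 256))
    assert (back != blob).mean() < 0.005
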