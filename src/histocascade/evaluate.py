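"""WSI-wise pixel metrics and cohort aggregation.

Metrics (pixel-wise recall, precision and Dice similarity coefficient) are
computed per slide against the annotation, after nearest-neighbour
resampling of the ground truth to the prediction geometry.  The cohort
report holds the unweighted (macro) mean and population standard deviation
of each metric, overall and per histological grade.

Degenerate conventions (real cohorts never have empty tumor annotations,
but synthetic tests may): empty ground truth with an empty prediction
scores 1 on every metric; empty ground truth with a non-empty prediction
scores recall 1, precision 0, Dice 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WsiMetrics", "CohortReport", "wsi_metrics", "aggregate",
           "resample_mask"]

METRICS = ("recall", "precision", "dsc")


@dataclass(frozen=True)
class WsiMetrics:
    wsi_id: str
    recall: float
    precision: float
    dsc: float
    grade: str


@dataclass
class CohortReport:
    overall: dict[str, tuple[float, float]]
    per_grade: dict[str, dict]
    n_wsi: int

    def to_json(self, path=None) -> str:
        payload = {
            "n_wsi": self.n_wsi,
            "overall": {m: {"mean": v[0], "sd": v[1]}
                        for m, v in self.overall.items()},
            "per_grade": {
                g: {
                    "n": d["n"],
                    **{m: {"mean": d[m][0], "sd": d[m][1]} for m in METRICS},
                }
                for g, d in self.per_grade.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def resample_mask(mask: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resampling of a binary mask (pixel-center rule)."""
    if mask.shape == out_shape:
        return mask.astype(np.uint8, copy=True)
    oh, ow = out_shape
    ys = np.minimum(((np.arange(oh) + 0.5) * mask.shape[0] / oh).astype(int),
                    mask.shape[0] - 1)
    xs = np.minimum(((np.arange(ow) + 0.5) * mask.shape[1] / ow).astype(int),
                    mask.shape[1] - 1)
    return mask[np.ix_(ys, xs)].astype(np.uint8)


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if not np.all(np.isin(np.unique(a), (0, 1))):
        raise TypeError(f"{name} mask must be binary {{0,1}}")
    return a.astype(bool)


def wsi_metrics(pred_mask: np.ndarray, gt_mask: np.ndarray,
                wsi_id: str = "", grade: str = "?") -> WsiMetrics:
    """Pixel-wise recall, precision and DSC for one slide."""
    pred = _check_binary(pred_mask, "prediction")
    gt = _check_binary(gt_mask, "ground-truth")
    if gt.shape != pred.shape:
        gt = resample_mask(gt.astype(np.uint8), pred.shape).astype(bool)
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    if tp + fn == 0:  # empty ground truth
        recall = 1.0
        precision = 1.0 if fp == 0 else 0.0
        dsc = 1.0 if fp == 0 else 0.0
    else:
        recall = tp / (tp + fn)
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        dsc = 2 * tp / (2 * tp + fp + fn)
    return WsiMetrics(wsi_id=wsi_id, recall=recall, precision=precision,
                      dsc=dsc, grade=grade)


def aggregate(metrics: list[WsiMetrics]) -> CohortReport:
    """Macro mean and population SD per metric, overall and per grade."""
    if not metrics:
        raise ValueError("cannot aggregate an empty metric list")
    df = pd.DataFrame([m.__dict__ for m in metrics])

    def _stats(sub: pd.DataFrame) -> dict[str, tuple[float, float]]:
        return {
            m: (float(sub[m].mean()), float(sub[m].std(ddof=0)))
            for m in METRICS
        }

    per_grade = {}
    for g, sub in df.groupby("grade"):
        per_grade[g] = {"n": int(len(sub)), **_stats(sub)}
    return CohortReport(overall=_stats(df), per_grade=per_grade,
                        n_wsi=int(len(df)))
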