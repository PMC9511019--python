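"""Evaluation metrics: PSNR, SSIM and foreground Dice, plus test-set reports.

All image metrics are computed on the 8-bit quantised [0, 255] scale so that
values match what would be measured on the PNG files on disk.  Mask PSNR and
SSIM are computed on deterministic fixed-palette renderings of the label
masks (the package's frozen convention for applying image metrics to
categorical data).  Dice is micro-averaged over the leaf classes, excluding
background, and reported on a 0–100 scale; the image-row and mask-row Dice
columns of a report are by construction the same mask-derived value.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity as _sk_ssim

from .core_types import (
    InstanceMask,
    PlantRecord,
    RGBFrame,
    mask_to_palette_image,
    onehot_to_mask,
)
from .dataset_io import DatasetIndex, make_windows

logger = logging.getLogger(__name__)

PSNR_CAP_DB = 100.0  # reported value for identical images (zero MSE)


def _to_255(frame: RGBFrame) -> np.ndarray:
    # frames loaded from PNG are exact multiples of 1/255, so this is the
    # 8-bit scale without introducing extra quantisation for in-memory data
    return frame.pixels.astype(np.float64) * 255.0


def psnr(a: RGBFrame, b: RGBFrame) -> float:
    """10*log10(255^2 / MSE) on the [0,255] scale; identical images return the cap."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(f"shape mismatch {a.pixels.shape} vs {b.pixels.shape}")
    mse = float(np.mean((_to_255(a) - _to_255(b)) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(10.0 * np.log10(255.0**2 / mse), PSNR_CAP_DB)


def ssim(a: RGBFrame, b: RGBFrame) -> float:
    """Mean SSIM (Gaussian window 11, sigma 1.5, L=255), averaged over channels."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(f"shape mismatch {a.pixels.shape} vs {b.pixels.shape}")
    if min(a.height, a.width) < 11:
        raise ValueError("image smaller than the 11-pixel SSIM window")
    return float(
        _sk_ssim(
            _to_255(a),
            _to_255(b),
            channel_axis=2,
            data_range=255.0,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
        )
    )


def dice_foreground(pred: InstanceMask, gt: InstanceMask) -> float:
    """Micro-averaged Dice over leaf classes 1..C-1, in [0, 100].

    Background is excluded: predicted leaves matter more than the (large)
    background region.  If neither mask contains any leaf pixel the overlap
    is vacuously perfect and 100 is returned with a logged notice.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    if pred.n_classes != gt.n_classes:
        raise ValueError("masks have different class counts")
    inter = 0
    total = 0
    for k in range(1, gt.n_classes):
        pk = pred.labels == k
        gk = gt.labels == k
        inter += int(np.sum(pk & gk))
        total += int(np.sum(pk)) + int(np.sum(gk))
    if total == 0:
        logger.info("dice_foreground: both masks are entirely background")
        return 100.0
    return 100.0 * 2.0 * inter / total


_METRIC_KEYS = ("i_psnr", "i_ssim", "i_dice", "m_psnr", "m_ssim", "m_dice")


@dataclass
class MetricsReport:
    """Per-frame and aggregate metrics for one (p, q) evaluation protocol."""

    protocol: tuple[int, int]
    n_samples: int
    per_sample: list[dict] = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "protocol": f"{self.protocol[0]}to{self.protocol[1]}",
                    "n_samples": self.n_samples,
                    "aggregate": self.aggregate,
                    "per_sample": self.per_sample,
                },
                indent=1,
            )
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["row", "record", "start", "frame", *_METRIC_KEYS])
            for s in self.per_sample:
                writer.writerow(
                    ["sample", s["record"], s["start"], s["frame"]]
                    + [f"{s[k]:.6g}" for k in _METRIC_KEYS]
                )
            writer.writerow(
                ["aggregate", "", "", ""] + [f"{self.aggregate[k]:.6g}" for k in _METRIC_KEYS]
            )


def evaluate_frame(pred_rgb: RGBFrame, pred_mask: InstanceMask,
                   gt_rgb: RGBFrame, gt_mask: InstanceMask) -> dict:
    """All six metrics for one predicted frame against its ground truth."""
    d = dice_foreground(pred_mask, gt_mask)
    return {
        "i_psnr": psnr(pred_rgb, gt_rgb),
        "i_ssim": ssim(pred_rgb, gt_rgb),
        "i_dice": d,
        "m_psnr": psnr(mask_to_palette_image(pred_mask), mask_to_palette_image(gt_mask)),
        "m_ssim": ssim(mask_to_palette_image(pred_mask), mask_to_palette_image(gt_mask)),
        "m_dice": d,
    }


def evaluate(model, index: DatasetIndex | list[PlantRecord], p: int, q: int,
             stride: int = 1) -> MetricsReport:
    """Evaluate a model over all (p, q) windows of the test records.

    ``model`` is anything exposing ``predict_sequence(x_hist, m_hist, q)``;
    aggregates are means over all predicted frames of all windows.
    """
    records = index.test_records() if isinstance(index, DatasetIndex) else list(index)
    windows = [w for rec in records for w in make_windows(rec, p, q, stride)]
    if not windows:
        raise ValueError(f"no test windows available for protocol {p}to{q}")
    per_sample = []
    for w in windows:
        x_hist = [rgb for rgb, _ in w.inputs]
        m_hist = [m for _, m in w.inputs]
        pred_rgbs, pred_softs = model.predict_sequence(x_hist, m_hist, q)
        for j, (soft, (gt_rgb, gt_mask)) in enumerate(zip(pred_softs, w.targets)):
            pred_mask = onehot_to_mask(soft, n_classes=gt_mask.n_classes)
            row = evaluate_frame(pred_rgbs[j], pred_mask, gt_rgb, gt_mask)
            rid = w.source_record.record_id if w.source_record else "?"
            per_sample.append({"record": rid, "start": w.start, "frame": j, **row})
    aggregate = {k: float(np.mean([s[k] for s in per_sample])) for k in _METRIC_KEYS}
    return MetricsReport(
        protocol=(p, q), n_samples=len(windows), per_sample=per_sample, aggregate=aggregate
    )


class GroundTruthOracle:
    """A 'model' that returns the ground truth — the analytic metric optimum.

    Used to validate the evaluation pipeline: feeding it through
    :func:`evaluate` must yield the PSNR cap, SSIM 1 and Dice 100.
    """

    def __init__(self, record: PlantRecord, p: int):
        self.record = record
        self.p = p

    def predict_sequence(self, x_hist, m_hist, q):
        # locate the window by matching the last input frame
        from .core_types import SoftMask, mask_to_onehot

        for start in range(self.record.n_frames - self.p - q + 1):
            last = self.record.frames[start + self.p - 1][0]
            if np.array_equal(last.pixels, x_hist[-1].pixels):
                targets = self.record.frames[start + self.p : start + self.p + q]
                return (
                    [rgb for rgb, _ in targets],
                    [mask_to_onehot(m) for _, m in targets],
                )
        raise ValueError("window not found in oracle record")
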