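"""Reading/writing time-series plant directories and windowing for training.

Canonical on-disk layout, one directory per plant/viewpoint::

    <dir>/rgb_000.png    8-bit RGB
    <dir>/label_000.png  8-bit single-channel, pixel value = leaf label

Other naming schemes (e.g. the public komatsuna archives) can be adapted via
the ``rgb_glob``/``label_glob`` arguments; frames are always paired by the
numeric index embedded in the file name.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import rotate as _sk_rotate

from .core_types import InstanceMask, PlantRecord, RGBFrame, SequenceSample

_NUM = re.compile(r"(\d+)")


def _index_of(path: Path) -> int:
    m = _NUM.findall(path.stem)
    if not m:
        raise ValueError(f"no numeric index in file name {path.name}")
    return int(m[-1])


def save_plant_record(record: PlantRecord, dir_path: str | Path) -> None:
    """Write a record as paired rgb_%03d.png / label_%03d.png files.

    Masks are lossless; RGB is quantised to 8 bit (round(value*255)).
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    for i, (rgb, mask) in enumerate(record.frames):
        rgb8 = np.round(rgb.pixels * 255.0).astype(np.uint8)
        Image.fromarray(rgb8, mode="RGB").save(dir_path / f"rgb_{i:03d}.png")
        lab8 = mask.labels.astype(np.uint8)
        Image.fromarray(lab8, mode="L").save(dir_path / f"label_{i:03d}.png")
    meta = {
        "plant_id": record.plant_id,
        "viewpoint": record.viewpoint,
        "time_step_hours": record.time_step_hours,
        "n_classes": record.n_classes,
    }
    (dir_path / "record.json").write_text(json.dumps(meta, indent=1))


def load_plant_record(
    dir_path: str | Path,
    n_classes: int = 9,
    rgb_glob: str = "rgb_*.png",
    label_glob: str = "label_*.png",
    plant_id: str | None = None,
    viewpoint: str = "vp0",
) -> PlantRecord:
    """Load a record directory; frames sorted by the numeric file index."""
    dir_path = Path(dir_path)
    rgbs = {_index_of(p): p for p in dir_path.glob(rgb_glob)}
    labels = {_index_of(p): p for p in dir_path.glob(label_glob)}
    unmatched = sorted(set(rgbs) ^ set(labels))
    if not rgbs and not labels:
        raise FileNotFoundError(f"no frames found in {dir_path}")
    if unmatched:
        raise ValueError(f"unpaired frame indices in {dir_path}: {unmatched}")
    meta_path = dir_path / "record.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    frames = []
    for idx in sorted(rgbs):
        rgb = np.asarray(Image.open(rgbs[idx]).convert("RGB"), dtype=np.float32) / 255.0
        lab = np.asarray(Image.open(labels[idx]).convert("L"), dtype=np.int64)
        if rgb.shape[:2] != lab.shape:
            raise ValueError(f"frame {idx}: RGB {rgb.shape[:2]} vs mask {lab.shape}")
        frames.append((RGBFrame(rgb), InstanceMask(lab, n_classes=meta.get("n_classes", n_classes))))
    return PlantRecord(
        plant_id=plant_id or meta.get("plant_id", dir_path.name),
        viewpoint=meta.get("viewpoint", viewpoint),
        frames=frames,
        time_step_hours=meta.get("time_step_hours", 4.0),
    )


def make_windows(record: PlantRecord, p: int, q: int, stride: int = 1) -> list[SequenceSample]:
    """Cut all (p input, q target) windows of consecutive frames."""
    if p < 1 or q < 1 or stride < 1:
        raise ValueError("p, q and stride must be >= 1")
    span = p + q
    windows = []
    for start in range(0, record.n_frames - span + 1, stride):
        windows.append(
            SequenceSample(
                inputs=record.frames[start : start + p],
                targets=record.frames[start + p : start + span],
                source_record=record,
                start=start,
            )
        )
    return windows


@dataclass
class DatasetIndex:
    """Plant-level train/test split over a set of records."""

    records: dict[str, PlantRecord]
    split: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for rid, s in self.split.items():
            if s not in ("train", "test"):
                raise ValueError(f"split for {rid} must be 'train' or 'test', got {s!r}")
            if rid not in self.records:
                raise KeyError(f"split references unknown record {rid}")

    def train_records(self) -> list[PlantRecord]:
        return [self.records[r] for r in sorted(self.records) if self.split.get(r) == "train"]

    def test_records(self) -> list[PlantRecord]:
        return [self.records[r] for r in sorted(self.records) if self.split.get(r) == "test"]

    def add_training_records(self, new: list[PlantRecord]) -> None:
        """Merge extra (e.g. augmented) records into the training split only."""
        for rec in new:
            rid = rec.record_id
            if rid in self.records:
                raise ValueError(f"duplicate record id {rid}")
            self.records[rid] = rec
            self.split[rid] = "train"

    def assert_no_leak(self, windows: list[SequenceSample]) -> None:
        test_ids = {id(self.records[r]) for r, s in self.split.items() if s == "test"}
        for w in windows:
            if w.source_record is not None and id(w.source_record) in test_ids:
                raise AssertionError("training window drawn from a test plant")

    def save_split(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.split, indent=1, sort_keys=True))

    @staticmethod
    def load_split(path: str | Path) -> dict[str, str]:
        return json.loads(Path(path).read_text())


def split_records(
    records: list[PlantRecord],
    test_fraction: float | None = None,
    train_ids: list[str] | None = None,
    test_ids: list[str] | None = None,
    seed: int = 0,
) -> DatasetIndex:
    """Split records at the plant level, by explicit id lists or a fraction.

    With ``test_fraction`` the test size is ``floor(f * n)`` after a seeded
    shuffle, but at least one test record when ``f > 0`` and ``n >= 2``.
    """
    by_id = {r.record_id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate record ids")
    if train_ids is not None or test_ids is not None:
        train_ids = list(train_ids or [])
        test_ids = list(test_ids or [])
        overlap = set(train_ids) & set(test_ids)
        if overlap:
            raise ValueError(f"records in both splits: {sorted(overlap)}")
        split = {rid: "train" for rid in train_ids}
        split.update({rid: "test" for rid in test_ids})
        return DatasetIndex(records=by_id, split=split)
    if test_fraction is None:
        raise ValueError("provide test_fraction or explicit id lists")
    ids = sorted(by_id)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_test = int(np.floor(test_fraction * len(ids)))
    if test_fraction > 0 and n_test == 0 and len(ids) >= 2:
        n_test = 1
    split = {rid: ("test" if i < n_test else "train") for i, rid in enumerate(ids)}
    return DatasetIndex(records=by_id, split=split)


def rotate_record(record: PlantRecord, angle_deg: float, suffix: str = "rot") -> PlantRecord:
    """Rotate every frame of a record by the same angle (offline augmentation).

    The same angle is applied to all frames so the time series stays
    consistent; masks use nearest-neighbour interpolation, RGB bilinear.
    """
    frames = []
    for rgb, mask in record.frames:
        r = _sk_rotate(rgb.pixels, angle_deg, order=1, mode="edge", preserve_range=True)
        m = _sk_rotate(
            mask.labels.astype(np.float64), angle_deg, order=0, mode="constant",
            cval=0, preserve_range=True,
        )
        frames.append(
            (RGBFrame(np.clip(r, 0, 1)), InstanceMask(m.astype(np.int64), mask.n_classes))
        )
    return PlantRecord(
        plant_id=f"{record.plant_id}_{suffix}{angle_deg:.0f}",
        viewpoint=record.viewpoint,
        frames=frames,
        time_step_hours=record.time_step_hours,
    )
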