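"""Time-series data augmentation: temporal mixup and temporal copy-paste.

Two augmentations designed for growth sequences:

* **T-Mixup** blends each frame of a window with its temporal successor by a
  single shared ratio ``lam``, producing a temporally consistent pseudo
  sequence of intermediate growth states (``x_new = lam*x_t + (1-lam)*x_{t+1}``,
  same for the masks mixed in one-hot probability space).  Blended frames look
  unnatural, so they are used only to pre-train the model.
* **T-Copy-Paste** builds whole new plants offline: per-leaf time-series
  tracks are extracted from existing records, filtered to drop leaves that are
  ever occluded, split or clipped, and then pasted — one rotation and scale
  per track, one shared background per plant — onto a clean background in
  emergence order, so that the composed record obeys the same label and
  occlusion conventions as real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.transform import rescale as _sk_rescale
from skimage.transform import rotate as _sk_rotate

from .core_types import (
    InstanceMask,
    PlantRecord,
    RGBFrame,
    SequenceSample,
    SoftMask,
    mask_to_onehot,
)

logger = logging.getLogger(__name__)


@dataclass
class MixupLambda:
    lam: float

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"mixup ratio must be in [0,1], got {self.lam}")


def _as_lam(lam) -> float:
    return lam.lam if isinstance(lam, MixupLambda) else MixupLambda(float(lam)).lam


def tmixup_frames(
    frame_a: tuple[RGBFrame, SoftMask],
    frame_b: tuple[RGBFrame, SoftMask],
    lam: float | MixupLambda,
) -> tuple[RGBFrame, SoftMask]:
    """Convex per-pixel combination of two frames and their soft masks."""
    lam = _as_lam(lam)
    rgb_a, soft_a = frame_a
    rgb_b, soft_b = frame_b
    if rgb_a.pixels.shape != rgb_b.pixels.shape or soft_a.probs.shape != soft_b.probs.shape:
        raise ValueError("frame shapes must match for mixup")
    rgb = lam * rgb_a.pixels + (1.0 - lam) * rgb_b.pixels
    probs = lam * soft_a.probs + (1.0 - lam) * soft_b.probs
    return RGBFrame(rgb), SoftMask(probs)


def tmixup_window(
    sample: SequenceSample,
    lam: float | MixupLambda | None = None,
    rng: np.random.Generator | None = None,
) -> SequenceSample | None:
    """Mix every frame of a window with its successor using one shared ratio.

    Returns a pseudo window whose mask entries are :class:`SoftMask` (mixing
    integer labels is meaningless, so masks are mixed in probability space).
    Windows ending at the last frame of their record have no successor and are
    skipped (returns ``None`` with a logged notice).
    """
    if sample.source_record is None:
        raise ValueError("window carries no source record reference")
    if lam is None:
        rng = rng or np.random.default_rng(0)
        lam = float(rng.uniform(0.0, 1.0))
    lam = _as_lam(lam)
    record = sample.source_record
    end = sample.start + sample.p + sample.q  # index of the successor of the last frame
    if end >= record.n_frames:
        logger.info(
            "T-Mixup skipped window at frame %d of %s: no successor frame",
            sample.start, record.record_id,
        )
        return None

    def mixed(t: int) -> tuple[RGBFrame, SoftMask]:
        rgb_t, m_t = record.frames[t]
        rgb_n, m_n = record.frames[t + 1]
        return tmixup_frames(
            (rgb_t, mask_to_onehot(m_t)), (rgb_n, mask_to_onehot(m_n)), lam
        )

    inputs = [mixed(sample.start + i) for i in range(sample.p)]
    targets = [mixed(sample.start + sample.p + j) for j in range(sample.q)]
    return SequenceSample(inputs=inputs, targets=targets, source_record=record, start=sample.start)


# ------------------------------------------------------------- leaf tracks
@dataclass
class LeafEntry:
    """One frame of a leaf track: bounding box and 1-px padded patches."""

    frame: int
    bbox: tuple[int, int, int, int] | None  # r0, c0, r1, c1 inclusive; None if invisible
    rgb: np.ndarray | None                  # (h+2, w+2, 3)
    mask: np.ndarray | None                 # (h+2, w+2) bool

    @property
    def area(self) -> int:
        return 0 if self.mask is None else int(self.mask.sum())


@dataclass
class LeafTrack:
    """One leaf's per-frame appearance from emergence to the last frame."""

    source_record_id: str
    label: int
    first_frame: int
    entries: list[LeafEntry]
    image_size: tuple[int, int]
    transform: tuple[float, float] = (0.0, 1.0)  # (rotation deg, scale)

    def __len__(self) -> int:
        return len(self.entries)


def extract_leaf_tracks(record: PlantRecord) -> list[LeafTrack]:
    """One candidate track per leaf label present in the record.

    Entries run contiguously from the leaf's emergence frame to the record's
    last frame; frames where the leaf is fully occluded get an empty entry
    (these tracks are dropped by :func:`filter_leaf_tracks`).
    """
    tracks = []
    for lab in range(1, record.n_classes):
        emerge = record.emergence_frame(lab)
        if emerge is None:
            continue
        entries = []
        for t in range(emerge, record.n_frames):
            rgb, mask = record.frames[t]
            where = mask.labels == lab
            if not where.any():
                entries.append(LeafEntry(frame=t, bbox=None, rgb=None, mask=None))
                continue
            rows = np.flatnonzero(where.any(axis=1))
            cols = np.flatnonzero(where.any(axis=0))
            r0, r1, c0, c1 = rows[0], rows[-1], cols[0], cols[-1]
            m = where[r0 : r1 + 1, c0 : c1 + 1]
            patch = rgb.pixels[r0 : r1 + 1, c0 : c1 + 1].copy()
            patch[~m] = 0.0
            # pad by one pixel so the mask never touches the patch border
            m = np.pad(m, 1)
            patch = np.pad(patch, ((1, 1), (1, 1), (0, 0)))
            entries.append(
                LeafEntry(frame=t, bbox=(int(r0), int(c0), int(r1), int(c1)), rgb=patch, mask=m)
            )
        tracks.append(
            LeafTrack(
                source_record_id=record.record_id,
                label=lab,
                first_frame=emerge,
                entries=entries,
                image_size=record.image_size,
            )
        )
    return tracks


def filter_leaf_tracks(
    tracks: list[LeafTrack],
    occlusion_threshold: float = 0.9,
    require_connected: bool = True,
) -> list[LeafTrack]:
    """Keep only tracks usable for copy-paste.

    A track survives when, in every frame from emergence on, the leaf's
    visible mask (a) is a single 8-connected component that never vanishes,
    (b) does not touch the image border (leaves clipped by the frame cannot
    be recovered), and (c) keeps at least ``occlusion_threshold`` times its
    maximum area so far (partial occlusion by newer leaves).  Conditions (a)
    and (b) are controlled by ``require_connected``; ``occlusion_threshold=0``
    with ``require_connected=False`` keeps everything.
    """
    kept = []
    for track in tracks:
        h, w = track.image_size
        ok = True
        running_max = 0
        for entry in track.entries:
            area = entry.area
            if area == 0:
                if require_connected or occlusion_threshold > 0:
                    ok = False
                    break
                continue
            if require_connected:
                n_comp = cc_label(entry.mask, connectivity=2).max()
                r0, c0, r1, c1 = entry.bbox
                touches = r0 == 0 or c0 == 0 or r1 == h - 1 or c1 == w - 1
                if n_comp != 1 or touches:
                    ok = False
                    break
            running_max = max(running_max, area)
            if area < occlusion_threshold * running_max:
                ok = False
                break
        if ok:
            kept.append(track)
    return kept


# -------------------------------------------------------------- composition
class PlacementError(ValueError):
    """A pasted leaf would fall outside the image."""


def _transform_patch(rgb: np.ndarray, mask: np.ndarray, rot_deg: float, scale: float):
    """Rotate then rescale a padded patch; crop back to the tight mask bbox."""
    if rot_deg:
        rgb = _sk_rotate(rgb, rot_deg, resize=True, order=1, mode="constant", cval=0.0)
        mask = _sk_rotate(mask.astype(np.float64), rot_deg, resize=True, order=0,
                          mode="constant", cval=0.0) > 0.5
    if scale != 1.0:
        rgb = _sk_rescale(rgb, scale, order=1, mode="constant", cval=0.0, channel_axis=2)
        mask = _sk_rescale(mask.astype(np.float64), scale, order=0, mode="constant",
                           cval=0.0) > 0.5
    if not mask.any():
        return None, None
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return np.clip(rgb[sl], 0, 1), mask[sl]


def compose_plant(
    background: RGBFrame,
    tracks: list[LeafTrack],
    placements: list[tuple[int, int]] | None = None,
    rng_seed: int = 0,
    n_frames: int | None = None,
    emergence_frames: list[int] | None = None,
    rotation_range: tuple[float, float] = (0.0, 360.0),
    scale_range: tuple[float, float] = (0.8, 1.2),
    plant_id: str = "aug",
    viewpoint: str = "vp0",
    n_classes: int = 9,
) -> PlantRecord:
    """Compose a new plant record from a background and filtered leaf tracks.

    One background is shared by all frames; each track receives ONE rotation
    and ONE scale applied to all its frames (temporal consistency).  Tracks
    are pasted in emergence order; track ``j`` (0-based paste order) gets
    label ``j+1`` and later tracks sit on top of earlier ones.  Deterministic
    given ``rng_seed``.
    """
    if not 1 <= len(tracks) <= n_classes - 1:
        raise ValueError(f"need 1..{n_classes - 1} tracks, got {len(tracks)}")
    for track in tracks:
        if any(e.mask is None for e in track.entries):
            raise ValueError(
                f"track {track.source_record_id}/leaf{track.label} has occluded frames; "
                "filter tracks before composing"
            )
    rng = np.random.default_rng(rng_seed)
    size_h, size_w = background.pixels.shape[:2]
    if n_frames is None:
        n_frames = max(len(t) for t in tracks)

    if emergence_frames is None:
        emergence = sorted(int(e) for e in rng.integers(0, max(1, n_frames // 2), len(tracks)))
    else:
        if len(emergence_frames) != len(tracks):
            raise ValueError("one emergence frame per track required")
        emergence = list(emergence_frames)
        if emergence != sorted(emergence):
            raise ValueError("emergence frames must be sorted (labels follow emergence order)")
    if max(emergence) >= n_frames:
        raise ValueError("emergence beyond the last output frame")

    # one rotation/scale per track, transformed once up front
    transformed: list[list[tuple[np.ndarray, np.ndarray]]] = []
    used_tracks = []
    for track in tracks:
        rot = float(rng.uniform(*rotation_range))
        scale = float(rng.uniform(*scale_range))
        patches = []
        for entry in track.entries:
            trg, tm = _transform_patch(entry.rgb, entry.mask, rot, scale)
            if trg is None:
                raise ValueError("leaf vanished under transform (scale too small)")
            patches.append((trg, tm))
        transformed.append(patches)
        t2 = LeafTrack(track.source_record_id, track.label, track.first_frame,
                       track.entries, track.image_size, transform=(rot, scale))
        used_tracks.append(t2)

    # placement: centre of the largest (last) patch must fit inside the image
    centers = []
    for j, patches in enumerate(transformed):
        ph, pw = patches[-1][1].shape
        if ph > size_h or pw > size_w:
            raise PlacementError(f"track {j}: transformed leaf larger than the image")
        if placements is None:
            r = int(rng.integers(ph // 2 + 1, size_h - (ph - ph // 2)))
            c = int(rng.integers(pw // 2 + 1, size_w - (pw - pw // 2)))
        else:
            r, c = placements[j]
            if not (ph // 2 <= r <= size_h - 1 - (ph - ph // 2 - 1)) or not (
                pw // 2 <= c <= size_w - 1 - (pw - pw // 2 - 1)
            ):
                raise PlacementError(f"track {j}: placement ({r},{c}) puts the leaf outside")
        centers.append((r, c))

    frames = []
    for t in range(n_frames):
        rgb = background.pixels.copy()
        mask = np.zeros((size_h, size_w), dtype=np.int64)
        for j, (patches, e) in enumerate(zip(transformed, emergence)):
            if t < e:
                continue
            idx = min(t - e, len(patches) - 1)
            prgb, pm = patches[idx]
            ph, pw = pm.shape
            r, c = centers[j]
            r0, c0 = r - ph // 2, c - pw // 2
            if r0 < 0 or c0 < 0 or r0 + ph > size_h or c0 + pw > size_w:
                raise PlacementError(f"track {j}: frame {t} leaf outside the image")
            region_rgb = rgb[r0 : r0 + ph, c0 : c0 + pw]
            region_rgb[pm] = prgb[pm]
            mask[r0 : r0 + ph, c0 : c0 + pw][pm] = j + 1
        frames.append((RGBFrame(rgb), InstanceMask(mask, n_classes=n_classes)))

    rec = PlantRecord(plant_id=plant_id, viewpoint=viewpoint, frames=frames)
    rec.tracks_used = used_tracks  # provenance for manifests
    rec.emergence_used = emergence
    return rec


def generate_augmented_dataset(
    records: list[PlantRecord],
    backgrounds: list[RGBFrame],
    n_new_plants: int = 40,
    rng_seed: int = 0,
    occlusion_threshold: float = 0.9,
    n_frames: int | None = None,
    rotation_range: tuple[float, float] = (0.0, 360.0),
    scale_range: tuple[float, float] = (0.8, 1.2),
    max_leaves: int = 8,
) -> list[PlantRecord]:
    """Offline copy-paste augmentation: build ``n_new_plants`` new records.

    Each new plant samples one background, 1..``max_leaves`` filtered tracks
    (with replacement) and composes them; defaults follow the study protocol
    of 40 augmented plants.
    """
    if not records or not backgrounds:
        raise ValueError("need non-empty record and background sets")
    tracks: list[LeafTrack] = []
    for rec in records:
        tracks.extend(filter_leaf_tracks(extract_leaf_tracks(rec), occlusion_threshold))
    if not tracks:
        raise ValueError("no leaf tracks survive filtering; cannot copy-paste")
    if n_frames is None:
        n_frames = max(r.n_frames for r in records)  # match the source length
    rng = np.random.default_rng(rng_seed)
    out = []
    for i in range(n_new_plants):
        bg = backgrounds[int(rng.integers(len(backgrounds)))]
        k = int(rng.integers(1, max_leaves + 1))
        chosen = [tracks[int(rng.integers(len(tracks)))] for _ in range(k)]
        for attempt in range(20):
            try:
                rec = compose_plant(
                    bg, chosen,
                    rng_seed=int(rng.integers(2**31)),
                    n_frames=n_frames,
                    rotation_range=rotation_range,
                    scale_range=scale_range,
                    plant_id=f"aug_{i:03d}",
                )
                break
            except (PlacementError, ValueError):
                if attempt == 19:
                    raise
        out.append(rec)
    return out
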