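"""Shared domain types for leaf-level growth prediction.

Conventions used throughout the package:

* RGB pixel values live in ``[0, 1]`` as float32 in memory and as 8-bit PNG on
  disk (conversion is exactly ``value / 255``).
* Instance masks are integer label images; label 0 is background and labels
  ``1..C-1`` are leaves, assigned in order of emergence (a later label never
  appears in an earlier frame than a smaller one).
* The default class count is ``C = 9``: background plus at most eight leaves,
  which is the maximum leaf count of top-view komatsuna rosettes in the
  dataset family this tool targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_CLASSES = 9

#: Frozen rendering palette for label masks: black background plus eight
#: maximally separated saturated hues.  Mask PSNR/SSIM are computed on this
#: rendering, so it must never change between runs.
PALETTE = np.array(
    [
        (0, 0, 0),        # 0 background
        (230, 25, 75),    # 1 red
        (60, 180, 75),    # 2 green
        (0, 130, 200),    # 3 blue
        (255, 225, 25),   # 4 yellow
        (240, 50, 230),   # 5 magenta
        (70, 240, 240),   # 6 cyan
        (245, 130, 48),   # 7 orange
        (145, 30, 180),   # 8 purple
    ],
    dtype=np.uint8,
)


class InvalidLabelError(ValueError):
    """A mask contains a label outside ``[0, C)``."""


@dataclass
class RGBFrame:
    """One RGB image, H×W×3, float values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"RGBFrame expects H×W×3, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("RGBFrame contains non-finite values")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class InstanceMask:
    """Integer label image, H×W; background is 0, leaves 1..C-1."""

    labels: np.ndarray
    n_classes: int = DEFAULT_N_CLASSES

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("InstanceMask labels must be integers")
        if self.labels.ndim != 2:
            raise ValueError(f"InstanceMask expects H×W, got {self.labels.shape}")
        if self.labels.size and self.labels.min() < 0:
            raise InvalidLabelError(f"negative label {int(self.labels.min())}")
        if self.labels.size and self.labels.max() >= self.n_classes:
            raise InvalidLabelError(
                f"label {int(self.labels.max())} >= n_classes {self.n_classes}"
            )
        self.labels = self.labels.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class SoftMask:
    """Per-pixel class probability map, H×W×C (channel sums 1)."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 3:
            raise ValueError(f"SoftMask expects H×W×C, got {self.probs.shape}")
        if self.probs.min() < -1e-5 or self.probs.max() > 1 + 1e-5:
            raise ValueError("SoftMask probabilities outside [0,1]")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("SoftMask channel sums deviate from 1 by more than 1e-5")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[2]


@dataclass
class FeatureMap:
    """Latent per-frame feature at quarter resolution."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMap contains non-finite values")


@dataclass
class PlantRecord:
    """One plant/viewpoint time series of aligned RGB frames and masks."""

    plant_id: str
    viewpoint: str
    frames: list[tuple[RGBFrame, InstanceMask]]
    time_step_hours: float = 4.0

    def __post_init__(self):
        if not self.frames:
            raise ValueError("PlantRecord requires at least one frame")
        h, w = self.frames[0][0].height, self.frames[0][0].width
        c = self.frames[0][1].n_classes
        for i, (rgb, mask) in enumerate(self.frames):
            if (rgb.height, rgb.width) != (h, w) or mask.shape != (h, w):
                raise ValueError(f"frame {i} has inconsistent dimensions")
            if mask.n_classes != c:
                raise ValueError(f"frame {i} has inconsistent class count")
        self._check_emergence_order()

    def _check_emergence_order(self):
        first = {}
        for t, (_, mask) in enumerate(self.frames):
            for lab in np.unique(mask.labels):
                if lab > 0 and lab not in first:
                    first[int(lab)] = t
        labs = sorted(first)
        for a, b in zip(labs, labs[1:]):
            if first[b] < first[a]:
                raise ValueError(
                    f"leaf {b} appears at frame {first[b]}, before leaf {a} "
                    f"(frame {first[a]}): emergence order must follow label order"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_classes(self) -> int:
        return self.frames[0][1].n_classes

    @property
    def image_size(self) -> tuple[int, int]:
        return self.frames[0][0].height, self.frames[0][0].width

    @property
    def record_id(self) -> str:
        return f"{self.plant_id}/{self.viewpoint}"

    def emergence_frame(self, label: int) -> int | None:
        for t, (_, mask) in enumerate(self.frames):
            if np.any(mask.labels == label):
                return t
        return None


@dataclass
class SequenceSample:
    """A (p input, q target) window of consecutive frames cut from a record."""

    inputs: list[tuple[RGBFrame, InstanceMask]]
    targets: list[tuple[RGBFrame, InstanceMask]]
    source_record: PlantRecord | None = field(default=None, repr=False)
    start: int = 0

    def __post_init__(self):
        if not self.inputs or not self.targets:
            raise ValueError("SequenceSample requires p>=1 inputs and q>=1 targets")

    @property
    def p(self) -> int:
        return len(self.inputs)

    @property
    def q(self) -> int:
        return len(self.targets)


# ----------------------------------------------------------------- operations
def mask_to_onehot(mask: InstanceMask, n_classes: int | None = None) -> SoftMask:
    """One-hot encode a label mask into a SoftMask (H×W×C)."""
    c = n_classes if n_classes is not None else mask.n_classes
    if mask.labels.size and mask.labels.max() >= c:
        raise InvalidLabelError(f"label {int(mask.labels.max())} >= n_classes {c}")
    onehot = np.eye(c, dtype=np.float32)[mask.labels]
    return SoftMask(onehot)


def onehot_to_mask(soft: SoftMask, n_classes: int | None = None) -> InstanceMask:
    """Per-pixel argmax; ties break toward the lowest channel index."""
    if soft.probs.size == 0:
        raise ValueError("empty SoftMask")
    labels = np.argmax(soft.probs, axis=2)  # np.argmax returns first maximum
    c = n_classes if n_classes is not None else soft.n_classes
    return InstanceMask(labels.astype(np.int64), n_classes=c)


def mask_to_palette_image(mask: InstanceMask, palette: np.ndarray = PALETTE) -> RGBFrame:
    """Deterministically render a label mask as an RGB image via a fixed palette."""
    palette = np.asarray(palette, dtype=np.uint8)
    if palette.shape != (mask.n_classes, 3):
        raise ValueError(
            f"palette has {palette.shape[0]} entries, mask has {mask.n_classes} classes"
        )
    if len({tuple(c) for c in palette.tolist()}) != palette.shape[0]:
        raise ValueError("palette colors must be distinct")
    if tuple(palette[0].tolist()) != (0, 0, 0):
        raise ValueError("palette entry 0 (background) must be black")
    return RGBFrame(palette[mask.labels].astype(np.float32) / 255.0)
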