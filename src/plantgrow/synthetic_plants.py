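"""Synthetic growing-rosette sequences with exact ground-truth instance masks.

The generator emulates a top-view komatsuna-style time series: a textured
soil/tray background, leaves emerging one by one in label order around the
plant centre, each leaf an oriented ellipse whose rasterised area grows
monotonically frame over frame, and newer leaves composited on top of older
ones (painter's algorithm, oldest first).  It exists so that every other
module — windowing, augmentation, training, evaluation — is testable without
downloading the real dataset.

Full-scale study conditions: 60 frames per plant (one frame every 4 h), at
most eight leaves, 256×256 images.  Tests use smaller sizes; the defaults
here are the full-scale conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .core_types import InstanceMask, PlantRecord, RGBFrame

_GOLDEN_ANGLE = 137.50776405003785  # degrees; phyllotactic spread of leaf azimuths


@dataclass
class SynthConfig:
    image_size: int = 256
    n_frames: int = 60
    max_leaves: int = 8
    #: frame index at which leaf k (label k) first appears; auto-spread if None
    emergence_frames: list[int] | None = None
    #: per-frame relative growth of leaf radii
    growth_rate: float = 0.04
    #: random offset (pixels) of the plant centre from the image centre
    center_jitter: float = 4.0
    #: size (pixels) of one coarse background texture cell
    background_texture_scale: float = 8.0
    seed: int = 0
    time_step_hours: float = 4.0
    plant_id: str = "synth"
    viewpoint: str = "vp0"

    def __post_init__(self):
        if self.image_size % 4:
            raise ValueError("image_size must be divisible by 4")
        if not 1 <= self.max_leaves <= 8:
            raise ValueError("max_leaves must be in 1..8")
        if self.emergence_frames is None:
            # spread emergences over the first 60% of the sequence
            span = max(1, int(0.6 * self.n_frames))
            self.emergence_frames = [
                int(k * span / self.max_leaves) for k in range(self.max_leaves)
            ]
        if len(self.emergence_frames) != self.max_leaves:
            raise ValueError("emergence_frames must have one entry per leaf")
        if any(b < a for a, b in zip(self.emergence_frames, self.emergence_frames[1:])):
            raise ValueError("emergence_frames must be non-decreasing")
        if max(self.emergence_frames) >= self.n_frames:
            raise ValueError("leaf emergence beyond the last frame")


def generate_background(size: int, texture_scale: float = 8.0, seed: int = 0) -> RGBFrame:
    """Leaf-free textured background (low-frequency noise over soil tones)."""
    if size % 4:
        raise ValueError("size must be divisible by 4")
    rng = np.random.default_rng(seed)
    coarse = max(2, int(size / max(texture_scale, 1.0)))
    base = np.array([0.36, 0.27, 0.20])  # brownish tray/soil tone
    noise = rng.normal(0.0, 0.06, (coarse, coarse, 3))
    tex = resize(noise, (size, size, 3), order=3, mode="reflect", anti_aliasing=False)
    fine = rng.normal(0.0, 0.012, (size, size, 3))
    img = base[None, None, :] + tex + fine
    return RGBFrame(np.clip(img, 0.0, 1.0))


def _leaf_geometry(k: int, size: int, rng: np.random.Generator):
    """Fixed-per-leaf placement: azimuth, centre offset, max radius, color."""
    azim = np.deg2rad(k * _GOLDEN_ANGLE + rng.uniform(-8, 8))
    # leaves sit on a ring around the plant centre; later leaves slightly closer
    margin = size * 0.08
    max_a = size * 0.17  # semi-major axis cap keeps leaves inside the frame
    dist = size * 0.11 + rng.uniform(-1.5, 1.5)
    green = np.array([0.18 + 0.10 * rng.random(), 0.45 + 0.25 * rng.random(), 0.12 + 0.10 * rng.random()])
    return azim, dist, max_a, margin, green


def generate_plant_record(config: SynthConfig) -> PlantRecord:
    """Render a growing rosette; masks agree exactly with the occlusion order."""
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    background = generate_background(
        size, config.background_texture_scale, seed=int(rng.integers(2**31))
    ).pixels
    cy = size / 2 + rng.uniform(-config.center_jitter, config.center_jitter)
    cx = size / 2 + rng.uniform(-config.center_jitter, config.center_jitter)

    leaves = []
    for k in range(1, config.max_leaves + 1):
        azim, dist, max_a, margin, color = _leaf_geometry(k - 1, size, rng)
        a0 = size * 0.035 + rng.uniform(0, size * 0.01)  # initial semi-major axis
        lcy = cy + dist * np.sin(azim)
        lcx = cx + dist * np.cos(azim)
        # cap so the fully grown ellipse stays inside the frame
        cap = min(
            max_a,
            lcy - margin * 0.25, size - 1 - lcy - margin * 0.25,
            lcx - margin * 0.25, size - 1 - lcx - margin * 0.25,
        )
        leaves.append(dict(center=(lcy, lcx), azim=azim, a0=a0, cap=max(cap, a0), color=color))

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    frames = []
    for t in range(config.n_frames):
        rgb = background.copy()
        mask = np.zeros((size, size), dtype=np.int64)
        for k in range(1, config.max_leaves + 1):
            emerge = config.emergence_frames[k - 1]
            if t < emerge:
                continue
            leaf = leaves[k - 1]
            age = t - emerge
            a = min(leaf["a0"] * (1.0 + config.growth_rate) ** age, leaf["cap"])
            b = 0.55 * a
            lcy, lcx = leaf["center"]
            ca, sa = np.cos(leaf["azim"]), np.sin(leaf["azim"])
            u = (xx - lcx) * ca + (yy - lcy) * sa
            v = -(xx - lcx) * sa + (yy - lcy) * ca
            rr = (u / a) ** 2 + (v / b) ** 2
            inside = rr <= 1.0
            # radial colour gradient, brighter at the leaf centre
            shade = (1.0 - 0.35 * np.sqrt(np.clip(rr, 0, 1)))[..., None]
            rgb = np.where(inside[..., None], leaf["color"][None, None, :] * shade, rgb)
            mask[inside] = k  # painter's rule: later labels overwrite
        frames.append((RGBFrame(np.clip(rgb, 0, 1)), InstanceMask(mask, n_classes=9)))

    return PlantRecord(
        plant_id=config.plant_id,
        viewpoint=config.viewpoint,
        frames=frames,
        time_step_hours=config.time_step_hours,
    )


def generate_dataset(
    n_plants: int,
    base_config: SynthConfig | None = None,
    seed: int = 0,
) -> list[PlantRecord]:
    """Generate ``n_plants`` independent records with per-plant seeds."""
    base = base_config or SynthConfig()
    children = np.random.SeedSequence(seed).spawn(n_plants)
    records = []
    for i, child in enumerate(children):
        cfg_kwargs = {f.name: getattr(base, f.name) for f in base.__dataclass_fields__.values()}
        cfg_kwargs["seed"] = int(child.generate_state(1)[0] % (2**31))
        cfg_kwargs["plant_id"] = f"plant_{i:03d}"
        cfg_kwargs["emergence_frames"] = list(base.emergence_frames)
        records.append(generate_plant_record(SynthConfig(**cfg_kwargs)))
    return records
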