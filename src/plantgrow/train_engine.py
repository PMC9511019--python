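"""Training orchestration: optional temporal-mixup pretraining, finetuning on
natural plus copy-paste-augmented sequences, alternating least-squares
generator/discriminator updates.

Protocol defaults follow the study conditions: AdamW at learning rate 1e-4,
200 epochs, batch size 4, 3-frame history predicting 1 future frame, loss
weights (lambda_x, lambda_m, lambda_MAE) = (1.5, 1.0, 100), 40 copy-paste
plants merged into the training split only.  Temporal mixup is applied online
and only during the pretraining phase; finetuning updates all layers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .augmentation import generate_augmented_dataset, tmixup_window
from .core_types import SequenceSample, SoftMask, mask_to_onehot
from .dataset_io import DatasetIndex, make_windows
from .network import (
    GrowthPredictor,
    ModelConfig,
    PatchDiscriminator,
    load_checkpoint,
    save_checkpoint,
)
from .nn import AdamW, Tensor
from .objectives import LossWeights, l_discriminator, l_gan_generator, l_mae, l_mask, l_total
from .synthetic_plants import generate_background

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    epochs: int = 200
    pretrain_epochs: int = 50
    lr: float = 1e-4
    batch_size: int = 4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.01
    p: int = 3
    q: int = 1
    stride: int = 1
    seed: int = 0
    use_tmixup: bool = True
    use_tcopypaste: bool = True
    n_copypaste_plants: int = 40
    weights: LossWeights = field(default_factory=LossWeights)
    disc_base_channels: int | None = None
    checkpoint_every: int = 50

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if isinstance(self.model, dict):
            self.model = ModelConfig(**self.model)
        if isinstance(self.weights, dict):
            self.weights = LossWeights(**self.weights)
        self.betas = tuple(self.betas)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["betas"] = list(self.betas)
        Path(path).write_text(yaml.safe_dump(data))


# ---------------------------------------------------------------- batching
def _to_chw(arr: np.ndarray) -> np.ndarray:
    return arr.transpose(2, 0, 1)


def batch_to_tensors(batch: list[SequenceSample], n_classes: int):
    """Stack a batch of equal-(p,q) windows into per-timestep tensors.

    Returns (x_seq, m_seq, x_targets, m_targets) where mask targets are a
    hard label array (N,H,W) for natural windows or soft probabilities
    (N,C,H,W) for mixed windows.
    """
    p, q = batch[0].p, batch[0].q
    if any(w.p != p or w.q != q for w in batch):
        raise ValueError("all windows in a batch must share (p, q)")

    def soft_probs(m):
        return m.probs if isinstance(m, SoftMask) else mask_to_onehot(m, n_classes).probs

    x_seq = [
        Tensor(np.stack([_to_chw(w.inputs[t][0].pixels) for w in batch]))
        for t in range(p)
    ]
    m_seq = [
        Tensor(np.stack([_to_chw(soft_probs(w.inputs[t][1])) for w in batch]))
        for t in range(p)
    ]
    x_tgt = [
        np.stack([_to_chw(w.targets[j][0].pixels) for w in batch]) for j in range(q)
    ]
    soft_targets = any(isinstance(w.targets[0][1], SoftMask) for w in batch)
    if soft_targets:
        m_tgt = [
            np.stack([_to_chw(soft_probs(w.targets[j][1])) for w in batch])
            for j in range(q)
        ]
    else:
        m_tgt = [np.stack([w.targets[j][1].labels for w in batch]) for j in range(q)]
    return x_seq, m_seq, x_tgt, m_tgt


def train_step(
    model: GrowthPredictor,
    disc: PatchDiscriminator,
    opt_g: AdamW,
    opt_d: AdamW,
    batch: list[SequenceSample],
    weights: LossWeights,
) -> dict[str, float]:
    """One alternating update: discriminator first (on detached generated
    frames), then the generator with the full composite objective."""
    n_classes = model.config.n_classes
    x_seq, m_seq, x_tgt, m_tgt = batch_to_tensors(batch, n_classes)
    q = len(x_tgt)

    images, logits = model(x_seq, m_seq, q)

    # -- discriminator update (generated frames detached) -------------------
    opt_d.zero_grad()
    real_maps = [disc(Tensor(x)) for x in x_tgt]
    fake_maps = [disc(img.detach()) for img in images]
    loss_d = l_discriminator(real_maps, fake_maps)
    if not np.isfinite(loss_d.data):
        raise RuntimeError(f"non-finite discriminator loss: {float(loss_d.data)}")
    loss_d.backward()
    opt_d.step()

    # -- generator update ---------------------------------------------------
    opt_g.zero_grad()
    opt_d.zero_grad()  # discard critic grads accumulated through the gen pass
    gen_maps = [disc(img) for img in images]
    mae = l_mae(images, [Tensor(x) for x in x_tgt])
    gan = l_gan_generator(gen_maps)
    mask = l_mask(logits, m_tgt)
    total, breakdown = l_total(mae, gan, mask, weights)
    if not np.isfinite(total.data):
        raise RuntimeError(f"non-finite generator loss; breakdown: {breakdown}")
    total.backward()
    opt_g.step()
    opt_d.zero_grad()

    breakdown["l_disc"] = float(loss_d.data)
    return breakdown


def _epoch_batches(windows: list[SequenceSample], batch_size: int,
                   rng: np.random.Generator) -> list[list[SequenceSample]]:
    order = rng.permutation(len(windows))
    return [
        [windows[i] for i in order[k : k + batch_size]]
        for k in range(0, len(order), batch_size)
    ]


def pretrain_with_tmixup(
    model: GrowthPredictor,
    disc: PatchDiscriminator,
    opt_g: AdamW,
    opt_d: AdamW,
    windows: list[SequenceSample],
    config: TrainConfig,
    rng: np.random.Generator,
    log_rows: list[dict] | None = None,
) -> int:
    """Pretraining phase: every window is mixed online with its successor
    frames (one uniform ratio per window, soft mask targets).  Returns the
    number of optimisation steps performed."""
    steps = 0
    for epoch in range(config.pretrain_epochs):
        for batch in _epoch_batches(windows, config.batch_size, rng):
            mixed = [tmixup_window(w, lam=float(rng.uniform()), rng=rng) for w in batch]
            mixed = [m for m in mixed if m is not None]
            if not mixed:
                continue
            row = train_step(model, disc, opt_g, opt_d, mixed, config.weights)
            steps += 1
            if log_rows is not None:
                log_rows.append({"phase": "pretrain", "epoch": epoch, "step": steps, **row})
    return steps


@dataclass
class FitResult:
    model: GrowthPredictor
    discriminator: PatchDiscriminator
    history: list[dict]
    checkpoint_path: Path | None


def fit(
    config: TrainConfig,
    index: DatasetIndex,
    out_dir: str | Path | None = None,
    max_steps: int | None = None,
    resume_from: str | Path | None = None,
) -> FitResult:
    """Full training run on the training split of ``index``.

    Copy-paste augmented records (if enabled) are generated from the training
    records only and merged into the training split; a leak check guarantees
    no test-plant frame ever enters a training window.  ``max_steps`` caps
    the number of finetuning steps (for micro-runs); determinism is governed
    by ``config.seed`` alone.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    weight_seed, data_seed, aug_seed, mix_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]

    train_records = index.train_records()
    if not train_records:
        raise ValueError("training split is empty")

    if config.use_tcopypaste:
        size = train_records[0].image_size[0]
        backgrounds = [
            generate_background(size, seed=aug_seed + i) for i in range(5)
        ]
        augmented = generate_augmented_dataset(
            train_records, backgrounds,
            n_new_plants=config.n_copypaste_plants, rng_seed=aug_seed,
        )
        index.add_training_records(augmented)
        train_records = index.train_records()
        logger.info("merged %d copy-paste records into the training split", len(augmented))

    windows = [
        w for rec in train_records for w in make_windows(rec, config.p, config.q, config.stride)
    ]
    if not windows:
        raise ValueError("no training windows for the requested (p, q)")
    index.assert_no_leak(windows)

    model = GrowthPredictor(config.model, seed=weight_seed)
    disc_base = config.disc_base_channels or 2 * config.model.base_channels
    disc = PatchDiscriminator(base_channels=disc_base, seed=weight_seed + 1)
    opt_g = AdamW(model.parameters(), lr=config.lr, betas=config.betas,
                  weight_decay=config.weight_decay)
    opt_d = AdamW(disc.parameters(), lr=config.lr, betas=config.betas,
                  weight_decay=config.weight_decay)

    history: list[dict] = []
    data_rng = np.random.default_rng(data_seed)
    start_epoch, step = 0, 0
    if resume_from is not None:
        prev_model, prev_disc, meta = load_checkpoint(resume_from)
        if prev_model.config != config.model:
            raise ValueError("checkpoint model config differs from the training config")
        model.load_state_dict(prev_model.state_dict())
        if prev_disc is not None:
            disc.load_state_dict(prev_disc.state_dict())
        start_epoch = int(meta.get("epoch", 0))
        step = int(meta.get("global_step", 0))
        # optimiser moments restart; pretraining is considered done
    elif config.use_tmixup and config.pretrain_epochs > 0:
        mix_rng = np.random.default_rng(mix_seed)
        pretrain_with_tmixup(model, disc, opt_g, opt_d, windows, config, mix_rng, history)

    ckpt_path = None
    done = False
    for epoch in range(start_epoch, config.epochs):
        for batch in _epoch_batches(windows, config.batch_size, data_rng):
            row = train_step(model, disc, opt_g, opt_d, batch, config.weights)
            step += 1
            history.append({"phase": "finetune", "epoch": epoch, "step": step, **row})
            if max_steps is not None and step >= max_steps:
                done = True
                break
        if out_dir is not None and (
            (epoch + 1) % config.checkpoint_every == 0 or epoch == config.epochs - 1 or done
        ):
            ckpt_path = out_dir / f"epoch_{epoch + 1:04d}.ckpt"
            save_checkpoint(ckpt_path, model, disc, epoch=epoch + 1, global_step=step)
        if done:
            break

    if out_dir is not None:
        with open(out_dir / "training_log.jsonl", "w") as fh:
            for row in history:
                fh.write(json.dumps(row) + "\n")
        if ckpt_path is None:
            ckpt_path = out_dir / "final.ckpt"
            save_checkpoint(ckpt_path, model, disc, epoch=config.epochs, global_step=step)
    return FitResult(model=model, discriminator=disc, history=history,
                     checkpoint_path=ckpt_path)
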