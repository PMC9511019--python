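"""The growth prediction model: paired CNN encoders, a convolutional-GRU
seq2seq time-series unit, paired decoders and a least-squares patch
discriminator.

Given ``p`` historical RGB frames and instance masks, the image and mask
encoders produce per-frame latent features at quarter resolution which are
summed element-wise (the two streams are assumed mutually informative).  The
time-series encoder consumes the feature sequence with a ConvGRU; the
time-series decoder autoregressively emits ``q`` future features, each decoded
by a dedicated image head (regression) and mask head (per-pixel
classification).  Both ``p`` and ``q`` are free at run time — one trained
weight set serves 2to1, 3to1, 3to2, ... protocols without retraining.

At full scale (256×256 inputs, 32 base channels, 256 latent channels) the
layer stack matches: a 7×7 stem, two stride-2 3×3 convolutions down to 64×64,
a 3×3 projection to the latent width, three residual blocks for the image
encoder and one for the simpler mask stream; BatchNorm in encoders/decoders,
GroupNorm inside the recurrent unit, InstanceNorm in the discriminator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .core_types import (
    FeatureMap,
    InstanceMask,
    RGBFrame,
    SoftMask,
    mask_to_onehot,
)
from .nn import Tensor


@dataclass
class ModelConfig:
    image_size: int = 256
    n_classes: int = 9
    base_channels: int = 32
    latent_channels: int = 256
    n_res_blocks_image: int = 3
    n_res_blocks_mask: int = 1
    dropout_rate: float = 0.2
    gru_layers: int = 1

    def __post_init__(self):
        if self.image_size % 4:
            raise ValueError("image_size must be divisible by 4")
        if min(self.base_channels, self.latent_channels, self.n_classes) < 1:
            raise ValueError("channel/class counts must be positive")
        if self.latent_channels % 4:
            raise ValueError("latent_channels must be divisible by 4")


def _gn_groups(channels: int, preferred: int = 8) -> int:
    """Largest divisor of ``channels`` not exceeding ``preferred``."""
    for g in range(min(preferred, channels), 0, -1):
        if channels % g == 0:
            return g
    return 1


class ConvBlock(nn.Module):
    """Conv → norm → activation, the repeating unit of Table-style stacks."""

    def __init__(self, in_ch, out_ch, kernel, stride, padding, rng,
                 norm: str = "bn", act: str = "relu"):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, kernel, stride, padding, rng=rng)
        if norm == "bn":
            self.norm = nn.BatchNorm2d(out_ch)
        elif norm == "in":
            self.norm = nn.InstanceNorm2d(out_ch)
        elif norm == "gn":
            self.norm = nn.GroupNorm(_gn_groups(out_ch), out_ch)
        else:
            self.norm = None
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        if self.act == "relu":
            x = x.relu()
        elif self.act == "lrelu":
            x = x.leaky_relu(0.2)
        elif self.act == "sigmoid":
            x = x.sigmoid()
        elif self.act == "tanh":
            x = x.tanh()
        return x


class ResidualBlock(nn.Module):
    """Channel-preserving Conv3-BN-ReLU-Conv3-BN + identity skip."""

    def __init__(self, channels: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3, 1, 1, rng=rng)
        self.bn1 = nn.BatchNorm2d(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3, 1, 1, rng=rng)
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        return (x + y).relu()


class FrameEncoder(nn.Module):
    """7×7 stem + two stride-2 convs (×4 downsampling) + latent projection."""

    def __init__(self, in_ch: int, base: int, latent: int, n_res: int, rng):
        super().__init__()
        self.stem = ConvBlock(in_ch, base, 7, 1, 3, rng)
        self.down1 = ConvBlock(base, 2 * base, 3, 2, 1, rng)
        self.down2 = ConvBlock(2 * base, 4 * base, 3, 2, 1, rng)
        self.proj = ConvBlock(4 * base, latent, 3, 1, 1, rng)
        self.res_blocks = [ResidualBlock(latent, rng) for _ in range(n_res)]

    def forward(self, x: Tensor) -> Tensor:
        x = self.proj(self.down2(self.down1(self.stem(x))))
        for block in self.res_blocks:
            x = block(x)
        return x


class ConvGRUCell(nn.Module):
    """Convolutional GRU update with GroupNorm on each gate convolution.

    z = sigmoid(GN(Conv([x, h])));  r = sigmoid(GN(Conv([x, h])))
    h~ = tanh(GN(Dropout(Conv([x, r*h]))));  h' = (1-z)*h + z*h~

    Dropout acts on the candidate convolution output during training only.
    """

    def __init__(self, channels: int, dropout_rate: float, rng, dropout_rng=None):
        super().__init__()
        g = _gn_groups(channels)
        self.conv_z = nn.Conv2d(2 * channels, channels, 3, 1, 1, rng=rng)
        self.gn_z = nn.GroupNorm(g, channels)
        self.conv_r = nn.Conv2d(2 * channels, channels, 3, 1, 1, rng=rng)
        self.gn_r = nn.GroupNorm(g, channels)
        self.conv_h = nn.Conv2d(2 * channels, channels, 3, 1, 1, rng=rng)
        self.gn_h = nn.GroupNorm(g, channels)
        self.drop = nn.Dropout(dropout_rate, rng=dropout_rng)

    def forward(self, x: Tensor, hidden: Tensor) -> Tensor:
        if x.shape != hidden.shape:
            raise ValueError(f"input {x.shape} vs hidden {hidden.shape} shape mismatch")
        xh = nn.concat([x, hidden], axis=1)
        z = self.gn_z(self.conv_z(xh)).sigmoid()
        r = self.gn_r(self.conv_r(xh)).sigmoid()
        cand = self.gn_h(self.drop(self.conv_h(nn.concat([x, r * hidden], axis=1)))).tanh()
        return (1.0 - z) * hidden + z * cand


@dataclass
class HiddenState:
    """Recurrent state handed from the time-series encoder to the decoder."""

    layer_states: list[Tensor]
    last_output: Tensor


class TimeSeriesUnit(nn.Module):
    """ConvGRU seq2seq over latent feature maps: encoder cells absorb the
    ``p`` historical features, decoder cells autoregressively emit ``q``
    future features starting from the encoder's final output."""

    def __init__(self, channels: int, dropout_rate: float, rng, n_layers: int = 1,
                 dropout_rng=None):
        super().__init__()
        self.channels = channels
        self.enc_cells = [ConvGRUCell(channels, dropout_rate, rng, dropout_rng)
                          for _ in range(n_layers)]
        self.dec_cells = [ConvGRUCell(channels, dropout_rate, rng, dropout_rng)
                          for _ in range(n_layers)]

    def _zero_state(self, like: Tensor) -> list[Tensor]:
        return [Tensor(np.zeros(like.shape, dtype=np.float32)) for _ in self.enc_cells]

    def ts_encode(self, features: list[Tensor]) -> HiddenState:
        if not features:
            raise ValueError("time-series encoder needs at least one feature map")
        states = self._zero_state(features[0])
        out = features[0]
        for f in features:
            out = f
            for l, cell in enumerate(self.enc_cells):
                states[l] = cell(out, states[l])
                out = states[l]
        return HiddenState(layer_states=states, last_output=out)

    def ts_decode(self, hidden: HiddenState, q: int) -> list[Tensor]:
        if q < 1:
            raise ValueError("q must be >= 1")
        states = list(hidden.layer_states)
        prev = hidden.last_output
        outputs = []
        for _ in range(q):
            out = prev
            for l, cell in enumerate(self.dec_cells):
                states[l] = cell(out, states[l])
                out = states[l]
            outputs.append(out)
            prev = out
        return outputs


class DecoderTrunk(nn.Module):
    """Two nearest-neighbour ×2 upsamplings, each followed by conv-BN-ReLU."""

    def __init__(self, latent: int, rng):
        super().__init__()
        self.up1 = nn.Upsample2x()
        self.conv1 = ConvBlock(latent, latent // 2, 3, 1, 1, rng)
        self.up2 = nn.Upsample2x()
        self.conv2 = ConvBlock(latent // 2, latent // 4, 3, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(self.up2(self.conv1(self.up1(x))))


class ImageHead(nn.Module):
    """Full-resolution RGB head; final conv is linear, clamped at inference."""

    def __init__(self, in_ch: int, base: int, rng):
        super().__init__()
        self.block = ConvBlock(in_ch, base, 3, 1, 1, rng)
        self.out = nn.Conv2d(base, 3, 3, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.out(self.block(x))


class MaskHead(nn.Module):
    """Full-resolution mask head emitting C-channel class logits."""

    def __init__(self, in_ch: int, base: int, n_classes: int, rng):
        super().__init__()
        self.block = ConvBlock(in_ch, base, 3, 1, 1, rng)
        self.out = nn.Conv2d(base, n_classes, 3, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.out(self.block(x))


class GrowthPredictor(nn.Module):
    """End-to-end generator: E_x/E_m + ConvGRU seq2seq + D_x/D_m."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(seed + 1)
        b, L = config.base_channels, config.latent_channels
        self.image_encoder = FrameEncoder(3, b, L, config.n_res_blocks_image, rng)
        self.mask_encoder = FrameEncoder(config.n_classes, b, L, config.n_res_blocks_mask, rng)
        self.ts_unit = TimeSeriesUnit(L, config.dropout_rate, rng,
                                      n_layers=config.gru_layers, dropout_rng=drop_rng)
        # separate upsampling trunks: the decode paths become stream-specific
        self.image_trunk = DecoderTrunk(L, rng)
        self.mask_trunk = DecoderTrunk(L, rng)
        self.image_head = ImageHead(max(L // 4, 1), b, rng)
        self.mask_head = MaskHead(max(L // 4, 1), b, config.n_classes, rng)
        self.last_future_features: list[Tensor] = []

    # ------------------------------------------------------------ components
    def encode_inputs(self, x_seq: list[Tensor], m_seq: list[Tensor]) -> list[Tensor]:
        """Per-frame F_t = E_x(x_t) + E_m(m_t) at latent resolution."""
        if len(x_seq) != len(m_seq):
            raise ValueError(f"{len(x_seq)} images vs {len(m_seq)} masks")
        if not x_seq:
            raise ValueError("need at least one input frame")
        return [self.image_encoder(x) + self.mask_encoder(m) for x, m in zip(x_seq, m_seq)]

    def decode_image(self, feature: Tensor) -> Tensor:
        return self.image_head(self.image_trunk(feature))

    def decode_mask_logits(self, feature: Tensor) -> Tensor:
        return self.mask_head(self.mask_trunk(feature))

    def decode_mask(self, feature: Tensor) -> Tensor:
        """Softmax class probabilities at full resolution."""
        return nn.softmax(self.decode_mask_logits(feature), axis=1)

    # --------------------------------------------------------------- forward
    def forward(self, x_seq: list[Tensor], m_seq: list[Tensor], q: int):
        """Predict q future frames: lists of image tensors and mask logits.

        Both decoders consume the *same* future feature tensors (recorded in
        ``self.last_future_features`` for inspection).
        """
        features = self.encode_inputs(x_seq, m_seq)
        hidden = self.ts_unit.ts_encode(features)
        future = self.ts_unit.ts_decode(hidden, q)
        self.last_future_features = future
        images = [self.decode_image(f) for f in future]
        logits = [self.decode_mask_logits(f) for f in future]
        return images, logits

    # ------------------------------------------------------------- inference
    def predict_sequence(
        self,
        x_hist: list[RGBFrame],
        m_hist: list[InstanceMask | SoftMask],
        q: int,
    ) -> tuple[list[RGBFrame], list[SoftMask]]:
        """Domain-typed inference: p history pairs in, q predicted pairs out."""
        was_training = self.training
        self.eval()
        try:
            x_seq = [Tensor(f.pixels.transpose(2, 0, 1)[None]) for f in x_hist]
            m_seq = []
            for m in m_hist:
                soft = m if isinstance(m, SoftMask) else mask_to_onehot(m, self.config.n_classes)
                m_seq.append(Tensor(soft.probs.transpose(2, 0, 1)[None]))
            images, logits = self.forward(x_seq, m_seq, q)
            out_imgs = [RGBFrame(np.clip(t.data[0].transpose(1, 2, 0), 0, 1)) for t in images]
            out_masks = [
                SoftMask(nn.softmax(t, axis=1).data[0].transpose(1, 2, 0)) for t in logits
            ]
            return out_imgs, out_masks
        finally:
            self.train(was_training)

    def feature_map(self, x: RGBFrame, m: InstanceMask | SoftMask) -> FeatureMap:
        """Latent feature of a single frame pair (diagnostic helper)."""
        soft = m if isinstance(m, SoftMask) else mask_to_onehot(m, self.config.n_classes)
        f = self.encode_inputs(
            [Tensor(x.pixels.transpose(2, 0, 1)[None])],
            [Tensor(soft.probs.transpose(2, 0, 1)[None])],
        )[0]
        return FeatureMap(f.data[0].transpose(1, 2, 0))


class PatchDiscriminator(nn.Module):
    """Least-squares patch critic: four strided/instance-normalised 4×4 conv
    blocks with LeakyReLU, then a 1-channel sigmoid score map over patches.
    The scalar score of an image is the arithmetic mean of its patch map."""

    def __init__(self, base_channels: int = 64, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        b = base_channels
        self.blocks = [
            ConvBlock(3, b, 4, 2, 1, rng, norm="in", act="lrelu"),
            ConvBlock(b, 2 * b, 4, 2, 1, rng, norm="in", act="lrelu"),
            ConvBlock(2 * b, 4 * b, 4, 2, 1, rng, norm="in", act="lrelu"),
            ConvBlock(4 * b, 8 * b, 4, 1, 1, rng, norm="in", act="lrelu"),
        ]
        self.out = nn.Conv2d(8 * b, 1, 4, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return self.out(x).sigmoid()

    discriminate = forward

    def score(self, x: Tensor) -> Tensor:
        """Scalar score: mean of the patch map."""
        return self.forward(x).mean()


# ------------------------------------------------------------- checkpointing
CHECKPOINT_VERSION = 1


def save_checkpoint(path, model: GrowthPredictor, discriminator: PatchDiscriminator | None = None,
                    **meta) -> None:
    """Single-file .npz checkpoint embedding the model config and metadata."""
    payload = {f"gen/{k}": v for k, v in model.state_dict().items()}
    disc_meta = {}
    if discriminator is not None:
        payload.update({f"disc/{k}": v for k, v in discriminator.state_dict().items()})
        disc_meta = {"disc_base_channels": discriminator.blocks[0].conv.weight.shape[0]}
    header = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "seed": model.seed,
        **disc_meta,
        **meta,
    }
    payload["__meta__"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path):
    """Load (model, discriminator_or_None, meta) from a checkpoint file."""
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(bytes(arrays.pop("__meta__")).decode())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
    config = ModelConfig(**meta["config"])
    model = GrowthPredictor(config, seed=meta.get("seed", 0))
    model.load_state_dict(
        {k[len("gen/"):]: v for k, v in arrays.items() if k.startswith("gen/")}
    )
    disc = None
    disc_state = {k[len("disc/"):]: v for k, v in arrays.items() if k.startswith("disc/")}
    if disc_state:
        disc = PatchDiscriminator(base_channels=int(meta["disc_base_channels"]))
        disc.load_state_dict(disc_state)
    return model, disc, meta
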