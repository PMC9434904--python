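"""Pix2pix conditional GAN for paired FA <-> OCT-map translation.

The generator is a U-Net encoder-decoder with skip connections whose depth
scales with log2(image_size) (innermost feature map 1 x 1); the
discriminator is a PatchGAN that scores overlapping patches of the
(source, candidate) channel concatenation.  The generator objective is

    generator_loss = adversarial_loss + lambda * L1_loss,   lambda = 100,

where L1 is the mean absolute pixel difference between the generated
translation and the target.  Training alternates discriminator and
generator Adam updates (lr 2e-4, beta1 0.5, batch 1) and snapshots the
generator every ``checkpoint_interval_epochs`` epochs — 200 epochs at
interval 10 yields the canonical 20 checkpoints per direction.

`Pix2PixModel` / `Pix2PixResults` present this as a fit/results pair in
the statsmodels style; the module-level functions are the underlying ops.
"""
from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .errors import ParameterError
from .image import RasterImage, as_pixels, resize_image
from .preprocess import PairedSample, split_composite

DIRECTIONS = ("fa_to_oct", "oct_to_fa")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Translator hyperparameters; defaults are the paper-scale profile."""

    image_size: int = 512
    epochs: int = 200
    checkpoint_interval_epochs: int = 10
    lambda_l1: float = 100.0
    batch_size: int = 1
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    seed: int = 0
    direction: str = "fa_to_oct"
    base_channels: int = 64       # generator width (doubles per level, cap 8x)
    disc_channels: int = 64

    def __post_init__(self):
        n = self.image_size
        if n < 32 or (n & (n - 1)) != 0:
            raise ParameterError("image_size must be a power of two >= 32")
        if self.epochs < self.checkpoint_interval_epochs:
            raise ParameterError("epochs must be >= checkpoint interval")
        if self.lambda_l1 < 0:
            raise ParameterError("lambda_l1 must be >= 0")
        if self.direction not in DIRECTIONS:
            raise ParameterError(f"direction must be one of {DIRECTIONS}")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """Small CPU profile used for tests and desk-scale studies."""
        base = dict(image_size=32, epochs=20, checkpoint_interval_epochs=2,
                    base_channels=16, disc_channels=16)
        base.update(overrides)
        return cls(**base)

    @property
    def n_checkpoints(self) -> int:
        return self.epochs // self.checkpoint_interval_epochs


@dataclasses.dataclass(frozen=True)
class LossBreakdown:
    """One objective evaluation; generator_loss = adv + lambda * L1."""

    adversarial_loss: float
    l1_loss: float
    generator_loss: float
    discriminator_loss: float = 0.0


def composite_generator_loss(adv: float, l1: float,
                             lambda_l1: float = 100.0,
                             discriminator_loss: float = 0.0) -> LossBreakdown:
    """Combine the adversarial and weighted-L1 terms of the generator loss."""
    if adv < 0 or l1 < 0 or lambda_l1 < 0:
        raise ParameterError("loss components must be non-negative")
    return LossBreakdown(adv, l1, adv + lambda_l1 * l1, discriminator_loss)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


class UNetGenerator:
    """Encoder-decoder with mirrored skip connections, tanh output.

    Depth is log2(image_size): the innermost activation is 1 x 1, so the
    same architecture stays valid from 32 px test configs to 512 px.
    """

    def __init__(self, image_size: int, in_ch: int = 3, out_ch: int = 3,
                 ngf: int = 64, rng: np.random.Generator = None):
        if image_size < 32 or (image_size & (image_size - 1)) != 0:
            raise ParameterError("image_size must be a power of two >= 32")
        rng = rng or np.random.default_rng(0)
        self.image_size = image_size
        levels = int(math.log2(image_size))
        ch = [min(ngf * 2 ** i, 8 * ngf) for i in range(levels)]
        self.levels = levels

        self.enc = []
        for i in range(levels):
            conv = _nn.Conv2d(in_ch if i == 0 else ch[i - 1], ch[i], rng=rng)
            norm = _nn.InstanceNorm2d(ch[i]) if 0 < i < levels - 1 else None
            self.enc.append((conv, norm, _nn.LeakyReLU(0.2) if i > 0 else None))

        self.dec = []
        for j in range(levels):
            cin = ch[levels - 1] if j == 0 else 2 * ch[levels - 1 - j]
            cout = ch[levels - 2 - j] if j < levels - 1 else out_ch
            conv = _nn.ConvTranspose2d(cin, cout, rng=rng)
            norm = _nn.InstanceNorm2d(cout) if j < levels - 1 else None
            self.dec.append((conv, norm, _nn.ReLU()))
        self.out_act = _nn.Tanh()

        self.layers = ([c for c, _, _ in self.enc] +
                       [n for _, n, _ in self.enc if n] +
                       [c for c, _, _ in self.dec] +
                       [n for _, n, _ in self.dec if n])
        self.params = _nn.collect_params(self.layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        h = x
        for conv, norm, act in self.enc:
            if act is not None:
                h = act.forward(h)
            h = conv.forward(h)
            if norm is not None:
                h = norm.forward(h)
            skips.append(h)
        self._skip_shapes = [s.shape for s in skips]
        h = skips[-1]
        for j, (conv, norm, act) in enumerate(self.dec):
            if j > 0:
                h = np.concatenate([h, skips[self.levels - 1 - j]], axis=1)
            h = act.forward(h)
            h = conv.forward(h)
            if norm is not None:
                h = norm.forward(h)
        return self.out_act.forward(h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dskips = [np.zeros(s, dtype=_nn.DTYPE) for s in self._skip_shapes]
        dh = self.out_act.backward(dy)
        for j in range(self.levels - 1, -1, -1):
            conv, norm, act = self.dec[j]
            if norm is not None:
                dh = norm.backward(dh)
            dh = conv.backward(dh)
            dh = act.backward(dh)
            if j > 0:
                split = dh.shape[1] - dskips[self.levels - 1 - j].shape[1]
                dskips[self.levels - 1 - j] += dh[:, split:]
                dh = dh[:, :split]
        dskips[-1] += dh
        dh = np.zeros_like(dskips[-1])
        for i in range(self.levels - 1, -1, -1):
            conv, norm, act = self.enc[i]
            dh = dh + dskips[i]
            if norm is not None:
                dh = norm.backward(dh)
            dh = conv.backward(dh)
            if act is not None:
                dh = act.backward(dh)
        return dh

    def get_weights(self):
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights):
        if len(weights) != len(self.params):
            raise ParameterError("weight list does not match the generator")
        for p, w in zip(self.params, weights):
            p.data[...] = np.asarray(w, dtype=_nn.DTYPE).reshape(p.data.shape)


class PatchDiscriminator:
    """PatchGAN: scores overlapping patches of concat(source, candidate).

    Three stride-2 convolutions plus two stride-1 heads; with 256-px input
    the score grid is 30 x 30 (the 70 x 70 receptive-field patch head).
    """

    def __init__(self, in_ch: int = 6, ndf: int = 64,
                 rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        self.blocks = []
        specs = [(in_ch, ndf, 2, False), (ndf, 2 * ndf, 2, True),
                 (2 * ndf, 4 * ndf, 2, True), (4 * ndf, 8 * ndf, 1, True)]
        for cin, cout, stride, use_norm in specs:
            conv = _nn.Conv2d(cin, cout, stride=stride, rng=rng)
            norm = _nn.InstanceNorm2d(cout) if use_norm else None
            self.blocks.append((conv, norm, _nn.LeakyReLU(0.2)))
        self.head = _nn.Conv2d(8 * ndf, 1, stride=1, rng=rng)
        self.layers = ([c for c, _, _ in self.blocks] +
                       [n for _, n, _ in self.blocks if n] + [self.head])
        self.params = _nn.collect_params(self.layers)

    def forward(self, source: np.ndarray, candidate: np.ndarray) -> np.ndarray:
        if source.shape[2:] != candidate.shape[2:]:
            raise ParameterError("source and candidate dims must match")
        h = np.concatenate([source, candidate], axis=1)
        self._in_ch_src = source.shape[1]
        for conv, norm, act in self.blocks:
            h = conv.forward(h)
            if norm is not None:
                h = norm.forward(h)
            h = act.forward(h)
        return self.head.forward(h)  # (N, 1, gh, gw) patch score logits

    def backward(self, dy: np.ndarray):
        dh = self.head.backward(dy)
        for conv, norm, act in reversed(self.blocks):
            dh = act.backward(dh)
            if norm is not None:
                dh = norm.backward(dh)
            dh = conv.backward(dh)
        return dh[:, :self._in_ch_src], dh[:, self._in_ch_src:]


def build_generator(config: TrainConfig) -> UNetGenerator:
    """Generator mapping image_size^2 x 3 -> image_size^2 x 3, tanh-bounded."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    return UNetGenerator(config.image_size, ngf=config.base_channels, rng=rng)


def build_discriminator(config: TrainConfig) -> PatchDiscriminator:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    return PatchDiscriminator(ndf=config.disc_channels, rng=rng)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------


def _to_tensor(img, size: int) -> np.ndarray:
    """uint8 image -> (1, 3, size, size) float32 in [-1, 1]."""
    px = as_pixels(img)
    if px.ndim == 2:
        px = np.repeat(px[:, :, None], 3, axis=2)
    if px.shape[:2] != (size, size):
        px = resize_image(px, size, size).pixels
    t = px.astype(_nn.DTYPE) / 127.5 - 1.0
    return t.transpose(2, 0, 1)[None]


def tensor_to_image(t: np.ndarray) -> RasterImage:
    """(1, 3, H, W) in [-1, 1] -> uint8 RGB image."""
    px = (np.clip(t[0], -1.0, 1.0).transpose(1, 2, 0) + 1.0) * 127.5
    return RasterImage.from_array(px)


def coerce_pairs(pairs, config: TrainConfig) -> list:
    """Normalize heterogeneous pair inputs to (source, target) tensors.

    Accepts PairedSample, (fa, oct) image tuples, or 2:1 composites; the
    direction selects which half is source vs target.
    """
    if not pairs:
        raise ParameterError("training requires at least one pair")
    out = []
    for p in pairs:
        if isinstance(p, PairedSample):
            fa, oct_img = p.fa_crop, p.oct_crop
        elif isinstance(p, (tuple, list)) and len(p) >= 2:
            fa, oct_img = p[0], p[1]
        else:
            fa, oct_img = split_composite(p)
        src, tgt = (fa, oct_img) if config.direction == "fa_to_oct" else (oct_img, fa)
        out.append((_to_tensor(src, config.image_size),
                    _to_tensor(tgt, config.image_size)))
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CheckpointSet:
    """Generator snapshots at strictly increasing epochs, one direction."""

    direction: str
    config: TrainConfig
    entries: list  # [(epoch, [weight arrays]), ...]

    def __post_init__(self):
        epochs = [e for e, _ in self.entries]
        if any(b <= a for a, b in zip(epochs, epochs[1:])):
            raise ParameterError("checkpoint epochs must be strictly increasing")

    def __len__(self):
        return len(self.entries)

    @property
    def epochs(self):
        return [e for e, _ in self.entries]

    def generator_at(self, index: int) -> UNetGenerator:
        gen = build_generator(self.config)
        gen.set_weights(self.entries[index][1])
        return gen

    def save(self, out_dir) -> Path:
        """Write ``g_<direction>_<epoch>.npz`` files plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for epoch, weights in self.entries:
            arrays = {f"p{i}": w for i, w in enumerate(weights)}
            np.savez(out / f"g_{self.direction}_{epoch:04d}.npz", **arrays)
        manifest = {
            "direction": self.direction,
            "epochs": self.epochs,
            "config": dataclasses.asdict(self.config),
        }
        (out / f"manifest_{self.direction}.json").write_text(
            json.dumps(manifest, indent=2))
        return out

    @classmethod
    def load(cls, out_dir, direction: str) -> "CheckpointSet":
        out = Path(out_dir)
        manifest = json.loads((out / f"manifest_{direction}.json").read_text())
        config = TrainConfig(**manifest["config"])
        entries = []
        for epoch in manifest["epochs"]:
            with np.load(out / f"g_{direction}_{epoch:04d}.npz") as z:
                entries.append((epoch, [z[f"p{i}"] for i in range(len(z.files))]))
        return cls(direction, config, entries)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train(pairs, config: TrainConfig, callback=None):
    """Train one direction; returns (CheckpointSet, per-epoch history).

    Alternates a discriminator step (real + fake patch BCE, halved) and a
    generator step (patch BCE toward "real" + lambda * L1) per sample, in a
    seeded shuffled order.  History rows carry the per-epoch mean of each
    loss component; the recorded generator loss is re-derivable as
    adv + lambda * L1 at every row.
    """
    data = coerce_pairs(pairs, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    gen = build_generator(config)
    disc = build_discriminator(config)
    opt_g = _nn.Adam(gen.params, lr=config.learning_rate, beta1=config.adam_beta1)
    opt_d = _nn.Adam(disc.params, lr=config.learning_rate, beta1=config.adam_beta1)
    lam = config.lambda_l1

    history = []
    entries = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(data))
        sums = np.zeros(4)
        for idx in order:
            src, tgt = data[idx]

            # -- discriminator step --------------------------------------
            fake = gen.forward(src)
            opt_d.zero_grad()
            z_real = disc.forward(src, tgt)
            loss_real, dz = _nn.bce_with_logits(z_real, 1.0)
            disc.backward(dz * 0.5)
            z_fake = disc.forward(src, fake)
            loss_fake, dz = _nn.bce_with_logits(z_fake, 0.0)
            disc.backward(dz * 0.5)
            d_loss = 0.5 * (loss_real + loss_fake)
            opt_d.step()

            # -- generator step ------------------------------------------
            opt_g.zero_grad()
            fake = gen.forward(src)
            z = disc.forward(src, fake)
            adv, dz = _nn.bce_with_logits(z, 1.0)
            opt_d.zero_grad()  # discard D grads from the G pass
            _, dfake_adv = disc.backward(dz)
            diff = fake - tgt
            l1 = float(np.mean(np.abs(diff)))
            dfake_l1 = (lam * np.sign(diff) / diff.size).astype(_nn.DTYPE)
            gen.backward(dfake_adv + dfake_l1)
            opt_g.step()

            breakdown = composite_generator_loss(adv, l1, lam, d_loss)
            sums += (breakdown.adversarial_loss, breakdown.l1_loss,
                     breakdown.generator_loss, breakdown.discriminator_loss)
        means = sums / len(data)
        history.append({"epoch": epoch, "adversarial_loss": means[0],
                        "l1_loss": means[1], "generator_loss": means[2],
                        "discriminator_loss": means[3]})
        if epoch % config.checkpoint_interval_epochs == 0:
            entries.append((epoch, gen.get_weights()))
        if callback is not None:
            callback(epoch, history[-1])
    return CheckpointSet(config.direction, config, entries), pd.DataFrame(history)


def translate(generator: UNetGenerator, source) -> RasterImage:
    """Run one image through a trained generator; deterministic inference."""
    px = as_pixels(source)
    if px.shape[0] != generator.image_size or px.shape[1] != generator.image_size:
        raise ParameterError(
            f"source must be {generator.image_size}px square, got {px.shape[:2]}")
    return tensor_to_image(generator.forward(_to_tensor(px, generator.image_size)))


# ---------------------------------------------------------------------------
# statsmodels-style surface
# ---------------------------------------------------------------------------


class Pix2PixModel:
    """Paired image-translation model in the fit/results idiom.

    Parameters
    ----------
    pairs : sequence
        PairedSample objects, (fa, oct) image tuples, or 2:1 composites.
    config : TrainConfig, optional
        Hyperparameters; defaults to the paper-scale profile.
    """

    def __init__(self, pairs, config: TrainConfig = None):
        self.config = config or TrainConfig()
        self.pairs = list(pairs)
        if not self.pairs:
            raise ParameterError("model requires at least one pair")

    @classmethod
    def from_dataset(cls, pairs, **config_overrides) -> "Pix2PixModel":
        return cls(pairs, TrainConfig(**config_overrides))

    def fit(self, callback=None) -> "Pix2PixResults":
        checkpoints, history = train(self.pairs, self.config, callback=callback)
        return Pix2PixResults(self, checkpoints, history)


class Pix2PixResults:
    """Fitted translator: checkpoints, loss history, selection and metrics."""

    def __init__(self, model: Pix2PixModel, checkpoints: CheckpointSet,
                 history: pd.DataFrame):
        self.model = model
        self.config = model.config
        self.checkpoints = checkpoints
        self.history = history
        self.best_index = None  # set by select_best
        self.fid_curve = None

    def generator(self, index: int = None) -> UNetGenerator:
        """Generator at a checkpoint index (best if selected, else last)."""
        if index is None:
            index = self.best_index if self.best_index is not None else len(self.checkpoints) - 1
        return self.checkpoints.generator_at(index)

    def translate(self, source, index: int = None) -> RasterImage:
        return translate(self.generator(index), source)

    def select_best(self, sources, real_targets, extractor=None):
        """FID-score every checkpoint against real targets; keep the argmin."""
        from .selection import select_best_checkpoint

        curve = select_best_checkpoint(self.checkpoints, real_targets,
                                       sources, extractor)
        self.fid_curve = curve
        self.best_index = curve.best_index
        return curve

    def evaluate(self, pairs, index: int = None):
        """Translate held-out sources and score them against the targets."""
        from .metrics import evaluate_pairs

        gen = self.generator(index)
        data = coerce_pairs(pairs, self.config)
        scored = []
        for src, tgt in data:
            synth = tensor_to_image(gen.forward(src))
            scored.append((tensor_to_image(tgt), synth))
        return evaluate_pairs(scored)

    def summary(self) -> str:
        cfg = self.config
        last = self.history.iloc[-1]
        lines = [
            "Pix2Pix Translation Results",
            "=" * 46,
            f"direction:            {cfg.direction}",
            f"image size:           {cfg.image_size} px",
            f"pairs:                {len(self.model.pairs)}",
            f"epochs / interval:    {cfg.epochs} / {cfg.checkpoint_interval_epochs}",
            f"lambda (L1 weight):   {cfg.lambda_l1:g}",
            f"checkpoints saved:    {len(self.checkpoints)}",
            f"final generator loss: {last['generator_loss']:.4f}",
            f"  adversarial part:   {last['adversarial_loss']:.4f}",
            f"  L1 part (x lambda): {cfg.lambda_l1 * last['l1_loss']:.4f}",
            f"final discriminator:  {last['discriminator_loss']:.4f}",
        ]
        if self.best_index is not None:
            lines.append(
                f"best checkpoint:      #{self.best_index + 1} "
                f"(epoch {self.checkpoints.epochs[self.best_index]}, "
                f"FID {self.fid_curve.scores[self.best_index]:.4f})")
        return "\n".join(lines)
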