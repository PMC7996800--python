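"""DCGAN: layer plans, losses, adversarial training and image generation.

The generator maps a 100-element uniform [0, 1] latent vector through a dense
layer of width (w/4)·(h/4)·256 into a (w/4, h/4, 256) tensor, then through
three transposed convolutions — (w/4, h/4, 128), (w/2, h/2, 64), (w, h, 1) —
with batch normalization and LeakyReLU after every layer except the output.
The discriminator is two stride-2 'same' convolutions (64 then 128 filters,
each followed by LeakyReLU and 30% dropout), a flatten of width
(w/4)·(h/4)·128 and a single sigmoid output unit.  For 28×28 images the dense
width is 12 544 and the flatten width 6 272.

Losses are binary cross-entropies in nats: the generator is scored against an
all-ones target, the discriminator against ones on real and zeros on
generated images, with the total discriminator loss being the sum of the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .convmath import ConvSpec, tconv_output_size
from .dataset import ImageDataset

__all__ = [
    "LATENT_DIM",
    "GeneratorPlan",
    "DiscriminatorPlan",
    "GanTrainConfig",
    "CrossEntropyTerms",
    "Generator",
    "Discriminator",
    "sample_latent",
    "build_generator",
    "build_discriminator",
    "generator_loss",
    "discriminator_loss",
    "train_gan",
    "generate_images",
]

LATENT_DIM = 100
#: Kernel size for every GAN (transposed) convolution; unstated by the
#: architecture description, 5×5 is the standard DCGAN choice.
DEFAULT_KERNEL = 5
#: Full-scale channel widths of the three generator stages / two
#: discriminator convolutions.
FULL_GEN_CHANNELS = (256, 128, 64)
FULL_DISC_CHANNELS = (64, 128)
#: Narrow desk-profile widths for CPU-scale training; same architecture,
#: eighth-width channels.
DESK_GEN_CHANNELS = (32, 16, 8)
_CLAMP = 1e-7


@dataclass(frozen=True)
class GeneratorPlan:
    """Shape chain of the generator for a (w_out, h_out) target image."""

    w_out: int
    h_out: int
    channels: tuple = FULL_GEN_CHANNELS
    kernel: int = DEFAULT_KERNEL

    def __post_init__(self) -> None:
        if self.w_out % 4 or self.h_out % 4 or self.w_out < 4 or self.h_out < 4:
            raise ValueError("w_out and h_out must be positive multiples of 4")

    @property
    def dense_units(self) -> int:
        return (self.w_out // 4) * (self.h_out // 4) * self.channels[0]

    @property
    def strides(self) -> tuple:
        # stage 1 keeps the (w/4, h/4) grid, stages 2-3 double it
        return (1, 2, 2)

    def shape_chain(self) -> list[tuple]:
        """Per-stage output shapes, from latent input to image output."""
        w, h = self.w_out // 4, self.h_out // 4
        chain = [(1, LATENT_DIM), (self.dense_units,), (h, w, self.channels[0])]
        stage_channels = (self.channels[1], self.channels[2], 1)
        for s, c in zip(self.strides, stage_channels):
            w = tconv_output_size(ConvSpec(L=w, F=self.kernel, S=s, P="same"))
            h = tconv_output_size(ConvSpec(L=h, F=self.kernel, S=s, P="same"))
            chain.append((h, w, c))
        return chain


@dataclass(frozen=True)
class DiscriminatorPlan:
    """Shape chain of the discriminator for (w, h, 1) input images."""

    w: int
    h: int
    channels: tuple = FULL_DISC_CHANNELS
    kernel: int = DEFAULT_KERNEL
    dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.w % 4 or self.h % 4 or self.w < 4 or self.h < 4:
            raise ValueError("w and h must be positive multiples of 4 (two stride-2 layers)")

    @property
    def flatten_width(self) -> int:
        return (self.w // 4) * (self.h // 4) * self.channels[1]

    def shape_chain(self) -> list[tuple]:
        return [
            (self.h, self.w, 1),
            (self.h // 2, self.w // 2, self.channels[0]),
            (self.h // 4, self.w // 4, self.channels[1]),
            (self.flatten_width,),
            (1,),
        ]


@dataclass(frozen=True)
class GanTrainConfig:
    """Adversarial training settings.

    The published epoch schedule is {100, 250, 500, 1000}; optimizer details
    are unreported upstream, so the defaults are the DCGAN conventions (Adam,
    learning rate 2e-4, batch 32), all overridable.
    """

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 2e-4
    solver: str = "Adam"
    seed: int = 0
    milestones: tuple = ()
    channels: tuple = FULL_GEN_CHANNELS
    kernel: int = DEFAULT_KERNEL

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if any(m < 1 or m > self.epochs for m in self.milestones):
            raise ValueError("milestones must lie within [1, epochs]")


@dataclass(frozen=True)
class CrossEntropyTerms:
    """Discriminator loss decomposition (nats): H_d = H_d_real + H_d_fake."""

    h_d_real: float
    h_d_fake: float

    @property
    def h_d(self) -> float:
        return self.h_d_real + self.h_d_fake


def sample_latent(n: int, seed: int) -> np.ndarray:
    """n latent vectors of 100 i.i.d. uniform [0, 1] entries (seeded)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.random((n, LATENT_DIM)).astype(np.float32)


class Generator:
    """Realized generator network plus its plan; outputs images in [0, 1]."""

    def __init__(self, plan: GeneratorPlan, seed: int = 0) -> None:
        self.plan = plan
        rng = np.random.default_rng(seed)
        w4, h4 = plan.w_out // 4, plan.h_out // 4
        c0, c1, c2 = plan.channels
        k = plan.kernel
        self.net = nn.Sequential(
            [
                nn.Dense(LATENT_DIM, plan.dense_units, rng),
                nn.BatchNorm(plan.dense_units),
                nn.LeakyReLU(),
                nn.Reshape((h4, w4, c0)),
                nn.ConvTranspose2D(c0, c1, k, 1, rng),
                nn.BatchNorm(c1),
                nn.LeakyReLU(),
                nn.ConvTranspose2D(c1, c2, k, 2, rng),
                nn.BatchNorm(c2),
                nn.LeakyReLU(),
                nn.ConvTranspose2D(c2, 1, k, 2, rng),
                nn.Sigmoid(),  # pixels in [0, 1]
            ]
        )

    def forward(self, z: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(z.astype(np.float32), training=training)

    def generate(self, n: int, seed: int) -> np.ndarray:
        """n images of shape (n, h, w) in [0, 1]; seed-deterministic."""
        if n < 0:
            raise ValueError("n must be >= 0")
        if n == 0:
            return np.zeros((0, self.plan.h_out, self.plan.w_out), dtype=np.float32)
        out = []
        remaining, offset = n, 0
        while remaining:
            m = min(remaining, 256)
            z = sample_latent(m, int(np.random.SeedSequence([seed, offset]).generate_state(1)[0] % 2**31))
            out.append(self.forward(z)[:, :, :, 0])
            remaining -= m
            offset += 1
        return np.clip(np.concatenate(out), 0.0, 1.0)


class Discriminator:
    """Realized discriminator network plus its plan; outputs P(real)."""

    def __init__(self, plan: DiscriminatorPlan, seed: int = 0) -> None:
        self.plan = plan
        rng = np.random.default_rng(seed)
        c0, c1 = plan.channels
        k = plan.kernel
        self.net = nn.Sequential(
            [
                nn.Conv2D(1, c0, k, 2, "same", rng),
                nn.LeakyReLU(),
                nn.Dropout(plan.dropout, rng),
                nn.Conv2D(c0, c1, k, 2, "same", rng),
                nn.LeakyReLU(),
                nn.Dropout(plan.dropout, rng),
                nn.Flatten(),
                nn.Dense(plan.flatten_width, 1, rng),
                nn.Sigmoid(),
            ]
        )

    def forward(self, images: np.ndarray, training: bool = False) -> np.ndarray:
        x = images.astype(np.float32)
        if x.ndim == 3:
            x = x[:, :, :, None]
        return self.net.forward(x, training=training)[:, 0]


def build_generator(w_out: int, h_out: int, channels: tuple = FULL_GEN_CHANNELS,
                    kernel: int = DEFAULT_KERNEL, seed: int = 0) -> Generator:
    """Generator for (w_out, h_out) targets; sizes must be multiples of 4."""
    return Generator(GeneratorPlan(w_out, h_out, channels, kernel), seed=seed)


def build_discriminator(w: int, h: int, channels: tuple = FULL_DISC_CHANNELS,
                        kernel: int = DEFAULT_KERNEL, seed: int = 0) -> Discriminator:
    """Discriminator for (w, h, 1) inputs; sizes must be multiples of 4."""
    return Discriminator(DiscriminatorPlan(w, h, channels, kernel), seed=seed)


def _bce(p: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy (nats) vs a constant target, with gradient."""
    p = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    n = len(p)
    if target == 1.0:
        loss = float(-np.log(p).mean())
        dp = -1.0 / (p * n)
    else:
        loss = float(-np.log(1.0 - p).mean())
        dp = 1.0 / ((1.0 - p) * n)
    return loss, dp


def generator_loss(d_out_fake: np.ndarray) -> float:
    """Cross-entropy of discriminator outputs on fakes vs an all-ones target."""
    d_out_fake = np.asarray(d_out_fake, dtype=float)
    if d_out_fake.size == 0:
        raise ValueError("empty discriminator output")
    return _bce(d_out_fake, 1.0)[0]


def discriminator_loss(d_out_real: np.ndarray, d_out_fake: np.ndarray) -> CrossEntropyTerms:
    """H_d_real = BCE(ones, real), H_d_fake = BCE(zeros, fake), H_d = sum."""
    d_out_real = np.asarray(d_out_real, dtype=float)
    d_out_fake = np.asarray(d_out_fake, dtype=float)
    if d_out_real.size == 0 or d_out_fake.size == 0:
        raise ValueError("empty discriminator output")
    return CrossEntropyTerms(_bce(d_out_real, 1.0)[0], _bce(d_out_fake, 0.0)[0])


def _save_grid(images: np.ndarray, path: Path, cols: int = 4) -> None:
    n, h, w = images.shape
    rows = -(-n // cols)
    grid = np.ones((rows * h, cols * w), dtype=np.float32)
    for i in range(n):
        r, c = divmod(i, cols)
        grid[r * h : (r + 1) * h, c * w : (c + 1) * w] = images[i]
    arr = np.clip(np.round(grid * 255), 0, 255).astype(np.uint8)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr, mode="L").save(path)


def train_gan(
    images: ImageDataset | np.ndarray,
    config: GanTrainConfig = GanTrainConfig(),
    out_dir: str | Path | None = None,
) -> tuple[Generator, pd.DataFrame]:
    """Adversarially train one generator on a single-class image stack.

    Each epoch shuffles the real images into batches; per batch the
    discriminator is updated on real + freshly generated images, then the
    generator is updated through the discriminator against an all-ones
    target.  Returns the trained generator and a per-epoch loss history
    (epoch, h_g, h_d_real, h_d_fake, h_d).  With ``out_dir`` set, milestone
    epochs dump a 16-image grid PNG from a fixed latent probe and the loss
    history is written as CSV.
    """
    pixels = images.images if isinstance(images, ImageDataset) else np.asarray(images)
    if pixels.ndim != 3 or len(pixels) < 1:
        raise ValueError("need a non-empty (n, h, w) image stack")
    h, w = pixels.shape[1:]
    if h != w or h % 4:
        raise ValueError("images must be square with size divisible by 4")

    gen = build_generator(w, h, channels=config.channels, kernel=config.kernel, seed=config.seed)
    disc_channels = (config.channels[2], config.channels[1])
    disc = build_discriminator(w, h, channels=disc_channels, kernel=config.kernel,
                               seed=config.seed + 1)
    opt_g = nn.make_optimizer(config.solver, config.learning_rate)
    opt_d = nn.make_optimizer(config.solver, config.learning_rate)
    rng = np.random.default_rng(config.seed)
    probe_z = sample_latent(16, config.seed)

    history = []
    out_dir = Path(out_dir) if out_dir is not None else None
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(pixels))
        sums = np.zeros(3)
        n_batches = 0
        for start in range(0, len(pixels), config.batch_size):
            real = pixels[order[start : start + config.batch_size]]
            nb = len(real)
            z = rng.random((nb, LATENT_DIM)).astype(np.float32)

            # --- discriminator step: real vs detached fakes
            fake = gen.forward(z, training=True)
            p_real = disc.forward(real, training=True)
            h_d_real, dp = _bce(p_real, 1.0)
            disc.net.backward(dp[:, None])
            stash = disc.net.copy_grads()
            p_fake = disc.forward(fake[:, :, :, 0], training=True)
            h_d_fake, dp = _bce(p_fake, 0.0)
            disc.net.backward(dp[:, None])
            disc.net.add_grads(stash)
            opt_d.step(disc.net)

            # --- generator step: push D(fake) toward 1
            z = rng.random((nb, LATENT_DIM)).astype(np.float32)
            fake = gen.forward(z, training=True)
            p_fake = disc.forward(fake[:, :, :, 0], training=True)
            h_g, dp = _bce(p_fake, 1.0)
            dx = disc.net.backward(dp[:, None])
            gen.net.backward(dx)
            opt_g.step(gen.net)

            sums += (h_g, h_d_real, h_d_fake)
            n_batches += 1
        h_g, h_d_real, h_d_fake = sums / n_batches
        history.append(
            {"epoch": epoch, "h_g": h_g, "h_d_real": h_d_real,
             "h_d_fake": h_d_fake, "h_d": h_d_real + h_d_fake}
        )
        if out_dir is not None and epoch in config.milestones:
            _save_grid(np.clip(gen.forward(probe_z)[:, :, :, 0], 0, 1),
                       out_dir / f"milestone_epoch_{epoch:04d}.png")

    history_df = pd.DataFrame(history)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        history_df.to_csv(out_dir / "loss_history.csv", index=False)
    return gen, history_df


def generate_images(generator: Generator, n: int, seed: int) -> ImageDataset:
    """n generator draws packaged as a dataset tagged provenance='generated'."""
    if n < 0:
        raise ValueError("n must be >= 0")
    imgs = generator.generate(n, seed)
    return ImageDataset(
        imgs,
        np.zeros(n, dtype=np.int64),
        provenance=np.full(n, "generated", dtype=object),
        seeds=np.full(n, seed, dtype=np.int64),
    )
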