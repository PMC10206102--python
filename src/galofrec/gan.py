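"""Restore-CycleGAN: unpaired translation from inpainted fuzzy images to the
reference-object domain.

Two U-Net generators (G_xy: fuzzy -> reference domain, G_yx: the reverse) and
two PatchGAN discriminators are trained with least-squares adversarial loss,
L1 cycle-consistency (weight alpha1 = 10) and L1 identity mapping (weight
alpha2 = 5). Discriminator losses are halved. Fake images fed to the
discriminators are drawn from a 50-image pool. Only G_xy is used after
training.

Printed filter schedules:
  generator      64-128-256-512-512-512-512-512-512-512-512-512-256-128-64-3
  discriminator  64-128-256-512-512-1

All strided (transpose-)convolutions use kernel 4, stride 2, padding 1;
encoder/discriminator activations are leaky (slope 0.2), the decoder uses
plain rectification and a tanh output; images are normalized to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import (Adam, Conv2d, ConvTranspose2d, Tensor, absval, astensor,
                 concat, crop2d, instance_norm, leaky_relu, mean, pad2d, relu,
                 square, tanh)

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "LossWeights", "TrainConfig",
    "ImagePool", "UNetGenerator", "PatchDiscriminator",
    "build_generator", "build_discriminator",
    "generator_loss", "discriminator_loss", "pool_sample",
    "train", "translate", "CycleGANCheckpoint", "reduced_specs",
]

FULL_GENERATOR_SCHEDULE = (64, 128, 256, 512, 512, 512, 512, 512,
                           512, 512, 512, 512, 256, 128, 64, 3)
FULL_DISCRIMINATOR_SCHEDULE = (64, 128, 256, 512, 512, 1)


@dataclass(frozen=True)
class GeneratorSpec:
    filter_schedule: tuple[int, ...] = FULL_GENERATOR_SCHEDULE
    input_size: int = 420
    kernel_size: int = 4
    stride: int = 2
    skip_connections: bool = True


@dataclass(frozen=True)
class DiscriminatorSpec:
    filter_schedule: tuple[int, ...] = FULL_DISCRIMINATOR_SCHEDULE
    kernel_size: int = 4
    patch_output: bool = True


@dataclass(frozen=True)
class LossWeights:
    """alpha1 weights the two cycle terms, alpha2 the identity term."""

    alpha1: float = 10.0
    alpha2: float = 5.0

    def __post_init__(self):
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 1
    learning_rate: float = 2e-4
    beta1: float = 0.5
    pool_size: int = 50
    init_sd: float = 0.02
    seed: int = 0
    reduced_scale: bool = False
    width_divisor: int = 8  # used when reduced_scale is set
    depth: int | None = None  # override U-Net depth (reduced scale)

    def __post_init__(self):
        for name in ("epochs", "batch_size", "learning_rate", "beta1",
                     "pool_size", "init_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class UNetGenerator:
    """U-Net: strided-conv encoder to a bottleneck, transposed-conv decoder
    with skip concatenations. Inputs whose sides are not a multiple of
    2**depth are zero-padded to the next multiple and the output cropped back.
    """

    def __init__(self, spec: GeneratorSpec | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        spec = spec or GeneratorSpec()
        rng = rng or np.random.default_rng(0)
        sched = tuple(spec.filter_schedule)
        if len(sched) < 4 or len(sched) % 2 != 0:
            raise ValueError("filter schedule must have even length >= 4")
        if sched[-1] != 3:
            raise ValueError("generator schedule must end in 3 (RGB output)")
        depth = len(sched) // 2
        if sched[depth - 1] != sched[depth]:
            raise ValueError("encoder/decoder halves cannot mirror at the bottleneck")
        self.spec = spec
        self.depth = depth
        enc_filters = sched[:depth]
        dec_filters = sched[depth:]
        k, s = spec.kernel_size, spec.stride
        self.encoder: list[Conv2d] = []
        cin = 3
        for f in enc_filters:
            self.encoder.append(Conv2d(cin, f, k=k, stride=s, pad=1, rng=rng,
                                       init_sd=0.02, dtype=dtype))
            cin = f
        self.decoder: list[ConvTranspose2d] = []
        for j, f in enumerate(dec_filters):
            if j == 0:
                cin = enc_filters[-1]
            elif spec.skip_connections:
                cin = dec_filters[j - 1] + enc_filters[depth - 1 - j]
            else:
                cin = dec_filters[j - 1]
            self.decoder.append(ConvTranspose2d(cin, f, k=k, stride=s, pad=1,
                                                rng=rng, init_sd=0.02, dtype=dtype))

    @property
    def output_channels(self) -> int:
        return self.decoder[-1].out_channels

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self.encoder + self.decoder:
            params.extend(layer.parameters())
        return params

    def __call__(self, x: Tensor) -> Tensor:
        x = astensor(x)
        _, _, h, w = x.data.shape
        unit = 2**self.depth
        ph = (-h) % unit
        pw = (-w) % unit
        if ph or pw:
            x = pad2d(x, ph, pw)
        skips: list[Tensor] = []
        hidden = x
        for i, conv in enumerate(self.encoder):
            hidden = conv(hidden)
            # no norm on the first (raw-image) and bottleneck layers
            if 0 < i < self.depth - 1:
                hidden = instance_norm(hidden)
            hidden = leaky_relu(hidden, 0.2)
            skips.append(hidden)
        for j, tconv in enumerate(self.decoder):
            hidden = tconv(hidden)
            if j < self.depth - 1:
                hidden = instance_norm(hidden)
                hidden = relu(hidden)
                if self.spec.skip_connections:
                    hidden = concat(hidden, skips[self.depth - 2 - j], axis=1)
            else:
                hidden = tanh(hidden)
        if ph or pw:
            hidden = crop2d(hidden, ph // 2, h, pw // 2, w)
        return hidden


class PatchDiscriminator:
    """PatchGAN: a stack of strided convolutions emitting a spatial map of
    real/fake scores, one per receptive-field patch. The last two layers use
    stride 1, the rest stride 2."""

    def __init__(self, spec: DiscriminatorSpec | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        spec = spec or DiscriminatorSpec()
        rng = rng or np.random.default_rng(0)
        sched = tuple(spec.filter_schedule)
        if len(sched) < 2 or sched[-1] != 1:
            raise ValueError("discriminator schedule must end in 1")
        self.spec = spec
        n = len(sched)
        self.layers: list[Conv2d] = []
        cin = 3
        for i, f in enumerate(sched):
            stride = 2 if i < n - 2 else 1
            self.layers.append(Conv2d(cin, f, k=spec.kernel_size, stride=stride,
                                      pad=1, rng=rng, init_sd=0.02, dtype=dtype))
            cin = f

    @property
    def output_channels(self) -> int:
        return self.layers[-1].out_channels

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self.layers:
            params.extend(layer.parameters())
        return params

    def __call__(self, x: Tensor) -> Tensor:
        hidden = astensor(x)
        n = len(self.layers)
        for i, conv in enumerate(self.layers):
            hidden = conv(hidden)
            if i < n - 1:
                if i > 0:
                    hidden = instance_norm(hidden)
                hidden = leaky_relu(hidden, 0.2)
        return hidden


def build_generator(spec: GeneratorSpec | None = None,
                    rng: np.random.Generator | None = None) -> UNetGenerator:
    return UNetGenerator(spec, rng)


def build_discriminator(spec: DiscriminatorSpec | None = None,
                        rng: np.random.Generator | None = None) -> PatchDiscriminator:
    return PatchDiscriminator(spec, rng)


def reduced_specs(image_size: int, width_divisor: int = 8,
                  depth: int | None = None) -> tuple[GeneratorSpec, DiscriminatorSpec]:
    """Desk-scale specs: narrowed filter schedules and a depth that fits the
    image (bottleneck no smaller than 2 pixels)."""
    if depth is None:
        depth = max(2, min(5, int(np.log2(image_size)) - 1))
    full_enc = FULL_GENERATOR_SCHEDULE[:8]
    enc = tuple(max(4, f // width_divisor) for f in full_enc[:depth])
    # mirrored decoder ending in 3, symmetric at the bottleneck
    gen_sched = enc + tuple(reversed(enc))[:-1] + (3,)
    n_disc = max(2, depth - 1)
    disc = tuple(max(4, f // width_divisor)
                 for f in FULL_DISCRIMINATOR_SCHEDULE[:n_disc]) + (1,)
    return (GeneratorSpec(filter_schedule=gen_sched, input_size=image_size),
            DiscriminatorSpec(filter_schedule=disc))


# --- losses -----------------------------------------------------------------

def generator_loss(x_batch, y_batch, g_xy, g_yx, d_y,
                   weights: LossWeights | None = None) -> Tensor:
    """Least-squares adversarial + cycle (both directions) + identity loss for
    the generator G_xy, with D_y and G_yx held fixed:

        E[(D_y(G_xy(x)) - 1)^2] + a1 E|G_xy(G_yx(y)) - y|
                                + a1 E|G_yx(G_xy(x)) - x|
                                + a2 E|G_xy(y) - y|
    """
    weights = weights or LossWeights()
    x = astensor(x_batch)
    y = astensor(y_batch)
    fake_y = g_xy(x)
    adv = mean(square(astensor(d_y(fake_y)) - 1.0))
    cycle_y = mean(absval(astensor(g_xy(astensor(g_yx(y)))) - y))
    cycle_x = mean(absval(astensor(g_yx(fake_y)) - x))
    identity = mean(absval(astensor(g_xy(y)) - y))
    return adv + weights.alpha1 * cycle_y + weights.alpha1 * cycle_x \
        + weights.alpha2 * identity


def discriminator_loss(y_batch, fake_from_pool, d_y) -> Tensor:
    """Halved least-squares loss: 0.5 (E[(D(y)-1)^2] + E[D(fake)^2])."""
    real = astensor(d_y(astensor(y_batch)))
    fake = astensor(d_y(astensor(fake_from_pool)))
    return 0.5 * (mean(square(real - 1.0)) + mean(square(fake)))


# --- image pool ---------------------------------------------------------------

class ImagePool:
    """Buffer of previously generated fakes for discriminator training.

    Below capacity every new fake is stored and returned. At capacity, with
    probability 1/2 the new fake is returned unstored; otherwise a uniformly
    chosen stored image is returned and replaced by the new fake.
    """

    def __init__(self, capacity: int = 50):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.store: list[np.ndarray] = []

    def query(self, new_fake: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        new_fake = np.asarray(new_fake)
        if len(self.store) < self.capacity:
            self.store.append(new_fake.copy())
            return new_fake
        if rng.random() < 0.5:
            return new_fake
        i = int(rng.integers(len(self.store)))
        out = self.store[i]
        self.store[i] = new_fake.copy()
        return out


def pool_sample(pool: ImagePool, new_fake: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    return pool.query(new_fake, rng)


# --- training -----------------------------------------------------------------

def _to_net(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float32 NCHW in [-1, 1]."""
    x = np.asarray(images, dtype=np.float32) / 127.5 - 1.0
    return x.transpose(0, 3, 1, 2)


def _from_net(x: np.ndarray) -> np.ndarray:
    """float NCHW in [-1, 1] -> uint8 (N, H, W, 3), round-half-up."""
    img = (np.asarray(x, dtype=np.float64).transpose(0, 2, 3, 1) + 1.0) * 127.5
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


@dataclass
class CycleGANCheckpoint:
    g_xy: UNetGenerator
    g_yx: UNetGenerator
    d_x: PatchDiscriminator
    d_y: PatchDiscriminator
    config: TrainConfig
    weights: LossWeights
    history: list[dict] = field(default_factory=list)


def _zero(nets) -> None:
    for net in nets:
        for p in net.parameters():
            p.grad = None


def train(fuzzy_images: np.ndarray, reference_images: np.ndarray,
          config: TrainConfig | None = None,
          weights: LossWeights | None = None,
          gen_spec: GeneratorSpec | None = None,
          disc_spec: DiscriminatorSpec | None = None,
          verbose: bool = False) -> CycleGANCheckpoint:
    """Train the Restore-CycleGAN on two unpaired image stacks.

    Per iteration: update G_xy (its full loss, D_y and G_yx fixed), then
    G_yx symmetrically, then D_y and D_x on a random real image and a fake
    drawn from the corresponding pool. Adam(lr, beta1) per the stated
    hyperparameters; weights initialized N(0, init_sd); per-epoch mean losses
    are logged.
    """
    config = config or TrainConfig()
    weights = weights or LossWeights()
    fuzzy_images = np.asarray(fuzzy_images)
    reference_images = np.asarray(reference_images)
    if len(fuzzy_images) == 0 or len(reference_images) == 0:
        raise ValueError("training stacks must be non-empty")

    rng = np.random.default_rng(config.seed)
    image_size = fuzzy_images.shape[1]
    if gen_spec is None or disc_spec is None:
        if config.reduced_scale:
            g_auto, d_auto = reduced_specs(image_size, config.width_divisor,
                                           config.depth)
        else:
            g_auto, d_auto = GeneratorSpec(), DiscriminatorSpec()
        gen_spec = gen_spec or g_auto
        disc_spec = disc_spec or d_auto

    g_xy = UNetGenerator(gen_spec, rng)
    g_yx = UNetGenerator(gen_spec, rng)
    d_y = PatchDiscriminator(disc_spec, rng)
    d_x = PatchDiscriminator(disc_spec, rng)
    nets = (g_xy, g_yx, d_y, d_x)
    opt_gxy = Adam(g_xy.parameters(), config.learning_rate, config.beta1)
    opt_gyx = Adam(g_yx.parameters(), config.learning_rate, config.beta1)
    opt_dy = Adam(d_y.parameters(), config.learning_rate, config.beta1)
    opt_dx = Adam(d_x.parameters(), config.learning_rate, config.beta1)
    pool_y = ImagePool(config.pool_size)
    pool_x = ImagePool(config.pool_size)

    xs = _to_net(fuzzy_images)
    ys = _to_net(reference_images)
    n_iter = max(len(xs), len(ys))
    bs = config.batch_size
    history: list[dict] = []

    for epoch in range(config.epochs):
        order_x = rng.permutation(len(xs))
        order_y = rng.permutation(len(ys))
        sums = {"g_xy": 0.0, "g_yx": 0.0, "d_y": 0.0, "d_x": 0.0}
        n_batches = 0
        for it in range(0, n_iter, bs):
            ix = order_x[[(it + j) % len(xs) for j in range(bs)]]
            iy = order_y[[(it + j) % len(ys) for j in range(bs)]]
            x = Tensor(xs[ix])
            y = Tensor(ys[iy])

            _zero(nets)
            loss_gxy = generator_loss(x, y, g_xy, g_yx, d_y, weights)
            loss_gxy.backward()
            opt_gxy.step()

            _zero(nets)
            loss_gyx = generator_loss(y, x, g_yx, g_xy, d_x, weights)
            loss_gyx.backward()
            opt_gyx.step()

            fake_y = pool_sample(pool_y, g_xy(x).data, rng)
            real_y = Tensor(ys[rng.integers(len(ys), size=bs)])
            _zero(nets)
            loss_dy = discriminator_loss(real_y, Tensor(fake_y), d_y)
            loss_dy.backward()
            opt_dy.step()

            fake_x = pool_sample(pool_x, g_yx(y).data, rng)
            real_x = Tensor(xs[rng.integers(len(xs), size=bs)])
            _zero(nets)
            loss_dx = discriminator_loss(real_x, Tensor(fake_x), d_x)
            loss_dx.backward()
            opt_dx.step()

            sums["g_xy"] += loss_gxy.item()
            sums["g_yx"] += loss_gyx.item()
            sums["d_y"] += loss_dy.item()
            sums["d_x"] += loss_dx.item()
            n_batches += 1
        record = {"epoch": epoch, **{k: v / n_batches for k, v in sums.items()}}
        history.append(record)
        if verbose:
            print(f"epoch {epoch}: " + ", ".join(
                f"{k}={v:.4f}" for k, v in record.items() if k != "epoch"))

    return CycleGANCheckpoint(g_xy=g_xy, g_yx=g_yx, d_x=d_x, d_y=d_y,
                              config=config, weights=weights, history=history)


def translate(image: np.ndarray, generator: UNetGenerator) -> np.ndarray:
    """One forward pass of a trained generator on an 8-bit RGB image."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    out = generator(Tensor(_to_net(image[None])))
    return _from_net(out.data)[0]
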