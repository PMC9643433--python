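"""Multi-conditional GAN for face generation from attribute features.

A DCGAN-style generator maps the feature concatenation
``z = (t_id, t_exp, t_gen)`` to a grayscale image in [-1, 1]; the improved
generator inserts an extra fully-connected layer before the first transposed
convolution and adds a mean-absolute-error term (weight ``lambda_g``) tying
each generated image to its paired real image.  The improved discriminator
adds three attribute heads (identity/expression/gender, sigmoid outputs)
parallel to the realness head; their six binary-cross-entropy terms enter the
discriminator objective with weight ``lambda_d``.  One-sided label smoothing
sets the real-image target to 0.9 (fake targets stay 0).  The four ablation
modes toggle the two improvements independently:

========== ========== ==========
mode       improved G improved D
========== ========== ==========
cgan       no         no
cgan_impD  no         yes
cgan_impG  yes        no
mcgan      yes        yes
========== ========== ==========
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .features import N_EXPRESSIONS, N_GENDERS, AttributeFeatures
from .utils import ConfigurationError

MODES = ("cgan", "cgan_impD", "cgan_impG", "mcgan")
BASE_GRID = 4  # spatial size of the first deconv input


@dataclass
class McGANConfig:
    id_dim: int = 512
    image_size: tuple = (64, 64)
    mode: str = "mcgan"
    lambda_d: float = 20.0
    lambda_g: float = 20.0
    batch_size: int = 16
    real_label: float = 0.9
    epochs: int = 50
    lr: float = 2e-4
    beta1: float = 0.5
    gen_base_channels: int = 128
    gen_fc_dim: int = 256
    disc_channels: tuple = (32, 64, 128, 128)
    bce_targets: str = "features"  # or "onehot"
    #: real images are normalized to [-tanh_headroom, tanh_headroom] rather
    #: than [-1, 1]: with high-contrast stimuli an exact +/-1 target sits at
    #: the tanh asymptote, where the pixel-loss gradient vanishes
    tanh_headroom: float = 0.9

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.lambda_d < 0 or self.lambda_g < 0:
            raise ValueError("lambda weights must be nonnegative")
        h, w = self.image_size
        if h != w or h < 16 or (h & (h - 1)) != 0:
            raise ConfigurationError(
                "image size must be square, a power of two, and at least 16 "
                f"(got {self.image_size})"
            )

    @property
    def z_dim(self):
        return self.id_dim + N_EXPRESSIONS + N_GENDERS

    @property
    def improved_generator(self):
        return self.mode in ("cgan_impG", "mcgan")

    @property
    def improved_discriminator(self):
        return self.mode in ("cgan_impD", "mcgan")

    @classmethod
    def desk_scale(cls, id_dim, image_size=(32, 32), epochs=30, **kwargs):
        defaults = dict(gen_base_channels=32, gen_fc_dim=64, disc_channels=(8, 16, 32, 32), lr=5e-3)
        defaults.update(kwargs)
        return cls(id_dim=id_dim, image_size=image_size, epochs=epochs, **defaults)


class Generator:
    def __init__(self, config: McGANConfig, seed=0):
        self.config = config
        rng = np.random.default_rng(seed)
        size = config.image_size[0]
        n_up = int(np.log2(size // BASE_GRID))
        c = config.gen_base_channels
        layers = []
        if config.improved_generator:
            layers += [nn.Dense(config.z_dim, config.gen_fc_dim, rng, init_std=0.02), nn.ReLU()]
            layers.append(nn.Dense(config.gen_fc_dim, c * BASE_GRID * BASE_GRID, rng, init_std=0.02))
        else:
            layers.append(nn.Dense(config.z_dim, c * BASE_GRID * BASE_GRID, rng, init_std=0.02))
        layers.append(nn.Reshape((c, BASE_GRID, BASE_GRID)))
        for _ in range(n_up - 1):
            layers += [nn.ConvTranspose2d(c, max(c // 2, 8), rng=rng), nn.ReLU()]
            c = max(c // 2, 8)
        layers += [nn.ConvTranspose2d(c, 1, rng=rng), nn.Tanh()]
        self.net = nn.Sequential(layers)

    def forward(self, z, train=False):
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.config.z_dim:
            raise ValueError(f"z has dim {z.shape[1]}, generator expects {self.config.z_dim}")
        return self.net.forward(z, train=train)

    def backward(self, dout):
        return self.net.backward(dout)

    def params_and_grads(self):
        return self.net.params_and_grads()

    def zero_grad(self):
        self.net.zero_grad()


@dataclass
class DiscriminatorOutput:
    realness: np.ndarray
    expression: np.ndarray | None = None
    identity: np.ndarray | None = None
    gender: np.ndarray | None = None

    @property
    def heads(self):
        return {"identity": self.identity, "expression": self.expression, "gender": self.gender}


class Discriminator:
    """Four-conv-stage trunk with a realness head and, in improved modes,
    three parallel attribute heads."""

    def __init__(self, config: McGANConfig, seed=0):
        self.config = config
        rng = np.random.default_rng(seed)
        size = config.image_size[0]
        layers, c_in = [], 1
        for c in config.disc_channels:
            layers += [nn.Conv2d(c_in, c, 4, 2, 1, rng=rng, init_std=0.02), nn.LeakyReLU(0.2)]
            c_in = c
        layers.append(nn.Flatten())
        self.trunk = nn.Sequential(layers)
        flat = config.disc_channels[-1] * (size // 16) ** 2
        self.heads = {"realness": nn.Sequential([nn.Dense(flat, 1, rng, init_std=0.02), nn.Sigmoid()])}
        if config.improved_discriminator:
            for name, dim in (
                ("identity", config.id_dim),
                ("expression", N_EXPRESSIONS),
                ("gender", N_GENDERS),
            ):
                self.heads[name] = nn.Sequential([nn.Dense(flat, dim, rng, init_std=0.02), nn.Sigmoid()])

    def forward(self, x, train=False):
        if x.shape[2:] != tuple(self.config.image_size):
            raise ValueError(f"input image size {x.shape[2:]} does not match {self.config.image_size}")
        h = self.trunk.forward(x, train=train)
        out = {name: head.forward(h, train=train) for name, head in self.heads.items()}
        return DiscriminatorOutput(
            realness=out["realness"][:, 0],
            expression=out.get("expression"),
            identity=out.get("identity"),
            gender=out.get("gender"),
        )

    def backward(self, d_realness, d_heads=None):
        dh = self.heads["realness"].backward(d_realness[:, None])
        if d_heads:
            for name, grad in d_heads.items():
                dh = dh + self.heads[name].backward(grad)
        return self.trunk.backward(dh)

    def params_and_grads(self):
        yield from (("trunk." + n, v, g, wd) for n, v, g, wd in self.trunk.params_and_grads())
        for name, head in self.heads.items():
            yield from ((f"{name}.{n}", v, g, wd) for n, v, g, wd in head.params_and_grads())

    def zero_grad(self):
        self.trunk.zero_grad()
        for head in self.heads.values():
            head.zero_grad()


def build_generator(config: McGANConfig, seed=0) -> Generator:
    return Generator(config, seed=seed)


def save_generator(gen: Generator, path):
    """Checkpoint: npz of weights plus a JSON config manifest alongside."""
    import dataclasses
    import json
    from pathlib import Path

    arrays = {n: v for n, v, _, _ in gen.params_and_grads()}
    np.savez(path, **arrays)
    Path(str(path) + ".json").write_text(json.dumps(dataclasses.asdict(gen.config), indent=2, default=list))


def load_generator(path) -> Generator:
    import json
    from pathlib import Path

    cfg = json.loads(Path(str(path) + ".json").read_text())
    for key in ("image_size", "disc_channels"):
        cfg[key] = tuple(cfg[key])
    gen = Generator(McGANConfig(**cfg))
    data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
    for n, v, _, _ in gen.params_and_grads():
        v[...] = data[n]
    return gen


def build_discriminator(config: McGANConfig, seed=0) -> Discriminator:
    return Discriminator(config, seed=seed)


def _validate_targets(targets):
    for name, t in targets.items():
        t = np.asarray(t, dtype=float)
        if t.min() < 0.0 or t.max() > 1.0:
            raise ValueError(f"{name} targets must lie in [0, 1]")


def discriminator_loss(real_out, fake_out, targets=None, lambda_d=20.0, real_target=0.9):
    """Value of the discriminator objective (maximization form).

    Adversarial part: E[log D(x)] + E[log(1 - D(G(z)))], with one-sided label
    smoothing folded into the real term as a BCE against ``real_target``
    (``real_target=1`` recovers the un-smoothed objective exactly).  In
    improved modes, minus ``lambda_d`` times the sum of the six attribute BCE
    terms (three heads, each on real and generated images).
    """
    p_real = np.asarray(real_out.realness, dtype=float)
    p_fake = np.asarray(fake_out.realness, dtype=float)
    adv = -nn.bce(p_real, real_target) - nn.bce(p_fake, 0.0)
    if targets is None or lambda_d == 0.0:
        penalty = 0.0
    else:
        _validate_targets(targets)
        penalty = 0.0
        for name, t in targets.items():
            penalty += nn.bce(real_out.heads[name], t) + nn.bce(fake_out.heads[name], t)
    return float(adv - lambda_d * penalty)


def generator_loss(fake_out, generated, real, lambda_g=20.0):
    """Value of the generator objective (minimized):
    E[log(1 - D(G(z)))] + lambda_g * MAE(G(z), x)."""
    generated, real = np.asarray(generated, float), np.asarray(real, float)
    if generated.shape != real.shape:
        raise ValueError(f"shape mismatch: {generated.shape} vs {real.shape}")
    p_fake = np.clip(np.asarray(fake_out.realness, dtype=float), nn.losses.EPS, 1 - nn.losses.EPS)
    adv = float(np.mean(np.log(1.0 - p_fake)))
    return adv + lambda_g * nn.mae(generated, real)


def _targets_from_features(features: AttributeFeatures, config: McGANConfig, id_labels=None):
    """Attribute-head BCE targets in [0,1]: softmax blocks pass through,
    identity features are sigmoid-squashed (or one-hot in 'onehot' mode)."""
    if config.bce_targets == "onehot":
        t_exp = np.eye(N_EXPRESSIONS)[features.t_exp.argmax(axis=1)]
        t_gen = np.eye(N_GENDERS)[features.t_gen.argmax(axis=1)]
        if id_labels is not None:
            t_id = np.eye(config.id_dim)[np.asarray(id_labels, dtype=int)]
        else:
            t_id = 1.0 / (1.0 + np.exp(-features.t_id))
    else:
        t_exp = np.clip(features.t_exp, 0.0, 1.0)
        t_gen = np.clip(features.t_gen, 0.0, 1.0)
        t_id = 1.0 / (1.0 + np.exp(-features.t_id))
    return {"identity": t_id, "expression": t_exp, "gender": t_gen}


def train_mcgan(images, features: AttributeFeatures, config: McGANConfig, seed=0, id_labels=None):
    """Alternating discriminator/generator updates (Adam, DCGAN settings).

    ``images`` are 0-255 grayscale arrays paired row-wise with ``features``.
    Returns the trained generator, the discriminator and a per-epoch log of
    the two objective values and the reconstruction MAE.
    """
    images = np.asarray(images)
    if len(images) != len(features):
        raise ValueError(f"{len(images)} images but {len(features)} feature rows")
    if images.shape[1:] != tuple(config.image_size):
        raise ValueError(f"image size {images.shape[1:]} does not match config {config.image_size}")
    x_all = ((images.astype(float) / 127.5 - 1.0) * config.tanh_headroom)[:, None]
    z_all = features.z
    targets_all = _targets_from_features(features, config, id_labels=id_labels) if config.improved_discriminator else None

    generator = Generator(config, seed=seed + 1)
    discriminator = Discriminator(config, seed=seed + 2)
    opt_g = nn.Adam(lr=config.lr, beta1=config.beta1)
    opt_d = nn.Adam(lr=config.lr, beta1=config.beta1)
    rng = np.random.default_rng(seed + 3)

    log = {"d_loss": [], "g_loss": [], "mae": []}
    n = len(images)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        d_vals, g_vals, maes = [], [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, zb = x_all[idx], z_all[idx]
            tb = {k: v[idx] for k, v in targets_all.items()} if targets_all else None

            # discriminator step (gradient ascent on the printed objective)
            discriminator.zero_grad()
            real_out = discriminator.forward(xb, train=True)
            d_real_grad = nn.bce_grad(real_out.realness, config.real_label)
            d_head_grads = None
            if tb is not None:
                d_head_grads = {k: config.lambda_d * nn.bce_grad(real_out.heads[k], tb[k]) for k in tb}
            discriminator.backward(d_real_grad, d_head_grads)

            g_imgs = generator.forward(zb, train=False)
            fake_out = discriminator.forward(g_imgs, train=True)
            d_fake_grad = nn.bce_grad(fake_out.realness, 0.0)
            d_head_grads = None
            if tb is not None:
                d_head_grads = {k: config.lambda_d * nn.bce_grad(fake_out.heads[k], tb[k]) for k in tb}
            discriminator.backward(d_fake_grad, d_head_grads)
            opt_d.step(discriminator)
            d_vals.append(discriminator_loss(real_out, fake_out, tb, config.lambda_d, config.real_label))

            # generator step
            generator.zero_grad()
            g_imgs = generator.forward(zb, train=True)
            fake_out = discriminator.forward(g_imgs, train=False)
            # d[mean log(1 - p)]/dp = -bce_grad(p, 0)
            dx = discriminator.backward(-nn.bce_grad(fake_out.realness, 0.0))
            if config.improved_generator and config.lambda_g > 0:
                dx = dx + config.lambda_g * nn.mae_grad(g_imgs, xb)
            generator.backward(dx)
            opt_g.step(generator)
            lam_g = config.lambda_g if config.improved_generator else 0.0
            g_vals.append(generator_loss(fake_out, g_imgs, xb, lam_g))
            maes.append(nn.mae(g_imgs, xb))
        log["d_loss"].append(float(np.mean(d_vals)))
        log["g_loss"].append(float(np.mean(g_vals)))
        log["mae"].append(float(np.mean(maes)))
    return generator, discriminator, log


def reconstruct(generator: Generator, features) -> np.ndarray:
    """Generate 8-bit grayscale images from attribute features."""
    z = features.z if isinstance(features, AttributeFeatures) else np.atleast_2d(np.asarray(features, float))
    out = generator.forward(z, train=False)[:, 0]
    out = np.clip(out / generator.config.tanh_headroom, -1.0, 1.0)
    return np.clip(np.rint((out + 1.0) * 127.5), 0, 255).astype(np.uint8)
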