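"""DNPAD: adversarial prediction of delayed RF from pre-delay RF.

The network replaces explicit time-of-flight delay computation: a U-Net
generator maps each pre-delay scanline section (receive-channel x axial
sample) directly to its properly delayed counterpart, trained adversarially
against a convolutional discriminator (a conditional image-to-image setup).
Channel summation of the predicted cube then yields the B-mode image exactly
as in the conventional delay-and-sum tail.

The generator loss is ``BCE(D(x, G(x)), real) + lambda_l1 * |G(x) - y|_1``
with ``lambda_l1 = 10``; the discriminator minimizes BCE on real/fake pairs.
Training uses Adam (beta1 = 0.5, beta2 = 0.999), initial learning rate 1e-4
with cosine annealing, batch size 4, and one of three input-noise variants:
INO (no injected noise), GN0.001, or GN0.01 (Gaussian noise of that std
added to the normalized pre-delay input only).

Usage follows the model/results idiom::

    model = DNPADModel(split, train_config=TrainConfig(epochs=30, ...))
    res = model.fit()
    print(res.summary())
    image = res.reconstruct(pre_delay_tensor)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .beamform import BModeImage, DelayedRFCube, envelope_log
from .dataset import DatasetSplit, NoiseConfig, PairedSample, add_gaussian_noise
from .nn import Adam, PatchDiscriminator, UNetGenerator, bce_loss, cosine_lr, l1_loss

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "TrainConfig",
    "TrainHistory",
    "build_generator",
    "build_discriminator",
    "generator_loss",
    "DNPADModel",
    "DNPADResults",
    "predict_cube",
    "dnn_reconstruct",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """U-Net generator hyperparameters.

    ``levels`` is fixed at 3 (the implemented encoder depth); with the
    default ``base_channels = 64`` and ``max_channels = 512`` the encoder
    widens 1 -> 64 -> 128 -> 256 with a 512-channel bottleneck, taking a
    128 x 1024 section down to 16 x 128.
    """

    levels: int = 3
    base_channels: int = 64
    max_channels: int = 512
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.levels != 3:
            raise ValueError("the generator implements exactly 3 levels")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Conditional discriminator hyperparameters.

    Five 4x4 convolutional layers; ``conditional`` concatenates the
    pre-delay input with the candidate output (2 input channels) as is
    standard for paired image-to-image adversarial training.
    """

    n_layers: int = 5
    base_channels: int = 64
    max_channels: int = 512
    conditional: bool = True

    def __post_init__(self) -> None:
        if self.n_layers != 5:
            raise ValueError("the discriminator implements exactly 5 conv layers")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one training variant."""

    lr: float = 1e-4
    betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 4
    epochs: int = 100
    lambda_l1: float = 10.0
    noise: NoiseConfig = field(default_factory=NoiseConfig.ino)
    label_smoothing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


@dataclass
class TrainHistory:
    """Per-epoch loss trajectory."""

    g_total: list = field(default_factory=list)
    g_l1: list = field(default_factory=list)  # unweighted mean |pred - target|
    g_adv: list = field(default_factory=list)
    d_loss: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    lr: list = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.g_total)


def build_generator(cfg: GeneratorConfig, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(cfg.base_channels, cfg.in_channels, cfg.max_channels,
                         seed=seed)


def build_discriminator(cfg: DiscriminatorConfig, seed: int = 0) -> PatchDiscriminator:
    in_ch = 2 if cfg.conditional else 1
    return PatchDiscriminator(in_ch, cfg.base_channels, cfg.max_channels,
                              seed=seed)


def generator_loss(pred, target, disc_score, lambda_l1: float = 10.0):
    """Adversarial + weighted L1 generator objective.

    Returns ``(total, {"adv": ..., "l1": ...})`` where the L1 component is
    the unweighted mean absolute error and the total is
    ``BCE(disc_score, 1) + lambda_l1 * l1``.
    """
    adv, _ = bce_loss(np.asarray(disc_score), 1.0)
    l1, _ = l1_loss(pred, target)
    return adv + lambda_l1 * l1, {"adv": adv, "l1": l1}


def _scanline_batches(samples: list[PairedSample]):
    """Flatten paired samples into per-scanline (input, target) 2-D arrays."""
    xs, ys = [], []
    for p in samples:
        for s in range(p.n_scanlines):
            x, y = p.scanline(s)
            xs.append(np.asarray(x, dtype=np.float64))
            ys.append(np.asarray(y, dtype=np.float64))
    return np.stack(xs)[:, None], np.stack(ys)[:, None]  # (N, 1, H, W)


def predict_cube(generator: UNetGenerator, pre_delay: np.ndarray,
                 batch_size: int = 8) -> DelayedRFCube:
    """Run the generator on every scanline of a pre-delay tensor.

    ``pre_delay`` has shape (n_focal, n_channels, n_scanlines) in [0, 1];
    the prediction is reassembled into the same layout.
    """
    pre = np.asarray(pre_delay, dtype=np.float64)
    n_f, n_ch, n_s = pre.shape
    x = np.transpose(pre, (2, 1, 0))[:, None]  # (n_s, 1, n_ch, n_f)
    out = np.empty_like(x)
    for i in range(0, n_s, batch_size):
        out[i:i + batch_size] = generator.forward(x[i:i + batch_size],
                                                  training=False)
    return DelayedRFCube(np.transpose(out[:, 0], (2, 1, 0)), radius_tag="predicted")


def dnn_reconstruct(generator: UNetGenerator, pre_delay: np.ndarray,
                    dynamic_range: float = 60.0,
                    value_range: tuple[float, float] | None = None) -> BModeImage:
    """Predict the delayed cube and finish with the conventional tail
    (channel summation, envelope detection, log compression).

    ``value_range`` is the (min, max) recorded when the target cube was
    normalized to [0, 1]; when given, the prediction is mapped back to
    physical RF amplitudes before summation.  Without it the [0, 1] offset
    dominates the channel sum and the image degenerates toward a flat field.
    """
    cube = predict_cube(generator, pre_delay)
    values = cube.values
    if value_range is not None:
        lo, hi = value_range
        values = values * (hi - lo) + lo
    return envelope_log(values.sum(axis=1), dynamic_range)


def pair_reconstruction_mse(generator: UNetGenerator, pair: PairedSample,
                            dynamic_range: float = 60.0) -> float:
    """Image-domain MSE of the predicted reconstruction against the
    delay-and-sum reference of the ground-truth cube.

    Both cubes are mapped back through the pair's recorded normalization
    range so the comparison happens on physical RF amplitudes.
    """
    from .spectral import mse

    lo, hi = pair.meta.get("post_range", (0.0, 1.0))
    ref_rf = (pair.post_delay * (hi - lo) + lo).sum(axis=1)
    ref = envelope_log(ref_rf, dynamic_range)
    img = dnn_reconstruct(generator, pair.pre_delay, dynamic_range, (lo, hi))
    return mse(ref.pixels, img.pixels)


class DNPADModel:
    """Adversarial delay-prediction model bound to a dataset split.

    Parameters
    ----------
    split : DatasetSplit
        Paired samples; ``train`` drives the updates, ``val`` (if non-empty)
        is scored with prediction MSE once per epoch.
    gen_config, disc_config, train_config : optional
        Architecture and optimization settings; defaults follow the study
        configuration (see module docstring).
    """

    def __init__(self, split: DatasetSplit,
                 gen_config: GeneratorConfig | None = None,
                 disc_config: DiscriminatorConfig | None = None,
                 train_config: TrainConfig | None = None):
        if not split.train:
            raise ValueError("training split is empty")
        if not all(isinstance(s, PairedSample) for s in split.train):
            raise TypeError("DNPADModel requires in-memory PairedSample splits")
        self.split = split
        self.gen_config = gen_config or GeneratorConfig()
        self.disc_config = disc_config or DiscriminatorConfig()
        self.train_config = train_config or TrainConfig()

    def with_noise(self, noise: NoiseConfig) -> "DNPADModel":
        """Same model with a different input-noise variant (INO/GN presets);
        architecture, seeds and schedule are untouched."""
        return DNPADModel(self.split, self.gen_config, self.disc_config,
                          replace(self.train_config, noise=noise))

    def fit(self, callback=None) -> "DNPADResults":
        """Train the generator/discriminator pair and return results.

        Alternates one discriminator and one generator update per batch.
        Injected input noise (per the configured variant) is applied to the
        pre-delay input only; targets stay clean.  Fully deterministic under
        the configured seed.  Raises ``RuntimeError`` on divergence (NaN
        loss).
        """
        tc = self.train_config
        gen = build_generator(self.gen_config, seed=tc.seed)
        disc = build_discriminator(self.disc_config, seed=tc.seed + 1)
        g_opt = Adam(gen.params(), tc.lr, tc.betas)
        d_opt = Adam(disc.params(), tc.lr, tc.betas)
        rng = np.random.default_rng(tc.seed + 2)
        noise_rng = np.random.default_rng(tc.seed + 3)

        x_all, y_all = _scanline_batches(self.split.train)
        n = x_all.shape[0]
        val = self.split.val if all(isinstance(s, PairedSample)
                                    for s in self.split.val) else []
        history = TrainHistory()
        real_label = 1.0 - tc.label_smoothing
        conditional = self.disc_config.conditional

        def d_input(x, cand):
            return np.concatenate([x, cand], axis=1) if conditional else cand

        for epoch in range(tc.epochs):
            lr = cosine_lr(tc.lr, epoch, tc.epochs)
            g_opt.lr = d_opt.lr = lr
            order = rng.permutation(n)
            ep = {"adv": 0.0, "l1": 0.0, "total": 0.0, "d": 0.0}
            n_batches = 0
            for i in range(0, n, tc.batch_size):
                idx = order[i:i + tc.batch_size]
                x = x_all[idx]
                y = y_all[idx]
                x = add_gaussian_noise(x, tc.noise, rng=noise_rng)

                fake = gen.forward(x, training=True)

                # discriminator update
                d_opt.zero_grad()
                p_real = disc.forward(d_input(x, y))
                loss_real, g_real = bce_loss(p_real, real_label)
                disc.backward(g_real)
                p_fake = disc.forward(d_input(x, fake))
                loss_fake, g_fake = bce_loss(p_fake, 0.0)
                disc.backward(g_fake)
                d_opt.step()
                d_loss = 0.5 * (loss_real + loss_fake)

                # generator update (fresh discriminator opinion of the fake)
                g_opt.zero_grad()
                d_opt.zero_grad()
                p_gen = disc.forward(d_input(x, fake))
                adv, g_adv = bce_loss(p_gen, 1.0)
                g_into = disc.backward(g_adv)
                grad_fake = g_into[:, 1:2] if conditional else g_into
                l1, g_l1 = l1_loss(fake, y)
                gen.backward(grad_fake + tc.lambda_l1 * g_l1)
                g_opt.step()

                total = adv + tc.lambda_l1 * l1
                if not np.isfinite(total) or not np.isfinite(d_loss):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: "
                        f"G loss {total}, D loss {d_loss}"
                    )
                ep["adv"] += adv
                ep["l1"] += l1
                ep["total"] += total
                ep["d"] += d_loss
                n_batches += 1

            history.g_total.append(ep["total"] / n_batches)
            history.g_adv.append(ep["adv"] / n_batches)
            history.g_l1.append(ep["l1"] / n_batches)
            history.d_loss.append(ep["d"] / n_batches)
            history.lr.append(lr)
            history.val_mse.append(self._val_mse(gen, val))
            logger.info(
                "epoch %d/%d  G=%.4f (L1 %.4f, adv %.4f)  D=%.4f  val MSE=%s",
                epoch + 1, tc.epochs, history.g_total[-1], history.g_l1[-1],
                history.g_adv[-1], history.d_loss[-1], history.val_mse[-1],
            )
            if callback is not None:
                callback(epoch, history)

        return DNPADResults(self, gen, disc, history)

    @staticmethod
    def _val_mse(gen: UNetGenerator, val: list) -> float | None:
        if not val:
            return None
        se, count = 0.0, 0
        for p in val:
            pred = predict_cube(gen, p.pre_delay)
            se += float(((pred.values - p.post_delay) ** 2).sum())
            count += p.post_delay.size
        return se / count


@dataclass
class DNPADResults:
    """Fitted DNPAD model: trained networks plus the training trajectory."""

    model: DNPADModel
    generator: UNetGenerator
    discriminator: PatchDiscriminator
    history: TrainHistory

    def predict(self, pre_delay: np.ndarray) -> DelayedRFCube:
        """Predicted delayed-RF cube for a normalized pre-delay tensor."""
        return predict_cube(self.generator, pre_delay)

    def reconstruct(self, pre_delay: np.ndarray,
                    dynamic_range: float = 60.0,
                    value_range: tuple[float, float] | None = None) -> BModeImage:
        """B-mode image from the predicted cube (sum + envelope + log)."""
        return dnn_reconstruct(self.generator, pre_delay, dynamic_range,
                               value_range)

    def summary(self) -> str:
        h = self.history
        tc = self.model.train_config
        lines = [
            "DNPAD adversarial delay-prediction model",
            "=" * 44,
            f"variant:            {tc.noise.label}",
            f"epochs:             {h.n_epochs}",
            f"batch size:         {tc.batch_size}",
            f"lr (init, cosine):  {tc.lr:g}",
            f"lambda_L1:          {tc.lambda_l1:g}",
            f"train scanlines:    "
            f"{sum(p.n_scanlines for p in self.model.split.train)}",
            f"final G loss:       {h.g_total[-1]:.4f}",
            f"final L1 term:      {h.g_l1[-1]:.4f}",
            f"final D loss:       {h.d_loss[-1]:.4f}",
        ]
        if h.val_mse[-1] is not None:
            lines.append(f"final val MSE:      {h.val_mse[-1]:.6f}")
        return "\n".join(lines)
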