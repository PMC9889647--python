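"""Conditional GAN mapping a BEV dose map to a 6-channel aperture stack.

A pix2pix-style setup: the generator is a U-Net with six stride-2
down-sampling blocks (4x4 convolution, batch norm, leaky ReLU), mirrored
transposed-convolution up-sampling blocks with skip connections, and
dropout as the noise source; the discriminator is a 70x70 PatchGAN with
spectral normalization, scoring patches of the (dose map, aperture stack)
pair as real or synthetic.  The discriminator minimizes binary
cross-entropy against soft, occasionally flipped labels; the generator
minimizes the adversarial term plus ``lambda_l1`` times the mean absolute
error to the ground-truth stack.

Everything — convolutions, backpropagation, Adam, spectral normalization —
is implemented on numpy, so training is deterministic for a fixed seed.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LeafSeqError
from .preprocessing import ApertureStack, DoseMap2D, N_CHANNELS, TrainingSet


class TrainingError(LeafSeqError):
    pass


# ---------------------------------------------------------------------------
# Configuration and cohort splits
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training protocol. Defaults follow the published protocol where it
    is stated (200 epochs, Adam beta_1 = 0.5, soft labels in [0, 1.2],
    spectral normalization) and this package's declared choices where it
    is not (learning rate 2e-4, lambda_l1 = 100, label sub-ranges,
    batch size 1)."""

    epochs: int = 200
    learning_rate: float = 2e-4
    beta_1: float = 0.5
    lambda_l1: float = 100.0
    soft_real: tuple[float, float] = (0.8, 1.2)
    soft_fake: tuple[float, float] = (0.0, 0.2)
    label_flip: float = 0.05
    dropout: float = 0.5
    batch_size: int = 1
    gen_filters: int = 64
    disc_filters: int = 64
    n_down: int = 6
    image_size: int = 128
    seed: int = 0
    # snapshot selection on training-set delivery fidelity (0 = off,
    # keep the final-epoch weights)
    checkpoint_every: int = 0
    checkpoint_beams: int = 8
    # exponential moving average of generator weights (0 = off); damps
    # the adversarial oscillation of individual snapshots
    ema_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0:
            raise ValueError("rates and epochs must be positive")
        if not 0 <= self.label_flip < 0.5:
            raise ValueError("label-flip probability must be < 0.5")
        if not self.dropout > 0:
            raise ValueError("dropout is the generator's noise source and "
                             "must be positive")


@dataclass
class CohortSplit:
    """Patient-based leave-one-out split that retains one fraction of the
    held-out patient in training (the prior-plan the model replans from)."""

    held_out_patient: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    retained_fraction: int = 1


def make_loocv_splits(meta: pd.DataFrame,
                      retained_fraction: int = 1) -> list[CohortSplit]:
    """One split per patient: train on all beams of the other patients
    plus the retained fraction of the held-out patient; test on the
    held-out patient's remaining fractions."""
    patients = sorted(meta["patient"].unique())
    if len(patients) < 2:
        raise TrainingError("leave-one-out needs at least 2 patients")
    splits = []
    for pid in patients:
        mine = meta["patient"] == pid
        fractions = sorted(meta.loc[mine, "fraction"].unique())
        if len(fractions) < 2:
            raise TrainingError(
                f"patient {pid} has {len(fractions)} fraction(s); "
                "at least 2 are needed to hold fractions out")
        test = mine & (meta["fraction"] != retained_fraction)
        splits.append(CohortSplit(
            held_out_patient=pid,
            train_idx=np.flatnonzero(~test.to_numpy()),
            test_idx=np.flatnonzero(test.to_numpy()),
            retained_fraction=retained_fraction))
    return splits


# ---------------------------------------------------------------------------
# Losses and labels
# ---------------------------------------------------------------------------

_EPS = 1e-7


def binary_cross_entropy(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy of patch scores against (possibly soft)
    labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError(f"score shape {scores.shape} != label shape "
                         f"{labels.shape}")
    p = np.clip(scores, _EPS, 1.0 - _EPS)
    return float(np.mean(-labels * np.log(p) - (1 - labels) * np.log(1 - p)))


def binary_cross_entropy_grad(scores: np.ndarray,
                              labels: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`binary_cross_entropy` w.r.t. scores."""
    p = np.clip(np.asarray(scores, dtype=float), _EPS, 1.0 - _EPS)
    return (-labels / p + (1 - labels) / (1 - p)) / p.size


def cgan_loss(d_real_scores: np.ndarray, d_fake_scores: np.ndarray,
              real_labels=None, fake_labels=None) -> float:
    """The adversarial objective the discriminator minimizes: cross
    entropy of real-pair scores against real labels plus fake-pair scores
    against fake labels (the log D(x,y) + log(1 - D(x,G(x))) structure)."""
    d_real_scores = np.asarray(d_real_scores, dtype=float)
    d_fake_scores = np.asarray(d_fake_scores, dtype=float)
    if real_labels is None:
        real_labels = np.ones_like(d_real_scores)
    if fake_labels is None:
        fake_labels = np.zeros_like(d_fake_scores)
    return (binary_cross_entropy(d_real_scores, real_labels)
            + binary_cross_entropy(d_fake_scores, fake_labels))


def generator_objective(adv: float, l1: float, lambda_l1: float) -> float:
    """Adversarial term plus lambda times the L1 reconstruction error."""
    if lambda_l1 < 0:
        raise ValueError("lambda_l1 must be non-negative")
    return float(adv) + float(lambda_l1) * float(l1)


def make_labels(rng: np.random.Generator, shape, kind: str,
                config: TrainConfig) -> np.ndarray:
    """Soft labels (uniform over the real/fake sub-range) with a
    per-sample chance of being flipped to the other kind."""
    if kind not in ("real", "fake"):
        raise ValueError(f"label kind must be 'real' or 'fake', got {kind!r}")
    lo_r, hi_r = config.soft_real
    lo_f, hi_f = config.soft_fake
    n = shape[0]
    flip = rng.random(n) < config.label_flip
    use_real = (kind == "real") ^ flip
    out = np.empty(shape, dtype=float)
    for i in range(n):
        lo, hi = (lo_r, hi_r) if use_real[i] else (lo_f, hi_f)
        out[i] = rng.uniform(lo, hi, shape[1:])
    return out


# ---------------------------------------------------------------------------
# Numpy layers
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


def _im2col(x: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for a in range(k):
        for b in range(k):
            cols[:, :, a, b] = xp[:, :, a:a + s * ho:s, b:b + s * wo:s]
    return cols.reshape(n, c * k * k, ho * wo)


def _col2im(cols: np.ndarray, out_hw: tuple[int, int], c: int,
            k: int, s: int, p: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`."""
    n = cols.shape[0]
    h, w = out_hw
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    for a in range(k):
        for b in range(k):
            xp[:, :, a:a + s * ho:s, b:b + s * wo:s] += cols[:, :, a, b]
    return xp[:, :, p:p + h, p:p + w]


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train, rng):
        raise NotImplementedError

    def backward(self, gy):
        raise NotImplementedError


class Conv2d(Layer):
    """4x4 convolution with optional spectral normalization (one power
    iteration per training step; gradients treat the singular vectors as
    constants, the standard approximation)."""

    def __init__(self, cin, cout, rng, k=4, s=2, p=1, spectral_norm=False):
        self.cin, self.cout, self.k, self.s, self.p = cin, cout, k, s, p
        self.w = Param(rng.normal(0.0, 0.02, (cout, cin * k * k)).astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self.sn = spectral_norm
        if spectral_norm:
            self.u = rng.normal(0.0, 1.0, cout).astype(np.float32)
            self.u /= np.linalg.norm(self.u) + 1e-12

    def params(self):
        return [self.w, self.b]

    def _w_eff(self, train):
        if not self.sn:
            return self.w.value, 1.0
        wm = self.w.value
        if train:
            v = wm.T @ self.u
            v /= np.linalg.norm(v) + 1e-12
            u = wm @ v
            u /= np.linalg.norm(u) + 1e-12
            self.u = u
        v = wm.T @ self.u
        sigma = float(np.linalg.norm(v)) + 1e-12
        self._v = v / sigma
        self._sigma = sigma
        return wm / sigma, sigma

    def forward(self, x, train, rng):
        self.x_shape = x.shape
        self.cols = _im2col(x, self.k, self.s, self.p)
        w_eff, _ = self._w_eff(train)
        self._w_used = w_eff
        n = x.shape[0]
        h, w = x.shape[2], x.shape[3]
        self.ho = (h + 2 * self.p - self.k) // self.s + 1
        self.wo = (w + 2 * self.p - self.k) // self.s + 1
        y = w_eff @ self.cols + self.b.value[None, :, None]
        return y.reshape(n, self.cout, self.ho, self.wo)

    def backward(self, gy):
        n = gy.shape[0]
        gyf = gy.reshape(n, self.cout, -1)
        dw_eff = np.matmul(gyf, self.cols.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += gyf.sum(axis=(0, 2))
        if self.sn:
            # d(W/sigma)/dW with u, v held fixed
            coeff = float(np.sum(dw_eff * self._w_used)) / self._sigma
            self.w.grad += dw_eff / self._sigma - coeff * np.outer(
                self.u, self._v)
        else:
            self.w.grad += dw_eff
        dcols = np.matmul(self._w_used.T, gyf)
        return _col2im(dcols, self.x_shape[2:], self.cin,
                       self.k, self.s, self.p)


class ConvTranspose2d(Layer):
    """Stride-2 4x4 transposed convolution (doubles spatial size)."""

    def __init__(self, cin, cout, rng, k=4, s=2, p=1):
        self.cin, self.cout, self.k, self.s, self.p = cin, cout, k, s, p
        self.w = Param(rng.normal(0.0, 0.02, (cin, cout * k * k)).astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train, rng):
        n, c, h, w = x.shape
        self.in_hw = (h, w)
        self.x_flat = x.reshape(n, c, h * w)
        self.out_hw = (self.s * (h - 1) + self.k - 2 * self.p,
                       self.s * (w - 1) + self.k - 2 * self.p)
        cols = np.matmul(self.w.value.T, self.x_flat)
        y = _col2im(cols, self.out_hw, self.cout, self.k, self.s, self.p)
        return y + self.b.value[None, :, None, None]

    def backward(self, gy):
        n = gy.shape[0]
        gycols = _im2col(gy, self.k, self.s, self.p)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        self.w.grad += np.matmul(self.x_flat, gycols.transpose(0, 2, 1)).sum(axis=0)
        dx = np.matmul(self.w.value, gycols)
        return dx.reshape(n, self.cin, *self.in_hw)


class BatchNorm2d(Layer):
    """Normalizes over batch and space with batch statistics in both
    training and inference (deterministic, instance-norm-like behaviour
    at batch size 1)."""

    def __init__(self, c, eps=1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train, rng):
        self.mu = x.mean(axis=(0, 2, 3), keepdims=True)
        self.var = x.var(axis=(0, 2, 3), keepdims=True)
        self.xhat = (x - self.mu) / np.sqrt(self.var + self.eps)
        self.n = x.shape[0] * x.shape[2] * x.shape[3]
        return self.gamma.value[None, :, None, None] * self.xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, gy):
        self.gamma.grad += (gy * self.xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        gx_hat = gy * g
        inv = 1.0 / np.sqrt(self.var + self.eps)
        return inv / self.n * (self.n * gx_hat
                               - gx_hat.sum(axis=(0, 2, 3), keepdims=True)
                               - self.xhat * (gx_hat * self.xhat).sum(
                                   axis=(0, 2, 3), keepdims=True))


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        self.alpha = alpha

    def forward(self, x, train, rng):
        self.mask = x >= 0
        return np.where(self.mask, x, self.alpha * x)

    def backward(self, gy):
        return np.where(self.mask, gy, self.alpha * gy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Dropout(Layer):
    def __init__(self, p):
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p <= 0:
            self.mask = None
            return x
        self.mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self.mask

    def backward(self, gy):
        return gy if self.mask is None else gy * self.mask


def _chain_forward(layers, x, train, rng):
    for lay in layers:
        x = lay.forward(x, train, rng)
    return x


def _chain_backward(layers, gy):
    for lay in reversed(layers):
        gy = lay.backward(gy)
    return gy


# ---------------------------------------------------------------------------
# Generator / discriminator
# ---------------------------------------------------------------------------

class Generator:
    """U-Net with stride-2 4x4 down blocks, transposed-conv up blocks,
    skip connections, and dropout on the innermost up blocks."""

    def __init__(self, rng, in_ch=1, out_ch=N_CHANNELS, nf=64, n_down=6,
                 dropout=0.5, image_size=128):
        n_down = min(n_down, int(np.log2(image_size)))
        self.n_down = n_down
        widths = [min(2 ** i, 8) * nf for i in range(n_down)]
        self.downs = []
        cin = in_ch
        for i, w in enumerate(widths):
            block = [Conv2d(cin, w, rng)]
            if i > 0:
                block.append(BatchNorm2d(w))
            block.append(LeakyReLU(0.2))
            self.downs.append(block)
            cin = w
        self.ups = []
        for i in range(n_down - 1):
            skip_ch = widths[n_down - 2 - i]
            cout = skip_ch
            block = [ConvTranspose2d(cin, cout, rng), BatchNorm2d(cout)]
            if i < 3:
                block.append(Dropout(dropout))
            block.append(ReLU())
            self.ups.append(block)
            cin = cout + skip_ch
        self.final = [ConvTranspose2d(cin, out_ch, rng)]

    def layers(self):
        for b in self.downs + self.ups + [self.final]:
            yield from b

    def params(self):
        return [p for lay in self.layers() for p in lay.params()]

    def forward(self, x, train, rng):
        skips = []
        for block in self.downs:
            x = _chain_forward(block, x, train, rng)
            skips.append(x)
        self._skip_ch = [s.shape[1] for s in skips]
        x = skips[-1]
        for i, block in enumerate(self.ups):
            x = _chain_forward(block, x, train, rng)
            x = np.concatenate([x, skips[-2 - i]], axis=1)
        return _chain_forward(self.final, x, train, rng)

    def backward(self, gy):
        gy = _chain_backward(self.final, gy)
        skip_grads = [None] * self.n_down
        for i in range(len(self.ups) - 1, -1, -1):
            up_ch = self.ups[i][0].cout
            g_up, g_skip = gy[:, :up_ch], gy[:, up_ch:]
            skip_grads[self.n_down - 2 - i] = g_skip
            gy = _chain_backward(self.ups[i], g_up)
        # gy is now the gradient flowing into the bottleneck (skips[-1])
        for i in range(self.n_down - 1, -1, -1):
            if skip_grads[i] is not None:
                gy = gy + skip_grads[i]
            gy = _chain_backward(self.downs[i], gy)
        return gy


class Discriminator:
    """70x70 PatchGAN on the concatenated (dose map, aperture stack)
    pair; spectral normalization on every convolution; emits a patch grid
    of real/fake logits."""

    def __init__(self, rng, in_ch=1 + N_CHANNELS, nf=64):
        self.net = [
            Conv2d(in_ch, nf, rng, spectral_norm=True), LeakyReLU(0.2),
            Conv2d(nf, 2 * nf, rng, spectral_norm=True), BatchNorm2d(2 * nf),
            LeakyReLU(0.2),
            Conv2d(2 * nf, 4 * nf, rng, spectral_norm=True),
            BatchNorm2d(4 * nf), LeakyReLU(0.2),
            Conv2d(4 * nf, 8 * nf, rng, s=1, spectral_norm=True),
            BatchNorm2d(8 * nf), LeakyReLU(0.2),
            Conv2d(8 * nf, 1, rng, s=1, spectral_norm=True),
        ]

    def params(self):
        return [p for lay in self.net for p in lay.params()]

    def forward(self, x, train, rng):
        return _chain_forward(self.net, x, train, rng)

    def backward(self, gy):
        return _chain_backward(self.net, gy)


class Adam:
    def __init__(self, params, lr, beta_1=0.5, beta_2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta_1, beta_2, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p in self.params:
            p.m *= self.b1
            p.m += (1 - self.b1) * p.grad
            p.v *= self.b2
            p.v += (1 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def _bce_logits(logits: np.ndarray, labels: np.ndarray):
    """Numerically stable mean BCE on logits; returns (loss, dL/dlogits).

    Identical in value to :func:`binary_cross_entropy` applied to
    sigmoid(logits)."""
    z, t = logits, labels
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))
    return float(loss), (p - t) / z.size


@dataclass
class TrainedModel:
    generator: Generator
    discriminator: Discriminator
    config: TrainConfig
    history: pd.DataFrame | None = None

    def save(self, path) -> None:
        """Checkpoint: one .npz of parameters plus a JSON manifest."""
        path = Path(path)
        arrays = {}
        for i, p in enumerate(self.generator.params()):
            arrays[f"g{i}"] = p.value
        for i, p in enumerate(self.discriminator.params()):
            arrays[f"d{i}"] = p.value
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        manifest = {"config": asdict(self.config), "format": 1}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = manifest["config"]
        for key in ("soft_real", "soft_fake"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = TrainConfig(**cfg_dict)
        model = build_model(cfg)
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(model.generator.params()):
                p.value[...] = data[f"g{i}"]
            for i, p in enumerate(model.discriminator.params()):
                p.value[...] = data[f"d{i}"]
        return model


def build_model(config: TrainConfig) -> TrainedModel:
    """Freshly initialized generator/discriminator pair (an 'untrained
    model' baseline when used without training)."""
    rng = np.random.default_rng(config.seed)
    gen = Generator(rng, nf=config.gen_filters, n_down=config.n_down,
                    dropout=config.dropout, image_size=config.image_size)
    disc = Discriminator(rng, nf=config.disc_filters)
    return TrainedModel(generator=gen, discriminator=disc, config=config)


def delivery_fidelity(pred_channels: np.ndarray, target_channels: np.ndarray,
                      threshold_fraction: float = 0.02) -> float:
    """Mean absolute error between the *sequenced* fluence of a predicted
    stack and the ground-truth fluence, in normalized MU units.

    Mirrors the sequencing rules (threshold at a fraction of the stack
    maximum, every surviving pixel forced to the channel maximum) without
    the leaf-grid collapse, so it is cheap enough to evaluate every few
    epochs.  Unlike the raw L1 loss it is sensitive to low-level energy
    in zero-padded channels, which sequencing turns into spurious
    deliverable segments.
    """
    stack_max = float(pred_channels.max(initial=0.0))
    fl_pred = np.zeros(pred_channels.shape[:2])
    for c in range(pred_channels.shape[-1]):
        ch = np.where(pred_channels[:, :, c]
                      >= threshold_fraction * stack_max,
                      pred_channels[:, :, c], 0.0)
        peak = ch.max()
        if peak > 0:
            fl_pred += np.where(ch > 0, peak, 0.0)
    return float(np.mean(np.abs(fl_pred - target_channels.sum(axis=-1))))


def train(pairs: TrainingSet, split: CohortSplit | None,
          config: TrainConfig, log_every: int = 0) -> TrainedModel:
    """Alternating discriminator/generator updates on the split's training
    beams.  Returns the model with its per-epoch loss history attached.

    Both networks' gradients for a batch are taken through the same
    discriminator forward passes (the usual simultaneous scheme), then
    applied one network at a time.

    Adversarial training oscillates, so when
    ``config.checkpoint_every > 0`` the generator weights are snapshot
    every that many epochs and scored with :func:`delivery_fidelity` on a
    fixed subset of *training* beams; the best snapshot is restored at
    the end.  This is the package's concrete realization of training
    "until stable": the retained model is the one whose sequenced
    training fluences are most faithful, judged without ever consulting
    held-out data.
    """
    data = pairs.subset(split.train_idx) if split is not None else pairs
    if len(data) == 0:
        raise TrainingError("training set is empty")
    if data.inputs.shape[1] != config.image_size:
        raise TrainingError(
            f"pairs are {data.inputs.shape[1]}px but config.image_size is "
            f"{config.image_size}")
    x_all = np.ascontiguousarray(
        data.inputs.transpose(0, 3, 1, 2).astype(np.float32))
    y_all = np.ascontiguousarray(
        data.targets.transpose(0, 3, 1, 2).astype(np.float32))

    model = build_model(config)
    gen, disc = model.generator, model.discriminator
    rng = np.random.default_rng(config.seed + 1)
    opt_g = Adam(gen.params(), config.learning_rate, config.beta_1)
    opt_d = Adam(disc.params(), config.learning_rate, config.beta_1)

    n = len(data)
    sel_idx = np.arange(min(config.checkpoint_beams, n))
    best = {"score": np.inf, "epoch": -1, "weights": None}
    gen_params = gen.params()
    ema = ([p.value.copy() for p in gen_params]
           if config.ema_decay > 0 else None)

    def _eval_weights():
        """The weights inference should use: EMA if enabled."""
        return ema if ema is not None else [p.value for p in gen_params]

    def _checkpoint(epoch: int) -> float:
        current = [p.value for p in gen_params]
        use = _eval_weights()
        for p, w in zip(gen_params, use):
            p.value = w
        try:
            scores = []
            for i in sel_idx:
                out = gen.forward(x_all[i:i + 1].astype(np.float64),
                                  train=False, rng=None)
                pred = np.clip(out[0].transpose(1, 2, 0), 0.0, None)
                scores.append(delivery_fidelity(
                    pred, data.targets[i].astype(np.float64)))
        finally:
            for p, w in zip(gen_params, current):
                p.value = w
        score = float(np.mean(scores))
        if score < best["score"]:
            best.update(score=score, epoch=epoch,
                        weights=[w.copy() for w in use])
        return score

    history = []
    bs = config.batch_size
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n, bs):
            sel = order[start:start + bs]
            x, y = x_all[sel], y_all[sel]
            fake = gen.forward(x, train=True, rng=rng)

            # discriminator gradients: real pair, then fake pair
            opt_d.zero_grad()
            logits_r = disc.forward(np.concatenate([x, y], axis=1),
                                    train=True, rng=rng)
            lab_r = make_labels(rng, logits_r.shape, "real", config)
            loss_r, gl_r = _bce_logits(logits_r, lab_r)
            disc.backward(gl_r)
            logits_f = disc.forward(np.concatenate([x, fake], axis=1),
                                    train=True, rng=rng)
            lab_f = make_labels(rng, logits_f.shape, "fake", config)
            loss_f, gl_f = _bce_logits(logits_f, lab_f)
            disc.backward(gl_f)
            opt_d.step()
            d_loss = loss_r + loss_f

            # generator gradients through the same fake forward (layer
            # caches hold the pre-step effective weights)
            opt_g.zero_grad()
            opt_d.zero_grad()
            adv, gl = _bce_logits(logits_f, np.ones_like(logits_f))
            gx = disc.backward(gl)
            g_fake = gx[:, x.shape[1]:]
            l1 = float(np.mean(np.abs(fake - y)))
            g_fake = g_fake + config.lambda_l1 * np.sign(fake - y) / fake.size
            gen.backward(g_fake)
            opt_g.step()
            if ema is not None:
                d = config.ema_decay
                for e, p in zip(ema, gen_params):
                    e *= d
                    e += (1.0 - d) * p.value
            g_loss = generator_objective(adv, l1, config.lambda_l1)

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: D={d_loss}, "
                    f"G={g_loss}")
            d_losses.append(d_loss)
            g_losses.append(g_loss)

        row = {"epoch": epoch,
               "d_loss": float(np.mean(d_losses)),
               "g_loss": float(np.mean(g_losses))}
        if config.checkpoint_every and \
                (epoch + 1) % config.checkpoint_every == 0:
            row["fidelity"] = _checkpoint(epoch)
        history.append(row)
        if log_every and (epoch + 1) % log_every == 0:
            print(f"epoch {epoch + 1}/{config.epochs}  "
                  f"D {row['d_loss']:.3f}  G {row['g_loss']:.3f}"
                  + (f"  fid {row['fidelity']:.4f}"
                     if "fidelity" in row else ""))

    final = best["weights"] if best["weights"] is not None else ema
    if final is not None:
        for p, w in zip(gen_params, final):
            p.value[...] = w
    model.history = pd.DataFrame(history)
    model.history.attrs["selected_epoch"] = best["epoch"]
    return model


def predict(model: TrainedModel, dose_map: DoseMap2D,
            mu_scale: float = 1.0) -> ApertureStack:
    """Predicted aperture stack for one normalized BEV dose map.

    Inference is deterministic: dropout is disabled and no labels are
    drawn.  Output is clipped at zero (apertures carry no negative MU).
    """
    pix = np.asarray(dose_map.pixels, dtype=float)
    if pix.max() > 1.0 + 1e-6:
        raise ValueError(
            f"input max {pix.max():.3f} > 1; normalize the dose map first")
    x = pix[None, None]
    out = model.generator.forward(x, train=False, rng=None)
    channels = np.clip(out[0].transpose(1, 2, 0), 0.0, None)
    n_real = int(np.sum(channels.max(axis=(0, 1)) > 0))
    return ApertureStack(channels=channels, mu_scale=mu_scale,
                         n_real_segments=n_real,
                         beam_ref=dose_map.beam_ref)


def predict_batch(model: TrainedModel, pairs: TrainingSet,
                  indices=None) -> list[ApertureStack]:
    idx = np.arange(len(pairs)) if indices is None else np.asarray(indices)
    out = []
    for i in idx:
        dm = DoseMap2D(pairs.inputs[i, :, :, 0],
                       scale=float(pairs.meta["scale"].iloc[i]))
        out.append(predict(model, dm,
                           mu_scale=float(pairs.meta["mu_scale"].iloc[i])))
    return out
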