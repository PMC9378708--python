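"""Composite loss, augmentation and the desk-scale training loop for FIN.

The training objective is a weighted sum of three terms computed between the
target field image ``y`` (2 channels: real, imaginary) and the prediction:

    L = alpha * L_MAE + beta * L_complex + gamma * L_percep

* ``L_MAE``: sum of absolute channel differences divided by the pixel count
  n = H*W (both channels share the same n);
* ``L_complex``: mean absolute difference of the 2D DFTs of the complex
  fields ``y_re + i y_im`` and ``yhat_re + i yhat_im``, divided by n;
* ``L_percep``: mean squared distance between low-level features of the
  amplitude images, from a pluggable extractor.  The default extractor is a
  fixed-seed two-layer random convolutional feature stack — deterministic
  and dependency-free; any object with ``features`` / ``backward`` methods
  (e.g. a pretrained-CNN wrapper) can be substituted.

Default weights are alpha = 0.5, beta = 1, gamma = 0.5.

Optimization is Adam with a cosine-annealing-with-warm-restarts learning
rate schedule; the returned model is the checkpoint with the lowest
validation loss.  Everything is plain numpy and bit-reproducible per seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .fin.model import FIN

__all__ = [
    "LossWeights",
    "TrainConfig",
    "RandomConvFeatures",
    "compute_loss",
    "loss_and_grad",
    "augment",
    "cosine_annealing_lr",
    "train_model",
    "transfer_finetune",
]


@dataclass
class LossWeights:
    alpha: float = 0.5    # MAE term
    beta: float = 1.0     # complex-domain (DFT) term
    gamma: float = 0.5    # perceptual term

    def validate(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")


class RandomConvFeatures:
    """Fixed-seed random convolutional feature extractor (two 3x3 layers).

    Filters are drawn once from the given seed and never trained; features
    are the second layer's maps after a ReLU between layers.  Deterministic,
    so perceptual distances are reproducible without any pretrained weights.
    """

    def __init__(self, seed: int = 0, n1: int = 4, n2: int = 8):
        rng = np.random.default_rng(seed)
        self.k1 = rng.normal(0, 1.0 / 3.0, (n1, 3, 3))
        self.k2 = rng.normal(0, 1.0 / (3.0 * np.sqrt(n1)), (n2, n1, 3, 3))

    def features(self, image: np.ndarray, cache: dict | None = None) -> np.ndarray:
        h1 = np.stack(
            [ndimage.correlate(image, k, mode="constant") for k in self.k1]
        )
        r1 = np.maximum(h1, 0.0)
        f = np.stack(
            [
                sum(ndimage.correlate(r1[i], self.k2[j, i], mode="constant")
                    for i in range(self.k1.shape[0]))
                for j in range(self.k2.shape[0])
            ]
        )
        if cache is not None:
            cache["h1"] = h1
            cache["r1"] = r1
        return f

    def backward(self, g_f: np.ndarray, cache: dict) -> np.ndarray:
        """Adjoint: gradient wrt the input image given dL/d(features)."""
        h1 = cache["h1"]
        g_r1 = np.zeros_like(cache["r1"])
        for j in range(self.k2.shape[0]):
            for i in range(self.k1.shape[0]):
                g_r1[i] += ndimage.convolve(g_f[j], self.k2[j, i], mode="constant")
        g_h1 = g_r1 * (h1 > 0)
        g_img = np.zeros(g_f.shape[-2:])
        for i in range(self.k1.shape[0]):
            g_img += ndimage.convolve(g_h1[i], self.k1[i], mode="constant")
        return g_img


def _amplitude(y: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    return np.sqrt(y[0] ** 2 + y[1] ** 2 + eps)


def _loss_single(
    y: np.ndarray,
    yhat: np.ndarray,
    weights: LossWeights,
    extractor,
    want_grad: bool,
) -> tuple[tuple[float, float, float, float], np.ndarray | None]:
    H, W = y.shape[-2:]
    n = H * W
    d = yhat - y
    mae = float(np.abs(d).sum() / n)

    cy = y[0] + 1j * y[1]
    chat = yhat[0] + 1j * yhat[1]
    E = np.fft.fft2(chat) - np.fft.fft2(cy)
    absE = np.abs(E)
    complex_term = float(absE.sum() / n)

    percep = 0.0
    g_percep = np.zeros_like(yhat) if want_grad else None
    if weights.gamma > 0 and extractor is not None:
        cache_hat: dict = {}
        a_y = _amplitude(y)
        a_hat = _amplitude(yhat)
        f_y = extractor.features(a_y)
        f_hat = extractor.features(a_hat, cache=cache_hat if want_grad else None)
        diff = f_hat - f_y
        percep = float(np.mean(diff**2))
        if want_grad:
            g_f = 2.0 * diff / diff.size
            g_amp = extractor.backward(g_f, cache_hat)
            g_percep[0] = g_amp * yhat[0] / a_hat
            g_percep[1] = g_amp * yhat[1] / a_hat

    total = weights.alpha * mae + weights.beta * complex_term + weights.gamma * percep
    grad = None
    if want_grad:
        g_mae = np.sign(d) / n
        GE = np.where(absE > 0, E / np.where(absE > 0, absE, 1.0), 0.0) / n
        Gc = np.fft.ifft2(GE) * (H * W)   # adjoint of the unnormalized DFT
        g_complex = np.stack([np.real(Gc), np.imag(Gc)])
        grad = (
            weights.alpha * g_mae
            + weights.beta * g_complex
            + weights.gamma * g_percep
        )
    return (total, mae, complex_term, percep), grad


def compute_loss(
    y: np.ndarray,
    yhat: np.ndarray,
    weights: LossWeights | None = None,
    extractor=None,
) -> tuple[float, float, float, float]:
    """Composite loss between target and predicted (2, H, W) field images.

    Returns ``(total, mae_term, complex_term, percep_term)``.  Batched
    (B, 2, H, W) inputs are averaged over the batch.
    """
    terms, _ = loss_and_grad(y, yhat, weights, extractor, want_grad=False)
    return terms


def loss_and_grad(
    y: np.ndarray,
    yhat: np.ndarray,
    weights: LossWeights | None = None,
    extractor=None,
    want_grad: bool = True,
) -> tuple[tuple[float, float, float, float], np.ndarray | None]:
    """Loss terms and (optionally) the gradient wrt the prediction."""
    weights = weights or LossWeights()
    weights.validate()
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: target {y.shape} vs prediction {yhat.shape}")
    if y.ndim == 3:
        return _loss_single(y, yhat, weights, extractor, want_grad)
    # batch: average terms and gradients
    B = y.shape[0]
    sums = np.zeros(4)
    grads = np.zeros_like(yhat) if want_grad else None
    for b in range(B):
        terms, g = _loss_single(y[b], yhat[b], weights, extractor, want_grad)
        sums += np.array(terms)
        if want_grad:
            grads[b] = g / B
    return tuple(sums / B), grads


def augment(
    stack: np.ndarray, target: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random rotation from {0, 90, 180, 270} degrees to a pair.

    The same rotation is applied to every hologram plane and both target
    channels; deterministic in the seed.  Requires a square FOV for the
    90/270 cases.
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(0, 4))
    if k % 2 == 1 and stack.shape[-2] != stack.shape[-1]:
        raise ValueError("90/270-degree rotation needs a square field of view")
    return np.rot90(stack, k, axes=(-2, -1)).copy(), np.rot90(
        target, k, axes=(-2, -1)
    ).copy()


def cosine_annealing_lr(
    epoch: int, lr_max: float, lr_min: float, period: int, mult: int = 2
) -> float:
    """Cosine-annealed learning rate with warm restarts.

    The first cycle lasts ``period`` epochs; each subsequent cycle is
    ``mult`` times longer.  At every restart the rate returns to ``lr_max``.
    """
    t, T = epoch, period
    while t >= T:
        t -= T
        T *= mult
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + np.cos(np.pi * t / T))


@dataclass
class TrainConfig:
    """Desk-scale training controls (defaults sized for CPU-only runs)."""

    epochs: int = 120
    batch_size: int = 8
    lr: float = 1e-3
    lr_min_factor: float = 0.01          # lr_min = lr * factor
    adam_betas: tuple[float, float] = (0.9, 0.999)
    scheduler_period: int = 50
    scheduler_mult: int = 2
    augment: bool = True
    validation_fraction: float = 1.0 / 7.0   # 6:1 train/validation split
    loss_weights: LossWeights = dc_field(default_factory=LossWeights)
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], betas: tuple[float, float]):
        self.b1, self.b2 = betas
        self.m = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in params.items()}
        self.v = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in params.items()}
        self.t = 0

    def step(
        self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float
    ) -> dict[str, np.ndarray]:
        self.t += 1
        out = {}
        for k, p in params.items():
            g = np.asarray(grads[k], dtype=float)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            out[k] = np.asarray(p, dtype=float) - lr * mhat / (np.sqrt(vhat) + 1e-8)
        return out


def _split_dataset(
    n: int, validation_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.permutation(n)
    n_val = max(1, int(round(n * validation_fraction))) if validation_fraction > 0 and n > 1 else 0
    return idx[n_val:], idx[:n_val]


def train_model(
    model: FIN,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig | None = None,
    extractor=None,
) -> tuple[FIN, dict]:
    """Train a FIN model on (hologram stack, target field) pairs.

    The dataset is split into train/validation per the config (6:1 default);
    per-epoch train and validation losses and the learning rate are recorded
    in the returned history, and the model is restored to the checkpoint
    with the lowest validation loss (training loss when no validation split
    exists).

    Returns ``(model, history)`` with history keys ``train_loss``,
    ``val_loss``, ``lr`` and ``best_epoch``.
    """
    config = config or TrainConfig()
    config.validate()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if extractor is None and config.loss_weights.gamma > 0:
        extractor = RandomConvFeatures(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _split_dataset(len(dataset), config.validation_fraction, rng)
    if len(train_idx) == 0:
        train_idx, val_idx = val_idx, train_idx

    optimizer = _Adam(model.parameters(), config.adam_betas)
    history: dict = {"train_loss": [], "val_loss": [], "lr": [], "best_epoch": None}
    best_val = np.inf
    best_params = copy.deepcopy(model.parameters())
    lr_min = config.lr * config.lr_min_factor

    def evaluate(indices: np.ndarray) -> float:
        if len(indices) == 0:
            return np.nan
        losses = []
        for i in indices:
            stack, target = dataset[i]
            pred = model.forward(stack, train=False)
            terms = compute_loss(target, pred, config.loss_weights, extractor)
            losses.append(terms[0])
        return float(np.mean(losses))

    for epoch in range(config.epochs):
        lr = cosine_annealing_lr(
            epoch, config.lr, lr_min, config.scheduler_period, config.scheduler_mult
        )
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            stacks, targets = [], []
            for i in batch:
                s, t = dataset[i]
                if config.augment:
                    s, t = augment(s, t, seed=int(rng.integers(0, 2**31 - 1)))
                stacks.append(s)
                targets.append(t)
            xb = np.stack(stacks)
            yb = np.stack(targets)
            pred = model.forward(xb, train=True)
            terms, g = loss_and_grad(yb, pred, config.loss_weights, extractor)
            grads = model.backward(g)
            model.set_parameters(optimizer.step(model.parameters(), grads, lr))
            epoch_losses.append(terms[0])
        train_loss = float(np.mean(epoch_losses)) if epoch_losses else np.nan
        val_loss = evaluate(val_idx) if len(val_idx) else train_loss
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        if val_loss < best_val:
            best_val = val_loss
            best_params = copy.deepcopy(model.parameters())
            history["best_epoch"] = epoch
    model.set_parameters(best_params)
    return model, history


def transfer_finetune(
    model: FIN,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig | None = None,
    extractor=None,
) -> tuple[FIN, dict]:
    """Fine-tune a pre-trained model on a new sample type.

    Identical loop to :func:`train_model`, starting from the provided
    weights; zero epochs returns the model unchanged.
    """
    config = config or TrainConfig(epochs=20)
    if config.epochs == 0:
        return model, {"train_loss": [], "val_loss": [], "lr": [], "best_epoch": None}
    return train_model(model, dataset, config, extractor)
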