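"""Segmentation stage: model construction, losses, preprocessing, training.

Two presets mirror the two-stage design: the cornea stage trains a U-Net at
512x512 with BCE-with-logits loss under RMSprop, the pterygium stage trains
an attention-gated U-Net++ at 96x96 with a combined BCE-Dice loss under
Adam, each selecting the checkpoint with the best validation metric (Dice
for the cornea, mean IoU for the pterygium).

The combined loss is, as configured by default,

    loss = 1e-3 * BCE(p, y) - Dice(p, y)

which is negative near convergence (minimum -1); a ``shifted`` variant adds
1 (i.e. uses the Dice *loss* 1 - Dice) and has identical gradients.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from skimage import exposure, morphology
from skimage.transform import resize_local_mean
from scipy import ndimage

from .nn import Adam, AttentionGate, RMSprop, Tensor, UNet, UNetPP
from .stats import dice_coefficient, miou

__all__ = [
    "SegModelConfig", "AttentionGateSpec", "TrainConfig",
    "build_model", "attention_gate",
    "bce_logits_loss", "soft_dice", "bce_dice_loss",
    "preprocess", "augment", "apply_transform",
    "train_model", "prob_to_mask", "smooth_edges",
    "save_checkpoint", "load_checkpoint",
]

PROB_THRESHOLD = 0.5


# ------------------------------------------------------------------ configs

@dataclass
class SegModelConfig:
    architecture: str = "attention_unetpp"  # unet | unetpp | attention_unetpp
    input_size: int = 96
    in_channels: int = 3
    base_channels: int = 16
    depth: int = 4
    seed: int = 0

    def validate(self):
        if self.architecture not in ("unet", "unetpp", "attention_unetpp"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.input_size % 2**self.depth:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}")


@dataclass
class AttentionGateSpec:
    f_g: int
    f_l: int
    f_int: int | None = None
    seed: int = 0

    def resolved_f_int(self) -> int:
        return self.f_int if self.f_int is not None else max(self.f_l // 2, 1)


@dataclass
class TrainConfig:
    loss: str = "bce_dice"            # bce_logits | bce_dice
    optimizer: str = "adam"           # rmsprop | adam
    learning_rate: float = 1e-3
    momentum_decay_1: float = 0.9
    momentum_decay_2: float = 0.99
    batch_size: int = 16
    epochs: int = 300
    weight_decay: float = 1e-4
    val_fraction: float = 0.1
    selection_metric: str = "miou"    # dice | miou
    seed: int = 0
    augmentations: tuple = ("flip", "translate", "rotate")
    target_metric: float | None = None  # stop early once the selection metric reaches this
    init_head_bias_prior: bool = True   # initialize the head bias at the foreground log-odds

    @classmethod
    def cornea_preset(cls, **overrides) -> "TrainConfig":
        base = dict(loss="bce_logits", optimizer="rmsprop", learning_rate=1e-5,
                    momentum_decay_1=0.9, momentum_decay_2=0.99, batch_size=4,
                    epochs=100, weight_decay=1e-8, val_fraction=0.1,
                    selection_metric="dice")
        base.update(overrides)
        return cls(**base)

    @classmethod
    def pterygium_preset(cls, **overrides) -> "TrainConfig":
        base = dict(loss="bce_dice", optimizer="adam", learning_rate=1e-3,
                    momentum_decay_1=0.9, momentum_decay_2=0.99, batch_size=16,
                    epochs=300, weight_decay=1e-4, val_fraction=0.1,
                    selection_metric="miou")
        base.update(overrides)
        return cls(**base)


def build_model(config: SegModelConfig):
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.architecture == "unet":
        return UNet(config.in_channels, config.base_channels, config.depth, rng)
    return UNetPP(config.in_channels, config.base_channels, config.depth,
                  attention=config.architecture == "attention_unetpp", rng=rng)


def attention_gate(x_l, g, spec: AttentionGateSpec,
                   gate: AttentionGate | None = None):
    """Apply an additive attention gate to a skip feature map.

    ``x_l`` is (N, F_l, H, W); ``g`` is (N, F_g, H/2, W/2).  Returns the
    gated feature map and the weight map alpha, both as numpy arrays.  A
    pre-built (e.g. trained) gate can be passed; otherwise one is drawn from
    ``spec.seed``.
    """
    x_l = np.asarray(x_l, dtype=float)
    g = np.asarray(g, dtype=float)
    if x_l.shape[1] != spec.f_l or g.shape[1] != spec.f_g:
        raise ValueError("channel counts do not match the gate spec")
    if gate is None:
        gate = AttentionGate(spec.f_g, spec.f_l, spec.resolved_f_int(),
                             np.random.default_rng(spec.seed))
    xt, gt = Tensor(x_l), Tensor(g)
    alpha = gate.alpha(xt, gt)
    return (alpha * xt).data, alpha.data


# ------------------------------------------------------------------ losses

def _validate_binary(targets: np.ndarray):
    if not np.isin(targets, (0, 1)).all():
        raise ValueError("targets must be binary {0, 1}")


def bce_logits_loss(logits, targets) -> float:
    """Numerically stable sigmoid + binary cross-entropy, mean over elements."""
    x = np.asarray(logits, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.shape != y.shape:
        raise ValueError("logits and targets must have the same shape")
    _validate_binary(y)
    return float(np.mean(np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))))


def soft_dice(pred_probs, targets, smooth: float = 1.0) -> float:
    """Soft Dice overlap with additive smoothing in numerator and denominator."""
    p = np.asarray(pred_probs, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    inter = (p * t).sum()
    return float((2.0 * inter + smooth) / (p.sum() + t.sum() + smooth))


def bce_dice_loss(pred_probs, targets, variant: str = "as_printed",
                  smooth: float = 1.0, eps: float = 1e-7) -> float:
    """Combined loss ``1e-3 * BCE - Dice`` (default) or its ``shifted`` form
    ``1e-3 * BCE + (1 - Dice)``; the two differ by a constant."""
    p = np.clip(np.asarray(pred_probs, dtype=float), eps, 1.0 - eps)
    t = np.asarray(targets, dtype=float)
    _validate_binary(t)
    bce = float(-np.mean(t * np.log(p) + (1 - t) * np.log(1 - p)))
    dice = soft_dice(pred_probs, targets, smooth)
    loss = 1e-3 * bce - dice
    if variant == "shifted":
        loss += 1.0
    elif variant != "as_printed":
        raise ValueError(f"unknown variant {variant!r}")
    return loss


def _bce_logits_tensor(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Stable BCE-with-logits as a differentiable scalar."""
    x = logits.data
    y = targets
    val = np.mean(np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x))))
    out = Tensor._make(np.asarray(val), (logits,), None)
    sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
    out._backward = lambda g: (g * (sig - y) / x.size,)
    return out


def _bce_dice_tensor(probs: Tensor, targets: np.ndarray,
                     smooth: float = 1.0, eps: float = 1e-7,
                     variant: str = "as_printed") -> Tensor:
    t = Tensor(targets)
    pc = probs.clip(eps, 1.0 - eps)
    bce = -(t * pc.log() + (1.0 - t) * (1.0 - pc).log()).mean()
    inter = (probs * t).sum()
    dice = (2.0 * inter + smooth) / (probs.sum() + t.sum() + smooth)
    loss = 1e-3 * bce - dice
    if variant == "shifted":
        loss = loss + 1.0
    return loss


# ------------------------------------------------------------------ images

def _stretch(channel: np.ndarray, p_lo=2, p_hi=98) -> np.ndarray:
    lo, hi = np.percentile(channel, (p_lo, p_hi))
    if hi <= lo:
        return channel.astype(float)
    return np.asarray(
        exposure.rescale_intensity(channel.astype(float), in_range=(lo, hi),
                                   out_range=(0.0, 255.0)))


def preprocess(image, stage: str) -> np.ndarray:
    """Contrast enhancement + area-interpolation resize for one stage.

    ``stage='cornea'``: per-channel percentile (2/98) contrast stretch,
    adaptive histogram equalization (CLAHE, clip limit 0.01, 8x8 tiles),
    resize to 512x512.  ``stage='pterygium'``: adaptive (percentile)
    contrast stretch, resize to 96x96.  Returns float32 in [0, 255] with a
    trailing channel axis.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 2:
        img = img[..., None]
    img = img.astype(float)
    out_size = {"cornea": 512, "pterygium": 96}.get(stage)
    if out_size is None:
        raise ValueError(f"unknown stage {stage!r}")
    chans = []
    for ch in range(img.shape[2]):
        c = _stretch(img[..., ch])
        if stage == "cornea" and np.ptp(c) > 0:
            kern = (max(c.shape[0] // 8, 1), max(c.shape[1] // 8, 1))
            c = exposure.equalize_adapthist(c / 255.0, kernel_size=kern,
                                            clip_limit=0.01) * 255.0
        chans.append(resize_local_mean(c, (out_size, out_size)))
    return np.stack(chans, axis=-1).astype(np.float32)


def apply_transform(image, mask, hflip: bool = False, vflip: bool = False,
                    angle_deg: float = 0.0, shift_px: tuple[float, float] = (0.0, 0.0)):
    """Apply one spatial transform identically to an image and its mask.

    The image is interpolated linearly, the mask with nearest neighbor so it
    stays binary.  Flips are exact involutions.
    """
    img = np.asarray(image, dtype=float)
    msk = np.asarray(mask)
    if hflip:
        img, msk = img[:, ::-1].copy(), msk[:, ::-1].copy()
    if vflip:
        img, msk = img[::-1].copy(), msk[::-1].copy()
    if angle_deg:
        img = ndimage.rotate(img, angle_deg, axes=(0, 1), reshape=False,
                             order=1, mode="nearest")
        msk = ndimage.rotate(msk.astype(float), angle_deg, axes=(0, 1),
                             reshape=False, order=0, mode="constant") > 0.5
    if shift_px != (0.0, 0.0):
        full_shift = shift_px + (0.0,) * (img.ndim - 2)
        img = ndimage.shift(img, full_shift, order=1, mode="nearest")
        msk = ndimage.shift(msk.astype(float), shift_px[: msk.ndim], order=0,
                            mode="constant") > 0.5
    return img, msk


def augment(image, mask, seed: int, augmentations=("flip", "translate", "rotate"),
            max_rotate_deg: float = 15.0, max_translate_frac: float = 0.05):
    """Random flip/translate/rotate, deterministic per seed, mask-consistent."""
    rng = np.random.default_rng(seed)
    hflip = "flip" in augmentations and rng.random() < 0.5
    angle = rng.uniform(-max_rotate_deg, max_rotate_deg) if "rotate" in augmentations else 0.0
    shift = (0.0, 0.0)
    if "translate" in augmentations:
        h, w = np.asarray(mask).shape[:2]
        shift = (rng.uniform(-max_translate_frac, max_translate_frac) * h,
                 rng.uniform(-max_translate_frac, max_translate_frac) * w)
    return apply_transform(image, mask, hflip=hflip, angle_deg=angle, shift_px=shift)


def prob_to_mask(probs, threshold: float = PROB_THRESHOLD) -> np.ndarray:
    return np.asarray(probs) >= threshold


def smooth_edges(mask, radius: int = 2) -> np.ndarray:
    """Morphological opening then closing with a disk footprint."""
    m = np.asarray(mask) > 0
    footprint = morphology.disk(radius)
    return morphology.closing(morphology.opening(m, footprint), footprint)


# ------------------------------------------------------------------ training

def _forward_probs(model, batch: np.ndarray) -> Tensor:
    return model(Tensor(batch)).sigmoid()


def _eval_metric(model, images: np.ndarray, masks: np.ndarray, metric: str) -> float:
    scores = []
    for i in range(images.shape[0]):
        probs = _forward_probs(model, images[i : i + 1]).data[0, 0]
        pred = prob_to_mask(probs)
        truth = masks[i, 0] > 0.5
        scores.append(dice_coefficient(pred, truth) if metric == "dice"
                      else miou(pred, truth))
    return float(np.mean(scores))


def train_model(model, images, masks, config: TrainConfig):
    """Train and return (model-with-best-weights, history).

    ``images`` is (N, C, S, S) float (any consistent scale; normalized to
    [0, 1] internally), ``masks`` is (N, 1, S, S) binary.  A validation
    fraction is split off once with the run seed; the returned weights are
    those of the epoch maximizing the selection metric on that split (on the
    training set itself when the split is empty).
    """
    x = np.asarray(images, dtype=float)
    y = np.asarray(masks, dtype=float)
    if x.ndim != 4 or y.ndim != 4 or x.shape[0] != y.shape[0]:
        raise ValueError("expected (N,C,S,S) images and (N,1,S,S) masks")
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty dataset")
    if n < config.batch_size and config.val_fraction > 0 and n > 1:
        pass  # small datasets are allowed; batches are simply smaller
    if x.max() > 1.5:
        x = x / 255.0
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = int(round(config.val_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if train_idx.size == 0:
        raise ValueError("validation fraction leaves no training data")
    if train_idx.size < 1 or config.batch_size < 1:
        raise ValueError("invalid batch configuration")

    if config.init_head_bias_prior and hasattr(model, "head"):
        # start the output layer at the foreground prior's log-odds so the
        # class-imbalanced Dice term does not saturate the sigmoid early on
        prior = float(np.clip(y[train_idx].mean(), 1e-3, 1.0 - 1e-3))
        model.head.bias.data[:] = np.log(prior / (1.0 - prior))

    params = model.parameters()
    if config.optimizer == "rmsprop":
        opt = RMSprop(params, lr=config.learning_rate,
                      momentum=config.momentum_decay_1,
                      alpha=config.momentum_decay_2,
                      weight_decay=config.weight_decay)
    elif config.optimizer == "adam":
        opt = Adam(params, lr=config.learning_rate,
                   beta1=config.momentum_decay_1, beta2=config.momentum_decay_2,
                   weight_decay=config.weight_decay)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    history = []
    best_metric, best_epoch, best_state = -np.inf, -1, model.state_dict()
    eval_idx = val_idx if val_idx.size else train_idx
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, order.size, config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            logits = model(Tensor(x[batch]))
            if config.loss == "bce_logits":
                loss = _bce_logits_tensor(logits, y[batch])
            elif config.loss == "bce_dice":
                loss = _bce_dice_tensor(logits.sigmoid(), y[batch])
            else:
                raise ValueError(f"unknown loss {config.loss!r}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        metric = _eval_metric(model, x[eval_idx], y[eval_idx],
                              config.selection_metric)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "val_metric": metric})
        if metric > best_metric:
            best_metric, best_epoch = metric, epoch
            best_state = model.state_dict()
        if config.target_metric is not None and best_metric >= config.target_metric:
            break
    model.load_state_dict(best_state)
    return model, {"history": history, "selected_epoch": best_epoch,
                   "best_metric": best_metric,
                   "n_train": int(train_idx.size), "n_val": int(val_idx.size)}


# ------------------------------------------------------------------ checkpoints

def save_checkpoint(path, model, model_config: SegModelConfig,
                    info: dict | None = None):
    """Serialized weights (.npz) plus a JSON sidecar with config and metrics."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = {"model_config": asdict(model_config), "info": info or {}}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path):
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = SegModelConfig(**sidecar["model_config"])
    model = build_model(config)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, config, sidecar["info"]
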