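"""Depth-3 3D U-Net for gross-tumor-volume segmentation.

The network is the classic encoder–decoder with skip connections: each
encoder level applies two 3×3×3 convolutions (instance-norm + ReLU) and
halves the spatial resolution by max pooling; the bottleneck doubles the
filters once more; each decoder level upsamples ×2, concatenates the
matching encoder features, and convolves twice; a final 1×1×1 convolution
with a sigmoid yields a per-voxel foreground probability. GTV1 and GTV2
are segmented by two independently trained binary models, each reading its
own 3-channel input recipe (see :mod:`gliotrack.preprocess`).

Training minimizes the soft Dice loss on randomly cropped, randomly
flipped/rotated volumes, reduces the learning rate when validation Dice
plateaus, keeps the best-validation checkpoint, and stops early after a
patience of non-improving epochs (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ParameterError, ValidationError
from .grids import VolumeGrid
from .preprocess import ChannelStack

__all__ = [
    "UnetConfig",
    "TrainConfig",
    "UNet3D",
    "build_unet3d",
    "soft_dice_loss",
    "AugmentInfo",
    "augment_sample",
    "should_stop",
    "train",
    "predict_volume",
]


@dataclass(frozen=True)
class UnetConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of pooling (downsampling) levels; filters start
    at ``base_filters`` and double per level, reaching
    ``base_filters * 2**depth`` at the bottleneck.
    """

    in_channels: int = 3
    depth: int = 3
    base_filters: int = 32
    norm: str = "instance"  # "instance" | "none"

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_filters < 1 or self.in_channels < 1:
            raise ParameterError("depth, base_filters and in_channels must be >= 1")
        if self.norm not in ("instance", "none"):
            raise ParameterError(f"norm must be 'instance' or 'none', got {self.norm!r}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam; exposed rather than hard-coded)."""

    lr: float = 1e-4
    scheduler_patience: int = 5
    scheduler_factor: float = 0.5
    early_stop_patience: int = 10
    max_epochs: int = 100
    batch_size: int = 1
    aug_probability: float = 0.5
    crop_shape: tuple[int, int, int] = (128, 128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stop_patience < 1:
            raise ParameterError("early_stop_patience must be >= 1")
        if not 0.0 <= self.aug_probability <= 1.0:
            raise ParameterError("aug_probability must be in [0, 1]")
        if not 0.0 < self.scheduler_factor < 1.0:
            raise ParameterError("scheduler_factor must be in (0, 1)")
        if self.lr <= 0:
            raise ParameterError("lr must be positive")


class _DoubleConv:
    """Two (conv -> [norm] -> ReLU) blocks."""

    def __init__(self, cin: int, cout: int, norm: str, rng: np.random.Generator):
        self.layers: list[nn.Layer] = []
        for c_in in (cin, cout):
            self.layers.append(nn.Conv3d(c_in, cout, k=3, rng=rng))
            if norm == "instance":
                self.layers.append(nn.InstanceNorm3d(cout))
            self.layers.append(nn.ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[dict]:
        return [p for layer in self.layers for p in layer.params()]


class UNet3D:
    """Encoder–decoder 3D segmentation network with skip connections.

    Input: (in_channels, D, H, W) with every spatial dim divisible by
    2**depth. Output: (D, H, W) per-voxel probability in [0, 1].
    """

    def __init__(self, cfg: UnetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f = cfg.base_filters
        self.encoders: list[_DoubleConv] = []
        self.pools: list[nn.MaxPool3d] = []
        cin = cfg.in_channels
        for level in range(cfg.depth):
            self.encoders.append(_DoubleConv(cin, f * 2**level, cfg.norm, rng))
            self.pools.append(nn.MaxPool3d())
            cin = f * 2**level
        self.bottleneck = _DoubleConv(cin, f * 2**cfg.depth, cfg.norm, rng)
        self.ups: list[nn.Upsample3d] = []
        self.decoders: list[_DoubleConv] = []
        for level in reversed(range(cfg.depth)):
            skip_c = f * 2**level
            up_c = f * 2 ** (level + 1)
            self.ups.append(nn.Upsample3d())
            self.decoders.append(_DoubleConv(up_c + skip_c, skip_c, cfg.norm, rng))
        self.head = nn.Conv3d(f, 1, k=1, rng=rng)
        self.out_act = nn.Sigmoid()

    # -- plumbing ----------------------------------------------------------

    def params(self) -> list[dict]:
        blocks = [*self.encoders, self.bottleneck, *self.decoders]
        out = [p for b in blocks for p in b.params()]
        out.extend(self.head.params())
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p["value"].size for p in self.params()))

    def get_state(self) -> list[np.ndarray]:
        return [p["value"].copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p["value"][...] = s

    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValidationError(
                f"input must be ({self.cfg.in_channels}, D, H, W), got {x.shape}"
            )
        div = 2**self.cfg.depth
        if any(s % div for s in x.shape[1:]):
            raise ValidationError(
                f"spatial dims {x.shape[1:]} must be divisible by 2**depth = {div}"
            )

    # -- compute -----------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_shape(x)
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for enc, pool in zip(self.encoders, self.pools):
            x = enc.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.decoders, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[0])
            x = dec.forward(np.concatenate([skip, x], axis=0))
        x = self.head.forward(x)
        return self.out_act.forward(x)[0]

    __call__ = forward

    def backward(self, grad: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probability); accumulates parameter grads."""
        g = self.out_act.backward(grad[None].astype(np.float32))
        g = self.head.backward(g)
        skip_grads = []
        for dec, up, sc in zip(
            reversed(self.decoders), reversed(self.ups), reversed(self._skip_channels)
        ):
            g = dec.backward(g)
            skip_grads.append(g[:sc])
            g = up.backward(g[sc:])
        g = self.bottleneck.backward(g)
        skip_grads.reverse()  # now ordered bottom (deepest) to top
        for enc, pool, sg in zip(
            reversed(self.encoders), reversed(self.pools), skip_grads
        ):
            g = pool.backward(g) + sg
            g = enc.backward(g)


def build_unet3d(cfg: UnetConfig | None = None, seed: int = 0) -> UNet3D:
    """Construct a randomly initialized (seeded) U-Net."""
    return UNet3D(cfg or UnetConfig(), seed=seed)


def soft_dice_loss(prob: np.ndarray, target: np.ndarray, smooth: float = 1e-5) -> float:
    """1 - (2·Σ(p·t)+s)/(Σp+Σt+s): the soft Dice loss, in [0, 1]."""
    prob = np.asarray(prob, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if prob.shape != target.shape:
        raise ValidationError(f"shape mismatch: {prob.shape} vs {target.shape}")
    if prob.min() < 0 or prob.max() > 1:
        raise ValidationError("prob must lie in [0, 1]")
    num = 2.0 * float((prob * target).sum()) + smooth
    den = float(prob.sum()) + float(target.sum()) + smooth
    return 1.0 - num / den


def _dice_loss_grad(prob: np.ndarray, target: np.ndarray, smooth: float = 1e-5) -> np.ndarray:
    """d(soft_dice_loss)/d(prob), by the quotient rule."""
    p = prob.astype(np.float64)
    t = target.astype(np.float64)
    num = 2.0 * float((p * t).sum()) + smooth
    den = float(p.sum()) + float(t.sum()) + smooth
    return ((num / den**2) - 2.0 * t / den).astype(np.float32)


@dataclass
class AugmentInfo:
    """What a single augmentation call actually did."""

    flipped: bool = False
    flip_axis: int | None = None
    rotated: bool = False
    rot_quarters: int = 0


def augment_sample(
    stack: np.ndarray,
    label: np.ndarray,
    p: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, AugmentInfo]:
    """Random flip and in-plane 90°-multiple rotation, applied jointly.

    With probability ``p`` the sample is flipped along one random spatial
    axis; independently with probability ``p`` it is rotated by a random
    multiple of 90° in the axial (first two spatial axes) plane. Image and
    label always receive identical transforms, so label geometry stays
    exact. Returns (stack, label, info).
    """
    if not 0.0 <= p <= 1.0:
        raise ParameterError("p must be in [0, 1]")
    rng = rng or np.random.default_rng(0)
    info = AugmentInfo()
    if rng.random() < p:
        info.flipped = True
        info.flip_axis = int(rng.integers(3))
        stack = np.flip(stack, axis=info.flip_axis + 1)
        label = np.flip(label, axis=info.flip_axis)
    if rng.random() < p:
        info.rotated = True
        info.rot_quarters = int(rng.integers(1, 4))
        stack = np.rot90(stack, k=info.rot_quarters, axes=(1, 2))
        label = np.rot90(label, k=info.rot_quarters, axes=(0, 1))
    return np.ascontiguousarray(stack), np.ascontiguousarray(label), info


def should_stop(val_history: list[float], patience: int = 10) -> bool:
    """True when the best validation value is ``patience`` or more epochs old.

    Improvement must be strict; ties with the running best do not reset the
    counter (the *first* occurrence of the best value is what counts).
    """
    if not val_history:
        raise ValidationError("val_history must be nonempty")
    best_idx = int(np.argmax(val_history))  # argmax -> first occurrence
    return (len(val_history) - 1 - best_idx) >= patience


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_dice: float
    lr: float


@dataclass
class TrainHistory:
    epochs: list[EpochRecord] = field(default_factory=list)

    @property
    def val_dice(self) -> list[float]:
        return [e.val_dice for e in self.epochs]


def _binary_dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _pad_to_divisible(arr: np.ndarray, div: int) -> tuple[np.ndarray, tuple[slice, ...]]:
    pads = [(0, (-s) % div) for s in arr.shape[1:]]
    un = tuple(slice(0, s) for s in arr.shape[1:])
    if any(p[1] for p in pads):
        arr = np.pad(arr, [(0, 0), *pads])
    return arr, un


def _random_crop(
    arr: np.ndarray,
    lab: np.ndarray,
    crop_shape: tuple[int, int, int],
    depth: int,
    rng: np.random.Generator,
    foreground_prob: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """One training crop, foreground-centred with probability 0.5.

    The crop is clipped to the volume and rounded down to the nearest
    multiple of 2**depth so the network accepts it.
    """
    div = 2**depth
    shape = arr.shape[1:]
    crop = tuple(min(int(c), s) // div * div for c, s in zip(crop_shape, shape))
    max_corner = [s - c for s, c in zip(shape, crop)]
    fg = np.argwhere(lab > 0)
    if len(fg) > 0 and rng.random() < foreground_prob:
        center = fg[rng.integers(len(fg))]
        corner = [
            int(np.clip(ci - cs // 2, 0, mc)) for ci, cs, mc in zip(center, crop, max_corner)
        ]
    else:
        corner = [int(rng.integers(mc + 1)) for mc in max_corner]
    sl = tuple(slice(c, c + cs) for c, cs in zip(corner, crop))
    return arr[(slice(None), *sl)].copy(), lab[sl].copy()


def _stack_arrays(case) -> tuple[np.ndarray, np.ndarray]:
    stack, label = case
    arr = stack.as_array() if isinstance(stack, ChannelStack) else np.asarray(stack, np.float32)
    lab = label.voxels if isinstance(label, VolumeGrid) else np.asarray(label)
    return arr, lab.astype(np.float32)


def train(
    model: UNet3D,
    train_cases: list,
    val_cases: list,
    cfg: TrainConfig | None = None,
) -> tuple[UNet3D, TrainHistory]:
    """Train with soft Dice loss, plateau LR decay and early stopping.

    ``train_cases`` / ``val_cases`` are lists of (ChannelStack, label) pairs
    (plain (3,D,H,W) arrays and 3D label arrays are also accepted). Each
    epoch draws one random, augmented crop per training case; validation is
    a full-volume forward pass with mean Dice at threshold 0.5. The model
    state with the best validation Dice is restored before returning.
    """
    cfg = cfg or TrainConfig()
    if not train_cases or not val_cases:
        raise ParameterError("need at least one training and one validation case")
    history = TrainHistory()
    if cfg.max_epochs == 0:
        return model, history

    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.lr)
    best_state = model.get_state()
    best_dice = -np.inf
    epochs_since_sched_improve = 0
    sched_best = -np.inf

    train_arrays = [_stack_arrays(c) for c in train_cases]
    val_arrays = [_stack_arrays(c) for c in val_cases]

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_arrays))
        losses = []
        for i in order:
            arr, lab = train_arrays[i]
            crop, lab_crop = _random_crop(arr, lab, cfg.crop_shape, model.cfg.depth, rng)
            crop, lab_crop, _ = augment_sample(crop, lab_crop, p=cfg.aug_probability, rng=rng)
            prob = model.forward(crop)
            losses.append(soft_dice_loss(prob, lab_crop))
            opt.zero_grad()
            model.backward(_dice_loss_grad(prob, lab_crop))
            opt.step()

        val_scores = []
        for arr, lab in val_arrays:
            padded, un = _pad_to_divisible(arr, 2**model.cfg.depth)
            prob = model.forward(padded)[un]
            val_scores.append(_binary_dice(prob >= 0.5, lab > 0))
        val_dice = float(np.mean(val_scores))
        history.epochs.append(
            EpochRecord(epoch=epoch, train_loss=float(np.mean(losses)), val_dice=val_dice, lr=opt.lr)
        )

        if val_dice > best_dice:
            best_dice = val_dice
            best_state = model.get_state()

        # plateau scheduler: strict improvement resets its own counter
        if val_dice > sched_best:
            sched_best = val_dice
            epochs_since_sched_improve = 0
        else:
            epochs_since_sched_improve += 1
            if epochs_since_sched_improve >= cfg.scheduler_patience:
                opt.lr *= cfg.scheduler_factor
                epochs_since_sched_improve = 0

        if should_stop(history.val_dice, cfg.early_stop_patience):
            break

    model.set_state(best_state)
    return model, history


def predict_volume(
    model: UNet3D,
    stack: ChannelStack | np.ndarray,
    window: tuple[int, int, int] | None = None,
    overlap: float = 0.5,
    threshold: float = 0.5,
) -> VolumeGrid:
    """Full-volume inference by sliding-window probability averaging.

    Windows step by ``window * (1 - overlap)``; overlapping probabilities
    are averaged before thresholding. With ``window=None``, or a window at
    least as large as the volume, a single padded forward pass is used.
    Output is a binary mask on the input grid.
    """
    if isinstance(stack, ChannelStack):
        arr = stack.as_array()
        spacing = stack.spacing_mm
    else:
        arr = np.asarray(stack, np.float32)
        spacing = (1.0, 1.0, 1.0)
    shape = arr.shape[1:]
    div = 2**model.cfg.depth

    if window is None or all(w >= s for w, s in zip(window, shape)):
        padded, un = _pad_to_divisible(arr, div)
        prob = model.forward(padded)[un]
        return VolumeGrid((prob >= threshold).astype(np.uint8), spacing_mm=spacing)

    window = tuple(int(w) for w in window)
    if any(w % div for w in window):
        raise ParameterError(f"window {window} must be divisible by 2**depth = {div}")
    if not 0.0 <= overlap < 1.0:
        raise ParameterError("overlap must be in [0, 1)")

    steps = [max(1, int(round(w * (1 - overlap)))) for w in window]
    starts_per_axis = []
    for s, w, st in zip(shape, window, steps):
        starts = list(range(0, max(s - w, 0) + 1, st))
        if starts[-1] != s - w and s > w:
            starts.append(s - w)
        starts_per_axis.append(starts)

    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.float64)
    for i in starts_per_axis[0]:
        for j in starts_per_axis[1]:
            for k in starts_per_axis[2]:
                sl = (
                    slice(i, i + window[0]),
                    slice(j, j + window[1]),
                    slice(k, k + window[2]),
                )
                tile = np.ascontiguousarray(arr[(slice(None), *sl)])
                padded, un = _pad_to_divisible(tile, div)
                acc[sl] += model.forward(padded)[un]
                cnt[sl] += 1.0
    prob = acc / np.maximum(cnt, 1.0)
    return VolumeGrid((prob >= threshold).astype(np.uint8), spacing_mm=spacing)
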