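"""The virtual-staining U-net: a symmetric encoder-decoder trained with an
MAE loss and Adam to map (phase-gradient-x, phase-gradient-y, phase) stacks
to single-channel stain images.

Architecture
------------
Four encoder blocks of (conv3x3 -> ReLU) x 2 with channel schedule C, 2C,
4C, 8C, each followed by stride-2 average pooling; four decoder levels,
each = bilinear x2 upsampling -> 1x1 projection to the skip's channel
count -> concatenation with the same-level encoder features (doubling the
channels) -> (conv3x3 -> ReLU) x 2 mapping the 2k concatenated channels to
k/2 outputs (a 4x channel reduction per block); a final 1x1 convolution
produces the single-channel stain.  The default geometry consumes
512 x 512 x 3 and emits 512 x 512 x 1; the "reduced" preset (side 128,
base 16) is the same network at desk scale.

The implementation is pure NumPy (see :mod:`holostain.nn`); training
determinism is platform-scoped: a fixed seed reproduces runs on one
platform but is not guaranteed bit-portable across BLAS builds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .preprocess import InputStack

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "TrainHistory",
    "TrainingExample",
    "UNet",
    "relu",
    "mae_loss",
    "build_model",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


# ----------------------------------------------------------------------
# Elementwise pieces (the network's two closed-form ingredients)
# ----------------------------------------------------------------------

def relu(x):
    """Rectified linear unit, ``max(x, 0)``, elementwise."""
    return np.maximum(x, 0)


def mae_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute error ``(1/m) sum |y_i - f(x_i)|`` over all elements."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return float(np.mean(np.abs(truth.astype(np.float64) - pred.astype(np.float64))))


# ----------------------------------------------------------------------
# Configuration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class UNetConfig:
    levels: int = 4
    base_channels: int = 64
    input_side: int = 512
    in_channels: int = 3
    out_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.base_channels < 2 or self.base_channels % 2:
            raise ValueError("base_channels must be an even number >= 2")
        if self.input_side % (2**self.levels) != 0:
            raise ValueError(
                f"input_side {self.input_side} must be divisible by "
                f"2^levels = {2**self.levels}"
            )
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")

    @classmethod
    def reduced(cls, in_channels: int = 3, seed: int = 0) -> "UNetConfig":
        """Desk-scale preset: side 128, base 16 channels."""
        return cls(base_channels=16, input_side=128, in_channels=in_channels, seed=seed)


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    betas: Tuple[float, float] = (0.9, 0.999)
    batch_size: int = 8
    epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @classmethod
    def reduced(cls, seed: int = 0) -> "TrainConfig":
        """Desk-scale preset: batch 4, 30 epochs."""
        return cls(batch_size=4, epochs=30, seed=seed)


@dataclass
class TrainHistory:
    train_mae: List[float] = dc_field(default_factory=list)
    val_mae: List[float] = dc_field(default_factory=list)
    best_epoch: int = -1
    checkpoint_path: Optional[str] = None

    @property
    def best_val_mae(self) -> float:
        return min(self.val_mae) if self.val_mae else float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainingExample:
    """One (input stack crop, stain target crop) pair with provenance."""

    input: np.ndarray  # (C, H, W)
    target: np.ndarray  # (H, W)
    example_id: str = ""
    split: str = ""

    def __post_init__(self) -> None:
        if self.input.ndim != 3 or self.target.ndim != 2:
            raise ValueError("input must be (C, H, W), target (H, W)")
        if self.input.shape[1:] != self.target.shape:
            raise ValueError("input channels and target must share side lengths")


# ----------------------------------------------------------------------
# Model
# ----------------------------------------------------------------------

class UNet:
    """Encoder-decoder network; see the module docstring for the wiring."""

    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        C = cfg.base_channels
        enc_ch = [C * 2**i for i in range(cfg.levels)]

        self.enc: List[nn.DoubleConv] = []
        cin = cfg.in_channels
        for ch in enc_ch:
            self.enc.append(nn.DoubleConv(cin, ch, rng))
            cin = ch
        # decoder runs deepest-first; skip channels reversed
        self.dec_proj: List[nn.Conv1x1] = []
        self.dec: List[nn.DoubleConv] = []
        cur = enc_ch[-1]
        for skip in reversed(enc_ch):
            self.dec_proj.append(nn.Conv1x1(cur, skip, rng))
            self.dec.append(nn.DoubleConv(2 * skip, skip // 2, rng))
            cur = skip // 2
        self.final = nn.Conv1x1(cur, cfg.out_channels, rng)

    # -- parameter access ------------------------------------------------
    def _layers(self) -> List:
        out: List = []
        for blk in self.enc:
            out.extend(blk.layers())
        for proj, blk in zip(self.dec_proj, self.dec):
            out.append(proj)
            out.extend(blk.layers())
        out.append(self.final)
        return out

    def parameters(self) -> List[np.ndarray]:
        ps: List[np.ndarray] = []
        for layer in self._layers():
            ps.extend([layer.W, layer.b])
        return ps

    def gradients(self) -> List[np.ndarray]:
        gs: List[np.ndarray] = []
        for layer in self._layers():
            gs.extend([layer.dW, layer.db])
        return gs

    def state_dict(self) -> dict:
        return {f"p{i}": p.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            src = state[f"p{i}"]
            if src.shape != p.shape:
                raise ValueError(f"parameter p{i} shape mismatch: {src.shape} vs {p.shape}")
            p[...] = src

    # -- forward / backward ---------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected input (N, {self.cfg.in_channels}, H, W), got {x.shape}"
            )
        h, w = x.shape[2:]
        d = 2**self.cfg.levels
        if h % d or w % d:
            raise ValueError(f"input side must be divisible by {d}, got {h}x{w}")

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        self._check_input(x)
        h = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # NCHW -> NHWC
        skips: List[np.ndarray] = []
        for blk in self.enc:
            h = blk.forward(h, train)
            skips.append(h)
            h = nn.avgpool2(h)
        self._skip_ch = [s.shape[3] for s in skips]
        for proj, blk, skip in zip(self.dec_proj, self.dec, reversed(skips)):
            h = nn.upsample2(h)
            h = proj.forward(h, train)
            h = np.concatenate([h, skip], axis=3)
            h = blk.forward(h, train)
        y = self.final.forward(h, train)
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))  # NHWC -> NCHW

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(
            np.asarray(dy, dtype=nn.DTYPE).transpose(0, 2, 3, 1)
        )
        dh = self.final.backward(dy)
        n_lvl = self.cfg.levels
        dskips: List[Optional[np.ndarray]] = [None] * n_lvl
        for d_idx in reversed(range(n_lvl)):
            proj, blk = self.dec_proj[d_idx], self.dec[d_idx]
            skip_level = n_lvl - 1 - d_idx
            k = self._skip_ch[skip_level]
            d = blk.backward(dh)
            dskips[skip_level] = np.ascontiguousarray(d[..., k:])
            dh = nn.upsample2_backward(proj.backward(np.ascontiguousarray(d[..., :k])))
        for i in reversed(range(n_lvl)):
            d = nn.avgpool2_backward(dh) + dskips[i]
            dh = self.enc[i].backward(d)
        return np.ascontiguousarray(dh.transpose(0, 3, 1, 2))


def build_model(cfg: Optional[UNetConfig] = None) -> UNet:
    """Construct a seeded U-net from its configuration."""
    return UNet(cfg or UNetConfig())


# ----------------------------------------------------------------------
# Training
# ----------------------------------------------------------------------

def _as_batches(
    examples: Sequence[TrainingExample], order: Iterable[int], batch_size: int
):
    idx = list(order)
    for i in range(0, len(idx), batch_size):
        chunk = idx[i : i + batch_size]
        x = np.stack([examples[j].input for j in chunk]).astype(nn.DTYPE)
        y = np.stack([examples[j].target[None] for j in chunk]).astype(nn.DTYPE)
        yield chunk, x, y


def _dataset_mae(model: UNet, examples: Sequence[TrainingExample], batch_size: int) -> float:
    total, count = 0.0, 0
    for _, x, y in _as_batches(examples, range(len(examples)), batch_size):
        pred = model.forward(x, train=False)
        total += float(np.sum(np.abs(pred.astype(np.float64) - y)))
        count += y.size
    return total / count


def train(
    model: UNet,
    train_set: Sequence[TrainingExample],
    val_set: Sequence[TrainingExample],
    tcfg: Optional[TrainConfig] = None,
) -> Tuple[UNet, TrainHistory]:
    """Adam minimization of the MAE loss with early stopping on
    validation MAE; returns the model restored to its best-validation
    state plus the per-epoch history."""
    tcfg = tcfg or TrainConfig()
    if not len(train_set) or not len(val_set):
        raise ValueError("train and validation sets must be non-empty")
    train_ids = {e.example_id for e in train_set if e.example_id}
    val_ids = {e.example_id for e in val_set if e.example_id}
    if train_ids & val_ids:
        raise ValueError(f"train/val splits overlap: {sorted(train_ids & val_ids)[:5]}")

    rng = np.random.default_rng(tcfg.seed)
    opt = nn.Adam(model.parameters(), lr=tcfg.lr, betas=tcfg.betas)
    history = TrainHistory()
    best_state: Optional[dict] = None
    best_val = np.inf

    for epoch in range(tcfg.epochs):
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for chunk, x, y in _as_batches(train_set, order, tcfg.batch_size):
            pred = model.forward(x, train=True)
            diff = pred - y
            loss = float(np.mean(np.abs(diff)))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch ids {chunk} "
                    f"(lr={tcfg.lr})"
                )
            model.backward(np.sign(diff) / nn.DTYPE(diff.size))
            opt.step(model.gradients())
            epoch_losses.append(loss)
        history.train_mae.append(float(np.mean(epoch_losses)))
        val = _dataset_mae(model, val_set, tcfg.batch_size)
        history.val_mae.append(val)
        if val < best_val:
            best_val = val
            best_state = model.state_dict()
            history.best_epoch = epoch
        elif epoch - history.best_epoch >= tcfg.patience:
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


# ----------------------------------------------------------------------
# Inference
# ----------------------------------------------------------------------

def predict(
    model: UNet,
    stack: Union[InputStack, np.ndarray],
    batch_size: int = 8,
) -> np.ndarray:
    """Stain map(s) for one input stack or a batch.

    Accepts an :class:`InputStack`, a (C, H, W) array, or a (N, C, H, W)
    batch; returns (H, W) or (N, H, W) clipped to [0, 1].
    """
    if isinstance(stack, InputStack):
        x = stack.channels
    else:
        x = np.asarray(stack)
    single = x.ndim == 3
    if single:
        x = x[None]
    if x.ndim != 4:
        raise ValueError(f"expected (C, H, W) or (N, C, H, W), got {x.shape}")
    outs = []
    for i in range(0, len(x), batch_size):
        pred = model.forward(x[i : i + batch_size], train=False)
        outs.append(pred[:, 0])
    out = np.clip(np.concatenate(outs, axis=0), 0.0, 1.0)
    return out[0] if single else out


# ----------------------------------------------------------------------
# Checkpointing
# ----------------------------------------------------------------------

def save_checkpoint(
    model: UNet,
    path: str | Path,
    history: Optional[TrainHistory] = None,
    extra_meta: Optional[dict] = None,
) -> Path:
    """Write weights (``.npz``) plus a JSON metadata sidecar; returns the
    weights path."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    meta = {"unet_config": asdict(model.cfg), "format": 1}
    if history is not None:
        meta["history"] = history.to_dict()
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def load_checkpoint(path: str | Path) -> UNet:
    """Rebuild a model from a checkpoint; predictions are bit-identical to
    the saved model's."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    model = UNet(UNetConfig(**meta["unet_config"]))
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
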