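"""The DiCARN network: cascading residual blocks with dilated convolutions and
spatial self-attention, trained under MSE loss to map low-coverage contact-map
tiles to their high-coverage counterparts.

Architecture (all spatial sizes preserved by zero padding):

* an entry 3x3 convolution lifts the single-channel 40x40 tile to ``channels``
  feature maps;
* ``n_cascades`` cascading layers follow.  Each layer applies a residual block
  (two dilated 3x3 convolutions with ReLU, a concluding 1x1 convolution, and an
  identity skip), then concatenates the block output with all earlier cascade
  features and fuses them through a 1x1 convolution — the "cascading" recombination;
* spatial self-attention (single-head query/key/value over flattened positions,
  residual-gated by a learnable scalar ``gamma`` initialized to 0) is applied
  after the cascading layers whose 1-based index is in ``attention_blocks``;
* a tail stack of dilated 3x3 convolutions and a final 1x1 convolution produce
  the single-channel enhanced tile.

Dilation spaces the kernel taps ``dilation_rate`` pixels apart, enlarging the
receptive field at constant parameter count; ``dilated_conv_reference`` is the
1-D scalar semantics every 2-D layer must match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .autograd import Adam, Parameter, Tensor, concat, conv2d, he_uniform
from .errors import DataError, DivergenceError, ShapeError, ValidationError
from .hic_io import TileSet
from .metrics import MetricParams, compute_mse, ssim


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the configuration found optimal for this architecture
    family: five cascading blocks, dilation rate 2 (two dilated convolutions
    per residual block plus a dilated stack at the network tail), and spatial
    self-attention on the first two cascade blocks only.  ``attention_blocks``
    uses 1-based cascade indices.
    """

    n_cascades: int = 5
    channels: int = 64
    kernel: int = 3
    dilation_rate: int = 2
    attention_blocks: tuple[int, ...] = (1, 2)
    tail_dilated_stack: int = 2
    tile_size: int = 40
    attention_reduction: int = 8

    def __post_init__(self) -> None:
        self.attention_blocks = tuple(sorted(set(self.attention_blocks)))
        if self.n_cascades < 1:
            raise ValidationError("n_cascades must be >= 1")
        if self.dilation_rate < 1:
            raise ValidationError("dilation_rate must be >= 1")
        bad = [b for b in self.attention_blocks if not (1 <= b <= self.n_cascades)]
        if bad:
            raise ValidationError(f"attention_blocks {bad} outside 1..{self.n_cascades}")

    @property
    def attn_channels(self) -> int:
        return max(self.channels // self.attention_reduction, 1)

    def to_dict(self) -> dict:
        return {
            "n_cascades": self.n_cascades,
            "channels": self.channels,
            "kernel": self.kernel,
            "dilation_rate": self.dilation_rate,
            "attention_blocks": list(self.attention_blocks),
            "tail_dilated_stack": self.tail_dilated_stack,
            "tile_size": self.tile_size,
            "attention_reduction": self.attention_reduction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["attention_blocks"] = tuple(d.get("attention_blocks", ()))
        return cls(**d)


@dataclass
class TrainConfig:
    """Optimization settings: Adam under MSE loss, fully seeded."""

    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 10
    seed: int = 0
    loss: str = "mse"

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.loss != "mse":
            raise ValidationError("only MSE loss is supported")

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "seed": self.seed,
            "loss": self.loss,
        }


@dataclass
class NetworkState:
    """Serializable snapshot: weights, config and model-selection bookkeeping."""

    weights: dict[str, np.ndarray]
    config: ModelConfig
    epoch: int = 0
    best_validation_score: float = float("nan")
    train_config: TrainConfig | None = None
    log: list[tuple[int, float, float]] = field(default_factory=list)  # (epoch, train_mse, val_ssim)


# ---------------------------------------------------------------------------
# Reference semantics
# ---------------------------------------------------------------------------

def dilated_conv_reference(x: Sequence[float], w: Sequence[float], d: int) -> np.ndarray:
    """1-D dilated convolution defining the tap semantics of the 2-D layers.

    ``out[i] = sum_k x[i + d * k] * w[k]`` for ``k = 0..len(w)-1`` over every
    ``i`` where the dilated footprint fits; the valid-region length is
    ``len(x) - d * (len(w) - 1)``.  The 2-D layers apply the same spacing
    independently per axis (with zero padding to preserve spatial size).
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    span = 1 + d * (len(w) - 1)
    if len(x) < span:
        raise ShapeError(f"sequence length {len(x)} shorter than dilated footprint {span}")
    n_out = len(x) - d * (len(w) - 1)
    out = np.zeros(n_out)
    for k, wk in enumerate(w):
        out += x[d * k : d * k + n_out] * wk
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Conv:
    def __init__(self, name: str, cin: int, cout: int, k: int, dilation: int,
                 rng: np.random.Generator, zero_init: bool = False):
        self.name = name
        self.dilation = dilation
        self.padding = dilation * (k - 1) // 2
        fan_in = cin * k * k
        w = np.zeros((cout, cin, k, k)) if zero_init else he_uniform(rng, (cout, cin, k, k), fan_in)
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, dilation=self.dilation, padding=self.padding)

    def params(self) -> dict[str, Parameter]:
        return {f"{self.name}.w": self.w, f"{self.name}.b": self.b}


class SelfAttention2d:
    """Single-head spatial self-attention with a learnable residual gate.

    Query/key/value maps are 1x1 convolutions; attention weights are a softmax
    over flattened spatial positions (each row sums to 1); the output is
    ``gamma * attended + input`` with ``gamma`` initialized to 0 so the module
    starts as an exact identity.
    """

    def __init__(self, name: str, channels: int, attn_channels: int, rng: np.random.Generator):
        self.name = name
        self.q = _Conv(f"{name}.q", channels, attn_channels, 1, 1, rng)
        self.k = _Conv(f"{name}.k", channels, attn_channels, 1, 1, rng)
        self.v = _Conv(f"{name}.v", channels, channels, 1, 1, rng)
        self.gamma = Parameter(np.zeros(()))

    def attention_map(self, x: Tensor) -> Tensor:
        """The ``(N, HW, HW)`` row-stochastic attention matrix for ``x``."""
        n, c, h, w = x.data.shape
        if not np.all(np.isfinite(x.data)):
            raise ValidationError("non-finite features passed to attention")
        hw = h * w
        qf = self.q(x).reshape(n, -1, hw).transpose(0, 2, 1)  # (N, HW, Cq)
        kf = self.k(x).reshape(n, -1, hw)  # (N, Cq, HW)
        return qf.matmul(kf).softmax(axis=-1)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        hw = h * w
        attn = self.attention_map(x)
        vf = self.v(x).reshape(n, c, hw)
        out = vf.matmul(attn.transpose(0, 2, 1)).reshape(n, c, h, w)
        return self.gamma * out + x

    def params(self) -> dict[str, Parameter]:
        d = {}
        for layer in (self.q, self.k, self.v):
            d.update(layer.params())
        d[f"{self.name}.gamma"] = self.gamma
        return d


class ResidualBlock:
    """Two dilated 3x3 convolutions with ReLU, a 1x1 convolution, and an
    identity skip: ``out = conv1x1(relu(conv(relu(conv(x))))) + x``."""

    def __init__(self, name: str, channels: int, k: int, dilation: int, rng: np.random.Generator):
        self.conv1 = _Conv(f"{name}.conv1", channels, channels, k, dilation, rng)
        self.conv2 = _Conv(f"{name}.conv2", channels, channels, k, dilation, rng)
        self.proj = _Conv(f"{name}.proj", channels, channels, 1, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        return self.proj(h) + x

    def params(self) -> dict[str, Parameter]:
        d = {}
        for layer in (self.conv1, self.conv2, self.proj):
            d.update(layer.params())
        return d


class DiCARN:
    """The full network.  Deterministically initialized from ``seed``."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c, k, d = config.channels, config.kernel, config.dilation_rate
        self.entry = _Conv("entry", 1, c, k, 1, rng)
        self.blocks = [
            ResidualBlock(f"cascade{b}.res", c, k, d, rng)
            for b in range(1, config.n_cascades + 1)
        ]
        self.fuse = [
            _Conv(f"cascade{b}.fuse", (b + 1) * c, c, 1, 1, rng)
            for b in range(1, config.n_cascades + 1)
        ]
        self.attn = {
            b: SelfAttention2d(f"cascade{b}.attn", c, config.attn_channels, rng)
            for b in config.attention_blocks
        }
        self.tail = [
            _Conv(f"tail{i}", c, c, k, d, rng) for i in range(config.tail_dilated_stack)
        ]
        self.head = _Conv("head", c, 1, 1, 1, rng)

    # -- parameters --------------------------------------------------------
    def named_parameters(self) -> dict[str, Parameter]:
        d = self.entry.params()
        for b, blk in enumerate(self.blocks, 1):
            d.update(blk.params())
            d.update(self.fuse[b - 1].params())
            if b in self.attn:
                d.update(self.attn[b].params())
        for layer in self.tail:
            d.update(layer.params())
        d.update(self.head.params())
        return d

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_weights(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_weights(self, weights: dict[str, np.ndarray]) -> None:
        named = self.named_parameters()
        if set(named) != set(weights):
            raise ShapeError("weight names do not match the configured architecture")
        for k, p in named.items():
            if p.data.shape != weights[k].shape:
                raise ShapeError(f"weight {k}: shape {weights[k].shape} != {p.data.shape}")
            p.data = weights[k].astype(np.float64).copy()

    @classmethod
    def from_state(cls, state: NetworkState) -> "DiCARN":
        net = cls(state.config, seed=0)
        net.load_weights(state.weights)
        return net

    # -- forward -----------------------------------------------------------
    def forward(self, x: Tensor) -> Tensor:
        h = self.entry(x).relu()
        feats = [h]
        for b, blk in enumerate(self.blocks, 1):
            r = blk(h)
            feats.append(r)
            h = self.fuse[b - 1](concat(feats, axis=1)).relu()
            if b in self.attn:
                h = self.attn[b](h)
        for layer in self.tail:
            h = layer(h).relu()
        return self.head(h)

    def predict(self, tiles: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Forward a ``(n, size, size)`` stack without building gradients."""
        tiles = np.asarray(tiles, dtype=float)
        outs = []
        params = self.parameters()
        flags = [p.requires_grad for p in params]
        for p in params:
            p.requires_grad = False
        try:
            for i in range(0, len(tiles), batch_size):
                x = Tensor(tiles[i : i + batch_size, None])
                outs.append(self.forward(x).data[:, 0])
        finally:
            for p, f in zip(params, flags):
                p.requires_grad = f
        return np.concatenate(outs) if outs else np.empty((0,) + tiles.shape[1:])


def residual_block_forward(x: np.ndarray, state: NetworkState, block_id: int) -> np.ndarray:
    """Run one residual block of a stored network on ``(N, C, H, W)`` features."""
    net = DiCARN.from_state(state)
    if not (1 <= block_id <= state.config.n_cascades):
        raise ValidationError(f"block_id {block_id} outside 1..{state.config.n_cascades}")
    x = np.asarray(x, dtype=float)
    if x.shape[1] != state.config.channels:
        raise ShapeError(f"expected {state.config.channels} channels, got {x.shape[1]}")
    return net.blocks[block_id - 1](Tensor(x)).data


def spatial_self_attention(features: np.ndarray, gamma: float, seed: int = 0,
                           return_attention: bool = False):
    """Apply a seeded self-attention module to ``(C, H, W)`` features.

    With ``gamma = 0`` the output equals the input exactly.  Set
    ``return_attention=True`` to also get the row-stochastic attention matrix.
    """
    features = np.asarray(features, dtype=float)
    c = features.shape[0]
    rng = np.random.default_rng(seed)
    mod = SelfAttention2d("attn", c, max(c // 8, 1), rng)
    mod.gamma.data = np.asarray(float(gamma))
    x = Tensor(features[None])
    out = mod(x).data[0]
    if return_attention:
        return out, mod.attention_map(x).data[0]
    return out


# ---------------------------------------------------------------------------
# Closed-form bookkeeping
# ---------------------------------------------------------------------------

def count_parameters(config: ModelConfig) -> int:
    """Analytic parameter count; independent of ``dilation_rate`` because
    dilation spaces taps without adding weights."""
    c, k = config.channels, config.kernel
    ca = config.attn_channels
    n = c * k * k + c  # entry
    for b in range(1, config.n_cascades + 1):
        n += 2 * (c * c * k * k + c) + (c * c + c)  # residual block
        n += (b + 1) * c * c + c  # cascade fusion 1x1
        if b in config.attention_blocks:
            n += 2 * (c * ca + ca) + (c * c + c) + 1  # q, k, v, gamma
    n += config.tail_dilated_stack * (c * c * k * k + c)
    n += c + 1  # head 1x1
    return n


def receptive_field_radius(config: ModelConfig) -> int:
    """Chebyshev radius of the (convolutional) receptive field.

    Each 3x3 convolution with dilation ``d`` adds ``d * (k - 1) / 2`` to the
    radius; 1x1 convolutions add nothing.  Self-attention is global but starts
    gated shut (``gamma = 0``), so this radius is exact at initialization.
    """
    per_conv = (config.kernel - 1) // 2
    r = per_conv  # entry, dilation 1
    r += config.n_cascades * 2 * config.dilation_rate * per_conv
    r += config.tail_dilated_stack * config.dilation_rate * per_conv
    return r


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _paired_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Accept (TileSet, TileSet) aligned by offsets, or a sequence of
    (lr, hr) array pairs; return (n, size, size) stacks."""
    if isinstance(pairs, tuple) and len(pairs) == 2 and isinstance(pairs[0], TileSet):
        lr_ts, hr_ts = pairs
        if len(lr_ts) != len(hr_ts):
            raise DataError("LR/HR tile sets differ in length")
        for a, b in zip(lr_ts.tiles, hr_ts.tiles):
            if (a.row_offset, a.col_offset) != (b.row_offset, b.col_offset):
                raise DataError("LR/HR tiles are not aligned by offset")
        return lr_ts.arrays(), hr_ts.arrays()
    lrs, hrs = zip(*pairs) if len(pairs) else ((), ())
    return (np.stack([np.asarray(a, float) for a in lrs]) if lrs else np.empty((0, 0, 0)),
            np.stack([np.asarray(b, float) for b in hrs]) if hrs else np.empty((0, 0, 0)))


def train_model(train, val, mcfg: ModelConfig, tcfg: TrainConfig) -> NetworkState:
    """Train under MSE loss with per-epoch validation-SSIM model selection.

    After every epoch the mean SSIM between the network's validation
    predictions and the validation targets is computed; the weights from the
    best-scoring epoch are returned.  Fully deterministic for a fixed
    ``tcfg.seed``.  The per-epoch curve is recorded in ``NetworkState.log``
    as ``(epoch, train_mse, val_ssim)`` tuples.
    """
    x_tr, y_tr = _paired_arrays(train)
    x_va, y_va = _paired_arrays(val)
    if x_tr.shape[0] == 0:
        raise DataError("empty training set")
    net = DiCARN(mcfg, seed=tcfg.seed)
    opt = Adam(net.parameters(), lr=tcfg.learning_rate)
    rng = np.random.default_rng(tcfg.seed + 1)
    mp = MetricParams(L=1.0)
    best_weights = net.state_weights()
    best_score = -np.inf
    best_epoch = 0
    log: list[tuple[int, float, float]] = []
    n = x_tr.shape[0]
    for epoch in range(1, tcfg.epochs + 1):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for i in range(0, n, tcfg.batch_size):
            idx = order[i : i + tcfg.batch_size]
            xb = Tensor(x_tr[idx][:, None])
            yb = Tensor(y_tr[idx][:, None])
            pred = net.forward(xb)
            loss = (pred - yb).square().mean()
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch}", epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
            seen += len(idx)
        train_mse = total / seen
        if x_va.shape[0]:
            pv = net.predict(x_va, batch_size=tcfg.batch_size)
            val_ssim = float(np.mean([ssim(pv[i], y_va[i], mp) for i in range(len(pv))]))
        else:
            val_ssim = float("nan")
        log.append((epoch, train_mse, val_ssim))
        score = val_ssim if x_va.shape[0] else -train_mse
        if score > best_score:
            best_score = score
            best_epoch = epoch
            best_weights = net.state_weights()
    return NetworkState(
        weights=best_weights,
        config=mcfg,
        epoch=best_epoch,
        best_validation_score=best_score,
        train_config=tcfg,
        log=log,
    )


def model_forward(tiles: TileSet, state: NetworkState, batch_size: int = 64) -> TileSet:
    """Enhance every tile of a TileSet; offsets and ordering are preserved."""
    size = state.config.tile_size
    for t in tiles.tiles:
        if t.values.shape != (size, size):
            raise ShapeError(f"expected {size}x{size} tiles, got {t.values.shape}")
    net = DiCARN.from_state(state)
    out = net.predict(tiles.arrays(), batch_size=batch_size)
    if not np.all(np.isfinite(out)):
        raise DivergenceError("non-finite prediction", state.epoch)
    return tiles.with_values(out)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state: NetworkState, path) -> None:
    """Weights + configs + selection metadata in one ``.npz`` archive."""
    meta = {
        "config": state.config.to_dict(),
        "train_config": state.train_config.to_dict() if state.train_config else None,
        "epoch": state.epoch,
        "best_validation_score": state.best_validation_score,
        "log": state.log,
    }
    np.savez_compressed(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{f"w/{k}": v for k, v in state.weights.items()},
    )


def load_checkpoint(path) -> NetworkState:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
        weights = {k[2:]: npz[k] for k in npz.files if k.startswith("w/")}
    tc = TrainConfig(**meta["train_config"]) if meta.get("train_config") else None
    return NetworkState(
        weights=weights,
        config=ModelConfig.from_dict(meta["config"]),
        epoch=int(meta["epoch"]),
        best_validation_score=float(meta["best_validation_score"]),
        train_config=tc,
        log=[tuple(e) for e in meta.get("log", [])],
    )
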