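"""Backbone architectures for chest-radiograph nodule screening.

Two classifiers are built here:

* a baseline 50-layer residual network whose 1000-class head is replaced
  by a 2-class (nodule / no-nodule) linear layer, and
* a hybrid that inserts one lightweight multi-scale transformer (MST)
  block after each of the four backbone stages and routes the enriched
  top-stage features through a parameter-free multiplicative spatial
  attention gate, producing both class logits and a weak-localization
  attention map at input resolution.

The MST block operates on stage features of width C: the map is
adaptively average-pooled to a 14x14 token grid whenever its spatial
extent exceeds 14, tokenized (one token per cell, embedding width C),
passed through a pre-norm 2-head self-attention sub-layer with an inner
residual, then a pre-norm two-layer GELU MLP whose *output* (not a
residual sum) is reshaped, bilinearly upsampled back to the stage
resolution, and added to the untouched stage features. The block
therefore costs exactly 6C^2 + 10C parameters (biased q/k/v + output
projections, two biased C->C MLP layers, two layer norms, no positional
embeddings), and zeroing its projection weights makes it an exact
identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from . import nn
from .nn import core

#: (channels, side) of each backbone stage for a 224x224 input
STAGE_SHAPES = {1: (256, 56), 2: (512, 28), 3: (1024, 14), 4: (2048, 7)}

CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class MSTBlockConfig:
    """Transformer-block hyperparameters (defaults as used throughout)."""

    num_heads: int = 2
    mlp_ratio: float = 1.0
    dropout: float = 0.1
    attn_grid: int = 14

    def validate(self, channels: int | None = None):
        if self.attn_grid <= 0:
            raise ValueError(f"attn_grid must be positive, got {self.attn_grid}")
        if self.num_heads < 1:
            raise ValueError("num_heads must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if channels is not None and channels % self.num_heads:
            raise ValueError(f"channels {channels} not divisible by num_heads {self.num_heads}")


@dataclass(frozen=True)
class BackboneConfig:
    """Which stages carry MST blocks, head width, and block settings."""

    mst_stages: frozenset[int] = frozenset({1, 2, 3, 4})
    num_classes: int = 2
    pretrained: bool = False
    block: MSTBlockConfig = field(default_factory=MSTBlockConfig)

    def __post_init__(self):
        object.__setattr__(self, "mst_stages", frozenset(self.mst_stages))
        bad = self.mst_stages - {1, 2, 3, 4}
        if bad:
            raise ValueError(f"invalid MST stage indices {sorted(bad)}; stages are 1-4")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        for s in self.mst_stages:
            self.block.validate(STAGE_SHAPES[s][0])

    def to_json(self) -> str:
        d = asdict(self)
        d["mst_stages"] = sorted(self.mst_stages)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "BackboneConfig":
        d = json.loads(s)
        d["block"] = MSTBlockConfig(**d["block"])
        d["mst_stages"] = frozenset(d["mst_stages"])
        return cls(**d)


@dataclass
class ModelOutput:
    """Forward-pass result of the hybrid model."""

    logits: core.Tensor  # (N, num_classes), graph-connected
    probabilities: np.ndarray  # (N, num_classes) softmax
    nodule_probability: np.ndarray  # (N,) positive-class probability
    attention_map: np.ndarray  # (N, H, W) in [0, 1]
    attention_degenerate: np.ndarray  # (N,) bool: constant gate, map zeroed


# ---------------------------------------------------------------------
# residual backbone


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_channels: int, width: int, stride: int = 1):
        super().__init__()
        out_channels = width * self.expansion
        self.conv1 = nn.Conv2d(in_channels, width, 1)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, stride=stride, padding=1)
        self.bn2 = nn.BatchNorm2d(width)
        self.conv3 = nn.Conv2d(width, out_channels, 1)
        self.bn3 = nn.BatchNorm2d(out_channels)
        if stride != 1 or in_channels != out_channels:
            self.downsample = nn.Sequential(
                nn.Conv2d(in_channels, out_channels, 1, stride=stride),
                nn.BatchNorm2d(out_channels),
            )
        else:
            self.downsample = nn.Identity()

    def forward(self, x):
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h)).relu()
        h = self.bn3(self.conv3(h))
        return (h + self.downsample(x)).relu()


class ResNet50(nn.Module):
    """Standard 50-layer residual network with a configurable head."""

    def __init__(self, num_classes: int = 2):
        super().__init__()
        self.stem = nn.Sequential(
            nn.Conv2d(3, 64, 7, stride=2, padding=3),
            nn.BatchNorm2d(64),
            nn.ReLU(),
            nn.MaxPool2d(3, 2, 1),
        )
        widths = (64, 128, 256, 512)
        depths = (3, 4, 6, 3)
        in_c = 64
        for i, (w, d) in enumerate(zip(widths, depths), start=1):
            blocks = []
            for j in range(d):
                stride = 2 if (j == 0 and i > 1) else 1
                blocks.append(Bottleneck(in_c, w, stride))
                in_c = w * self.expansion_channels(w)
            setattr(self, f"layer{i}", nn.Sequential(*blocks))
        self.fc = nn.Linear(512 * 4, num_classes)

    @staticmethod
    def expansion_channels(width):
        return Bottleneck.expansion

    def stage(self, i: int) -> nn.Sequential:
        return getattr(self, f"layer{i}")

    def forward_features(self, x: core.Tensor) -> core.Tensor:
        h = self.stem(x)
        for i in range(1, 5):
            h = self.stage(i)(h)
        return h

    def forward(self, x: core.Tensor) -> core.Tensor:
        h = self.forward_features(x)
        pooled = h.mean(axis=(2, 3))
        return self.fc(pooled)


# ---------------------------------------------------------------------
# multi-scale transformer block


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, channels: int, num_heads: int, dropout: float):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = channels // num_heads
        self.qkv = nn.Linear(channels, 3 * channels, bias=True)
        self.proj = nn.Linear(channels, channels, bias=True)
        self.attn_drop = nn.Dropout(dropout)

    def forward(self, tokens: core.Tensor) -> core.Tensor:
        n, length, c = tokens.shape
        qkv = self.qkv(tokens)  # (N, L, 3C)
        qkv = qkv.reshape(n, length, 3, self.num_heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, N, heads, L, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scale = 1.0 / np.sqrt(self.head_dim)
        attn = core.softmax((q @ k.transpose(0, 1, 3, 2)) * scale, axis=-1)
        attn = self.attn_drop(attn)
        out = attn @ v  # (N, heads, L, hd)
        out = out.transpose(0, 2, 1, 3).reshape(n, length, c)
        return self.proj(out)


class MSTBlock(nn.Module):
    """Pre-norm transformer block fused residually into a CNN stage.

    Pooling to the ``attn_grid`` token grid happens iff the stage's
    spatial extent exceeds the grid; the MLP sub-layer output is
    upsampled back and added to the original stage features.
    """

    def __init__(self, channels: int, cfg: MSTBlockConfig = MSTBlockConfig()):
        super().__init__()
        cfg.validate(channels)
        self.channels = channels
        self.cfg = cfg
        self.norm1 = nn.LayerNorm(channels)
        self.attn = MultiHeadSelfAttention(channels, cfg.num_heads, cfg.dropout)
        self.norm2 = nn.LayerNorm(channels)
        hidden = int(cfg.mlp_ratio * channels)
        self.mlp = nn.Sequential(
            nn.Linear(channels, hidden, bias=True),
            nn.GELU(),
            nn.Dropout(cfg.dropout),
            nn.Linear(hidden, channels, bias=True),
            nn.Dropout(cfg.dropout),
        )
        # inspection hooks, populated on every forward
        self.last_token_count: int | None = None
        self.last_pooled: bool | None = None

    def forward(self, x: core.Tensor) -> core.Tensor:
        n, c, h, w = x.shape
        grid = self.cfg.attn_grid
        pooled = h > grid or w > grid
        t = core.adaptive_avg_pool2d(x, (grid, grid)) if pooled else x
        th, tw = t.shape[2], t.shape[3]
        tokens = t.reshape(n, c, th * tw).transpose(0, 2, 1)  # (N, L, C)
        object.__setattr__(self, "last_token_count", th * tw)
        object.__setattr__(self, "last_pooled", pooled)
        tokens = tokens + self.attn(self.norm1(tokens))
        s_mlp = self.mlp(self.norm2(tokens))  # MLP sub-layer output only
        y = s_mlp.transpose(0, 2, 1).reshape(n, c, th, tw)
        if pooled:
            y = core.upsample_bilinear(y, (h, w))
        return x + y

    def zero_projections(self):
        """Zero every projection weight/bias; the block becomes identity."""
        for name, p in self.named_parameters():
            if name.startswith(("attn.", "mlp.")):
                p.data = np.zeros_like(p.data)


def mst_block_parameter_count(channels: int, cfg: MSTBlockConfig = MSTBlockConfig()) -> int:
    """Closed-form parameter cost of one MST block at width C.

    With mlp_ratio 1.0 this is 6C^2 + 10C: q/k/v and output projections
    with bias (4C^2 + 4C), two biased C->C MLP layers (2C^2 + 2C), and
    two layer norms (4C). No positional embeddings.
    """
    cfg.validate(channels)
    c = channels
    hidden = int(cfg.mlp_ratio * c)
    return (3 * c * c + 3 * c) + (c * c + c) + (c * hidden + hidden) + (hidden * c + c) + 4 * c


# ---------------------------------------------------------------------
# spatial attention


@dataclass
class SpatialAttentionResult:
    gated: core.Tensor  # features gated by the spatial sigmoid mask
    attention_map: np.ndarray  # (N, out_h, out_w) min-max rescaled to [0, 1]
    degenerate: np.ndarray  # (N,) bool flags for constant gates


def spatial_attention(features: core.Tensor | np.ndarray, out_size: tuple[int, int] = (224, 224)) -> SpatialAttentionResult:
    """Parameter-free multiplicative spatial attention over stage features.

    The gate is the logistic squashing of the channel-mean map; features
    are multiplied elementwise by the gate (broadcast over channels).
    The returned weak-localization map is the gate bilinearly upsampled
    to ``out_size`` and min-max rescaled per image; a constant gate has
    no spatial preference, so its map is zeroed and flagged degenerate.
    """
    f = features if isinstance(features, core.Tensor) else core.Tensor(np.asarray(features, np.float32))
    raw = f.mean(axis=1, keepdims=True)  # (N, 1, H, W) channel-mean
    gate = raw.sigmoid()
    gated = f * gate

    with core.no_grad():
        up = core.upsample_bilinear(core.Tensor(gate.data), out_size).data[:, 0]  # (N, oh, ow)
        lo = up.min(axis=(1, 2), keepdims=True)
        hi = up.max(axis=(1, 2), keepdims=True)
        span = hi - lo
        degenerate = (span[:, 0, 0] <= 1e-12)
        safe = np.where(span > 1e-12, span, 1.0)
        amap = (up - lo) / safe
        amap[degenerate] = 0.0
    return SpatialAttentionResult(gated=gated, attention_map=amap.astype(np.float32), degenerate=degenerate)


# ---------------------------------------------------------------------
# full hybrid model


class MSTResNet(nn.Module):
    """ResNet-50 interleaved with MST blocks plus the attention branch."""

    def __init__(self, config: BackboneConfig):
        super().__init__()
        self.config = config
        self.backbone = ResNet50(config.num_classes)
        self.mst = nn.ModuleDict(
            {str(s): MSTBlock(STAGE_SHAPES[s][0], config.block) for s in sorted(config.mst_stages)}
        )

    def forward(self, x: core.Tensor | np.ndarray) -> ModelOutput:
        if not isinstance(x, core.Tensor):
            x = core.Tensor(np.asarray(x, np.float32))
        in_h, in_w = x.shape[2], x.shape[3]
        h = self.backbone.stem(x)
        for s in range(1, 5):
            h = self.backbone.stage(s)(h)
            if str(s) in self.mst:
                h = self.mst[str(s)](h)
        att = spatial_attention(h, out_size=(in_h, in_w))
        pooled = att.gated.mean(axis=(2, 3))
        logits = self.backbone.fc(pooled)
        with core.no_grad():
            probs = core.softmax(core.Tensor(logits.data), axis=1).data
        return ModelOutput(
            logits=logits,
            probabilities=probs,
            nodule_probability=probs[:, 1],
            attention_map=att.attention_map,
            attention_degenerate=att.degenerate,
        )

    def zero_mst_projections(self):
        for _, block in self.mst.items():
            block.zero_projections()


# ---------------------------------------------------------------------
# construction / initialization


def _init_resnet(model: ResNet50, rng: np.random.Generator):
    """He-initialize convolutions, unit/zero norms, small-normal head.

    Walks parameters in registration order so the backbone draw sequence
    is identical for every configuration sharing a seed.
    """
    for name, p in model.named_parameters():
        if p.data.ndim == 4:  # conv kernels
            nn.kaiming_normal_(p, rng)
        elif name.startswith("fc.weight"):
            p.data = (rng.standard_normal(p.data.shape) * 0.01).astype(np.float32)
        elif name.endswith("weight"):  # norm scales
            p.data = np.ones_like(p.data)
        else:
            p.data = np.zeros_like(p.data)


def _init_mst_block(block: MSTBlock, rng: np.random.Generator):
    """Truncated-normal(0.02) projections, zero biases, unit/zero norms."""
    for name, p in block.named_parameters():
        if name.endswith("weight") and p.data.ndim == 2:
            nn.trunc_normal_(p, rng, std=0.02)
        elif name in ("norm1.weight", "norm2.weight"):
            p.data = np.ones_like(p.data)
        else:
            p.data = np.zeros_like(p.data)


def build_baseline(num_classes: int = 2, pretrained: bool = False, seed: int = 0) -> ResNet50:
    """Baseline ResNet-50 classifier (2048 -> ``num_classes`` head)."""
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    if pretrained:
        raise RuntimeError(
            "pretrained weights are not bundled and cannot be downloaded in this "
            "environment; pass pretrained=False and fine-tune from scratch"
        )
    model = ResNet50(num_classes)
    _init_resnet(model, np.random.default_rng(seed))
    return model


def build_mst_resnet(config: BackboneConfig | None = None, seed: int = 0) -> MSTResNet:
    """Hybrid model per ``config``; an empty stage set reproduces the baseline
    backbone exactly (plus the parameter-free attention branch)."""
    config = config or BackboneConfig()
    if config.pretrained:
        raise RuntimeError(
            "pretrained weights are not bundled and cannot be downloaded in this "
            "environment; use pretrained=False"
        )
    model = MSTResNet(config)
    # backbone draw is independent of which MST stages exist
    _init_resnet(model.backbone, np.random.default_rng(seed))
    for s in sorted(config.mst_stages):
        _init_mst_block(model.mst[str(s)], np.random.default_rng([seed, 1000 + s]))
    return model


def count_parameters(model: nn.Module, trainable_only: bool = False) -> int:
    return sum(
        p.data.size for _, p in model.named_parameters() if (p.requires_grad or not trainable_only)
    )


def expected_parameter_count(config: BackboneConfig) -> int:
    """Closed-form ledger: baseline count + sum of per-stage MST costs."""
    base = _BASELINE_PARAMS_1000 - (2048 * 1000 + 1000) + (2048 * config.num_classes + config.num_classes)
    return base + sum(mst_block_parameter_count(STAGE_SHAPES[s][0], config.block) for s in config.mst_stages)


_BASELINE_PARAMS_1000 = 25_557_032  # canonical 50-layer network, 1000-class head


# ---------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: MSTResNet | ResNet50, path):
    """Serialize weights + config into a single .npz archive."""
    meta = {"version": CHECKPOINT_VERSION}
    if isinstance(model, MSTResNet):
        meta["kind"] = "mst_resnet"
        meta["config"] = json.loads(model.config.to_json())
    else:
        meta["kind"] = "resnet50"
        meta["num_classes"] = model.fc.weight.shape[0]
    arrays = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, expected_config: BackboneConfig | None = None):
    """Rebuild a model from an archive; refuses mismatched configurations."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        state = {k[len("state/"):]: z[k] for k in z.files if k.startswith("state/")}
    if meta["kind"] == "mst_resnet":
        cfg = BackboneConfig.from_json(json.dumps(meta["config"]))
        if expected_config is not None and cfg != expected_config:
            raise ValueError("checkpoint config does not match the requested configuration")
        model: nn.Module = MSTResNet(cfg)
    else:
        model = ResNet50(meta["num_classes"])
    model.load_state_dict(state)
    model.eval()
    return model
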