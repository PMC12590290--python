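"""The particle-detection network.

Architecture, end to end: a convolutional backbone produces a coarse feature
map ``X in R^{B x C x H x W}``; the map is flattened to a token sequence,
summed with a fixed 2D sinusoidal positional code ``P``, and contextualized
by a transformer encoder into memory ``M``. A decoder then refines ``Q = G x
Qg`` learned queries: each query owns a learnable normalized 2D *reference
point* whose sinusoidal embedding ``P_ref`` is added to the query before
cross-attending to ``M``, and the box head predicts centers as offsets from
that reference point (applied in logit space, squashed by a sigmoid).
Queries are partitioned into ``G`` groups that never see each other in
self-attention, so the decoder behaves as ``G`` independent single-group
decoders with shared weights — during training each ground-truth particle
can then be assigned one query per group (one-to-many supervision), which
raises recall in densely packed micrographs.

Classification is binary (particle vs. background) through a sigmoid head,
matching the focal-loss objective. Every decoder layer emits predictions so
auxiliary losses can supervise intermediate layers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .nn import softmax as softmax_fn

__all__ = [
    "ModelConfig", "GroupedQuerySet", "positional_encoding",
    "reference_encoding", "TinyBackbone", "ResNetBackbone", "build_backbone",
    "EncoderLayer", "DecoderLayer", "ParticleDetector",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    hidden_dim: int = 256
    n_heads: int = 8
    n_encoder_layers: int = 6
    n_decoder_layers: int = 6
    groups: int = 3
    queries_per_group: int = 100
    dropout: float = 0.1
    dim_feedforward: int = 2048
    backbone: str = "resnet101"
    frozen_backbone_stats: bool = True
    temperature: float = 10000.0
    aux_loss: bool = True
    ref_sigma: float = 0.25  # initial cross-attention locality width, normalized units

    def __post_init__(self):
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.hidden_dim % 4:
            raise ValueError("hidden_dim must be divisible by 4 for 2D encodings")
        if min(self.n_decoder_layers, self.groups, self.queries_per_group, self.n_heads) < 1:
            raise ValueError("layer/group/query counts must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def num_queries(self) -> int:
        return self.groups * self.queries_per_group


@dataclass
class GroupedQuerySet:
    """Decoder query state: content, reference points and their encoding."""

    content: Tensor            # (Q, B, C)
    reference_points: Tensor   # (Q, 2), normalized (x, y)
    reference_encoding: Tensor  # (Q, C), recomputed whenever points change
    group_of: np.ndarray       # (Q,) int group index


def positional_encoding(height: int, width: int, channels: int,
                        temperature: float = 10000.0) -> np.ndarray:
    """Fixed 2D sinusoidal code, shape (H, W, C), values in [-1, 1].

    The first C/2 channels encode the column position, the last C/2 the row
    position, each as interleaved sin/cos over a geometric frequency ladder.
    Positions are normalized to one period of the base frequency (column j
    maps to ``2*pi*j/W``), the same scale :func:`reference_encoding` uses for
    normalized points — so a query's reference-point code and the code of the
    memory token at that location align in dot products. Position (0, 0) has
    all sine channels 0 and cosine channels 1.
    """
    if channels % 4:
        raise ValueError("channels must be divisible by 4")
    half = channels // 2
    freq = temperature ** (2 * (np.arange(half // 2)) / half)
    xs = 2.0 * np.pi * (np.arange(width) / width)[:, None] / freq[None, :]
    ys = 2.0 * np.pi * (np.arange(height) / height)[:, None] / freq[None, :]

    def interleave(arg):  # (n, half/2) -> (n, half)
        out = np.empty((arg.shape[0], half))
        out[:, 0::2] = np.sin(arg)
        out[:, 1::2] = np.cos(arg)
        return out

    code_x = interleave(xs)  # (W, half)
    code_y = interleave(ys)  # (H, half)
    pe = np.empty((height, width, channels))
    pe[:, :, :half] = code_x[None, :, :]
    pe[:, :, half:] = code_y[:, None, :]
    return pe


def reference_encoding(points: Tensor, channels: int,
                       temperature: float = 10000.0) -> Tensor:
    """Differentiable sinusoidal embedding of normalized (x, y) points.

    Same trigonometric family as :func:`positional_encoding`, with the unit
    interval mapped to one full period of the base frequency. ``points`` may
    be (Q, 2) or (Q, B, 2); the output replaces the last axis with C.
    """
    half = channels // 2
    freq = temperature ** (2 * (np.arange(half // 2)) / half)
    scale = 2.0 * np.pi / freq  # (half/2,)

    def embed(coord: Tensor) -> Tensor:  # (..., 1) -> (..., half)
        arg = coord * scale  # broadcast to (..., half/2)
        lead = arg.shape[:-1]
        return nn.stack([arg.sin(), arg.cos()], axis=-1).reshape(*lead, half)

    ex = embed(points[..., 0:1])
    ey = embed(points[..., 1:2])
    return nn.concatenate([ex, ey], axis=-1)


def _inverse_sigmoid(x: Tensor, eps: float = 1e-6) -> Tensor:
    x = x.clamp(eps, 1.0 - eps)
    return (x / (1.0 - x)).log()


# -- backbones ----------------------------------------------------------------


def _avg_pool(x: Tensor, k: int) -> Tensor:
    b, c, h, w = x.shape
    return x.reshape(b, c, h // k, k, w // k, k).mean(axis=(3, 5))


def _space_to_depth(x: Tensor, s: int) -> Tensor:
    """(B, 1, H, W) -> (B, s*s, H/s, W/s): sub-cells become channels."""
    b, _, h, w = x.shape
    return (x.reshape(b, h // s, s, w // s, s)
             .transpose(0, 2, 4, 1, 3)
             .reshape(b, s * s, h // s, w // s))


class TinyBackbone(nn.Module):
    """Small stride-16 backbone for CPU-scale work.

    Blob detection in heavy noise is fundamentally an averaging problem, so
    the stem is an anti-aliasing 4x average pool (a matched filter for
    disk-like particles) followed by two stride-2 conv blocks. Alongside the
    learned features, a fixed local-mean pyramid (16, 8 and 4 px averages,
    finer scales folded into channels) carries local intensity — the
    dominant particle cue, including its sub-token spatial layout — to the
    feature map undistorted even at random initialization.
    """

    stride = 16
    out_channels = 64 + 1 + 4 + 16

    def __init__(self):
        super().__init__()
        self.blocks = [
            nn.Conv2d(1, 32, 3, stride=1, padding=1),
            nn.FrozenBatchNorm2d(32), nn.ReLU(),
            nn.Conv2d(32, 64, 3, stride=2, padding=1),
            nn.FrozenBatchNorm2d(64), nn.ReLU(),
            nn.Conv2d(64, 64, 3, stride=2, padding=1),
            nn.FrozenBatchNorm2d(64), nn.ReLU(),
        ]

    def forward(self, x: Tensor) -> Tensor:
        features = _avg_pool(x, 4)
        for block in self.blocks:
            features = block(features)
        mean16 = _avg_pool(x, 16)
        mean8 = _space_to_depth(_avg_pool(x, 8), 2)
        mean4 = _space_to_depth(_avg_pool(x, 4), 4)
        return nn.concatenate([features, mean16, mean8, mean4], axis=1)


class _BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, cin, planes, stride=1):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, planes, 3, stride=stride, padding=1, bias=False)
        self.bn1 = nn.FrozenBatchNorm2d(planes)
        self.conv2 = nn.Conv2d(planes, planes, 3, stride=1, padding=1, bias=False)
        self.bn2 = nn.FrozenBatchNorm2d(planes)
        self.down = None
        if stride != 1 or cin != planes:
            self.down = nn.Sequential(nn.Conv2d(cin, planes, 1, stride=stride, bias=False),
                                      nn.FrozenBatchNorm2d(planes))

    def forward(self, x):
        identity = self.down(x) if self.down is not None else x
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + identity).relu()


class _Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, cin, planes, stride=1):
        super().__init__()
        cout = planes * self.expansion
        self.conv1 = nn.Conv2d(cin, planes, 1, bias=False)
        self.bn1 = nn.FrozenBatchNorm2d(planes)
        self.conv2 = nn.Conv2d(planes, planes, 3, stride=stride, padding=1, bias=False)
        self.bn2 = nn.FrozenBatchNorm2d(planes)
        self.conv3 = nn.Conv2d(planes, cout, 1, bias=False)
        self.bn3 = nn.FrozenBatchNorm2d(cout)
        self.down = None
        if stride != 1 or cin != cout:
            self.down = nn.Sequential(nn.Conv2d(cin, cout, 1, stride=stride, bias=False),
                                      nn.FrozenBatchNorm2d(cout))

    def forward(self, x):
        identity = self.down(x) if self.down is not None else x
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        return (out + identity).relu()


_RESNET_SPECS = {
    "resnet18": (_BasicBlock, [2, 2, 2, 2]),
    "resnet34": (_BasicBlock, [3, 4, 6, 3]),
    "resnet50": (_Bottleneck, [3, 4, 6, 3]),
    "resnet101": (_Bottleneck, [3, 4, 23, 3]),
}


class ResNetBackbone(nn.Module):
    """Deep residual backbone, total stride 32, frozen-statistics norms."""

    stride = 32

    def __init__(self, name: str):
        super().__init__()
        block, counts = _RESNET_SPECS[name]
        self.stem = nn.Sequential(
            nn.Conv2d(1, 64, 7, stride=2, padding=3, bias=False),
            nn.FrozenBatchNorm2d(64), nn.ReLU(),
            nn.MaxPool2d(3, stride=2, padding=1))
        self.stages = []
        cin = 64
        for i, (planes, n_blocks) in enumerate(zip([64, 128, 256, 512], counts)):
            stride = 1 if i == 0 else 2
            blocks = []
            for j in range(n_blocks):
                blocks.append(block(cin, planes, stride=stride if j == 0 else 1))
                cin = planes * block.expansion
            self.stages.append(nn.Sequential(*blocks))
        self.out_channels = cin

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        for stage in self.stages:
            x = stage(x)
        return x


def build_backbone(name: str) -> nn.Module:
    if name == "tiny":
        return TinyBackbone()
    if name in _RESNET_SPECS:
        return ResNetBackbone(name)
    raise ValueError(f"unknown backbone {name!r}")


# -- transformer --------------------------------------------------------------


class EncoderLayer(nn.Module):
    """Post-norm transformer encoder layer; dropout sits before each norm."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.attn = nn.MultiheadAttention(cfg.hidden_dim, cfg.n_heads, cfg.dropout)
        self.linear1 = nn.Linear(cfg.hidden_dim, cfg.dim_feedforward)
        self.linear2 = nn.Linear(cfg.dim_feedforward, cfg.hidden_dim)
        self.norm1 = nn.LayerNorm(cfg.hidden_dim)
        self.norm2 = nn.LayerNorm(cfg.hidden_dim)
        self.drop1 = nn.Dropout(cfg.dropout)
        self.drop2 = nn.Dropout(cfg.dropout)
        self.drop_ffn = nn.Dropout(cfg.dropout)

    def forward(self, x: Tensor, attn_mask: np.ndarray | None = None) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x, x, x, attn_mask=attn_mask)))
        ffn = self.linear2(self.drop_ffn(self.linear1(x).relu()))
        return self.norm2(x + self.drop2(ffn))


class DecoderLayer(nn.Module):
    """Self-attention (group-masked), reference-point cross-attention, FFN.

    Self-attention uses the raw query content as query/key/value. The
    reference point conditions cross-attention twice: its sinusoidal
    encoding is added to the query, and an explicit locality bias
    ``-||p_token - p_ref||^2 / (2 sigma^2)`` (per-layer learnable sigma, in
    normalized image units) is added to the attention logits, so each query
    starts out reading the memory near its own reference point instead of
    having to discover spatial alignment from scratch.
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.self_attn = nn.MultiheadAttention(cfg.hidden_dim, cfg.n_heads, cfg.dropout)
        self.cross_attn = nn.MultiheadAttention(cfg.hidden_dim, cfg.n_heads, cfg.dropout)
        self.ref_sigma_log = nn.Parameter(np.array(np.log(cfg.ref_sigma)))
        # content gate on the attention logits: tokens that look like
        # particles draw attention within the locality window; the training
        # loop may supervise last_gate_logits directly (token objectness)
        self.key_gate = nn.Linear(cfg.hidden_dim, 1)
        self.last_gate_logits: Tensor | None = None
        self.temperature = cfg.temperature
        self.linear1 = nn.Linear(cfg.hidden_dim, cfg.dim_feedforward)
        self.linear2 = nn.Linear(cfg.dim_feedforward, cfg.hidden_dim)
        self.norm1 = nn.LayerNorm(cfg.hidden_dim)
        self.norm2 = nn.LayerNorm(cfg.hidden_dim)
        self.norm3 = nn.LayerNorm(cfg.hidden_dim)
        self.drop1 = nn.Dropout(cfg.dropout)
        self.drop2 = nn.Dropout(cfg.dropout)
        self.drop3 = nn.Dropout(cfg.dropout)
        self.drop_ffn = nn.Dropout(cfg.dropout)

    def forward(self, queries: GroupedQuerySet, memory: Tensor,
                self_attn_mask: np.ndarray | None = None,
                token_positions: np.ndarray | None = None) -> GroupedQuerySet:
        q = queries.content
        n_q = q.shape[0]
        sa = self.self_attn(q, q, q, attn_mask=self_attn_mask)
        q1 = self.norm1(q + self.drop1(sa))
        enc = queries.reference_encoding
        pref = enc.reshape(n_q, 1, -1) if enc.ndim == 2 else enc
        bias = None
        new_ref = queries.reference_points
        new_enc = queries.reference_encoding
        if token_positions is not None:
            n_heads = self.cross_attn.num_heads
            n_tok, batch, channels = memory.shape
            ref = queries.reference_points  # (Q, 2) or (Q, B, 2)
            d2 = ((ref[..., 0:1] - token_positions[None, :, 0]) ** 2.0
                  + (ref[..., 1:2] - token_positions[None, :, 1]) ** 2.0)
            inv_two_sigma_sq = 0.5 * (self.ref_sigma_log * -2.0).exp()
            locality = d2 * -1.0 * inv_two_sigma_sq
            if locality.ndim == 2:  # (Q, HW) -> (1, Q, HW), same for every item
                locality = locality.reshape(1, n_q, n_tok)
            else:                   # (Q, B, HW) -> (B, Q, HW)
                locality = locality.transpose(1, 0, 2)
            gate_logits = self.key_gate(memory)              # (HW, B, 1)
            self.last_gate_logits = gate_logits
            gate = gate_logits.transpose(1, 2, 0)            # (B, 1, HW)
            bias = locality + gate                           # (B, Q, HW)
            if bias.shape[0] == 1 and batch > 1:
                bias = bias * np.ones((batch, 1, 1))
            # dynamic reference update: move each query's reference point to
            # the center of mass of its locality-gated attention profile (a
            # soft-argmax over token positions), then recompute its encoding
            profile = softmax_fn(bias, axis=-1)              # (B, Q, HW)
            new_ref = (profile @ token_positions).transpose(1, 0, 2)  # (Q, B, 2)
            new_enc = reference_encoding(
                new_ref, channels, self.temperature)
            bias = (bias.reshape(batch, 1, n_q, n_tok) * np.ones((1, n_heads, 1, 1))
                    ).reshape(batch * n_heads, n_q, n_tok)
        ca = self.cross_attn(q1 + pref, memory, memory, attn_mask=bias)
        q2 = self.norm2(q1 + self.drop2(ca))
        ffn = self.linear2(self.drop_ffn(self.linear1(q2).relu()))
        q3 = self.norm3(q2 + self.drop3(ffn))
        return GroupedQuerySet(content=q3, reference_points=new_ref,
                               reference_encoding=new_enc,
                               group_of=queries.group_of)


def _jittered_grid(n: int, rng: np.random.Generator) -> np.ndarray:
    """n points in (0, 1)^2: near-square grid plus jitter, clipped inside."""
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    xs = (np.arange(cols) + 0.5) / cols
    ys = (np.arange(rows) + 0.5) / rows
    grid = np.array([(x, y) for y in ys for x in xs])[:n]
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2)) / np.array([cols, rows])
    return np.clip(grid + jitter, 0.02, 0.98)


def group_attention_mask(group_of: np.ndarray) -> np.ndarray:
    """Additive (Q, Q) mask: -inf wherever two queries belong to different groups."""
    same = group_of[:, None] == group_of[None, :]
    mask = np.where(same, 0.0, -np.inf)
    return mask


class ParticleDetector(nn.Module):
    """Full detector; ``forward`` returns per-decoder-layer predictions."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        self.backbone = build_backbone(cfg.backbone)
        self.input_proj = nn.Conv2d(self.backbone.out_channels, cfg.hidden_dim, 1)
        self.encoder_layers = [EncoderLayer(cfg) for _ in range(cfg.n_encoder_layers)]
        self.decoder_layers = [DecoderLayer(cfg) for _ in range(cfg.n_decoder_layers)]
        # coarse-to-fine: each successive decoder layer starts with a
        # locality window a quarter as wide as the previous one, so late
        # layers commit to a single nearby particle instead of averaging
        # over neighbors
        for i, layer in enumerate(self.decoder_layers):
            layer.ref_sigma_log.data = np.array(np.log(cfg.ref_sigma / 4 ** i))
        self.query_embed = nn.Embedding(cfg.num_queries, cfg.hidden_dim)
        rng = nn.get_rng()
        # each group's reference points start on a jittered grid covering the
        # frame, so every region has a nearby query from the first step
        init = np.concatenate([_jittered_grid(cfg.queries_per_group, rng)
                               for _ in range(cfg.groups)], axis=0)
        self.reference_logits = nn.Parameter(np.log(init / (1.0 - init)))
        self.class_head = nn.Linear(cfg.hidden_dim, 1)
        self.box_head = nn.MLP(cfg.hidden_dim, cfg.hidden_dim, 4, 3)
        # small-object prior: particles occupy a small fraction of the frame,
        # so start box sizes near sigmoid(-2) ~ 0.12 instead of 0.5
        self.box_head.layers[-1].bias.data[2:] = -2.0
        self.group_of = np.repeat(np.arange(cfg.groups), cfg.queries_per_group)
        self._group_mask = group_attention_mask(self.group_of) if cfg.groups > 1 else None

    # individual stages, exposed for inspection and testing ------------------

    def backbone_forward(self, images: Tensor) -> Tensor:
        if min(images.shape[-2:]) < self.backbone.stride:
            raise ValueError(
                f"image smaller than backbone stride {self.backbone.stride}")
        return self.input_proj(self.backbone(images))

    def encode(self, feature_map: Tensor) -> Tensor:
        b, c, h, w = feature_map.shape
        tokens = feature_map.reshape(b, c, h * w).transpose(2, 0, 1)  # (HW, B, C)
        pe = positional_encoding(h, w, c, self.cfg.temperature)
        tokens = tokens + pe.reshape(h * w, 1, c)
        for layer in self.encoder_layers:
            tokens = layer(tokens)
        return tokens

    def initial_queries(self, batch_size: int) -> GroupedQuerySet:
        content = self.query_embed(np.arange(self.cfg.num_queries))
        content = (content.reshape(self.cfg.num_queries, 1, self.cfg.hidden_dim)
                   * np.ones((1, batch_size, 1)))
        points = self.reference_logits.sigmoid()
        encoding = reference_encoding(points, self.cfg.hidden_dim, self.cfg.temperature)
        return GroupedQuerySet(content=content, reference_points=points,
                               reference_encoding=encoding, group_of=self.group_of)

    def prediction_heads(self, queries: GroupedQuerySet) -> tuple[Tensor, Tensor]:
        """Class probabilities (Q, B) and boxes (Q, B, 4) in center form."""
        scores = self.class_head(queries.content)[:, :, 0].sigmoid()
        raw = self.box_head(queries.content)  # (Q, B, 4)
        n_q = raw.shape[0]
        inv = _inverse_sigmoid(queries.reference_points)
        anchor = inv.reshape(n_q, 1, 2) if inv.ndim == 2 else inv
        centers = (raw[:, :, 0:2] + anchor).sigmoid()
        sizes = raw[:, :, 2:4].sigmoid()
        boxes = nn.concatenate([centers, sizes], axis=-1)
        return scores, boxes

    def forward(self, images: Tensor) -> list[tuple[Tensor, Tensor]]:
        feature_map = self.backbone_forward(images)
        _, _, fh, fw = feature_map.shape
        memory = self.encode(feature_map)
        self.last_grid = (fh, fw)
        # normalized centers of the memory tokens, row-major like the flatten
        tx = (np.arange(fw) + 0.5) / fw
        ty = (np.arange(fh) + 0.5) / fh
        token_positions = np.stack(
            [np.tile(tx, fh), np.repeat(ty, fw)], axis=1)  # (HW, 2)
        queries = self.initial_queries(images.shape[0])
        outputs = []
        for layer in self.decoder_layers:
            queries = layer(queries, memory, self_attn_mask=self._group_mask,
                            token_positions=token_positions)
            outputs.append(self.prediction_heads(queries))
        return outputs


# -- checkpointing ------------------------------------------------------------


def save_checkpoint(model: ParticleDetector, path: str | Path,
                    extra: dict | None = None) -> None:
    """Save weights + config (+ JSON-serializable extras) to an .npz file."""
    meta = {"config": asdict(model.cfg), "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[ParticleDetector, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    cfg = ModelConfig(**meta["config"])
    model = ParticleDetector(cfg)
    model.load_state_dict(state)
    return model, meta["extra"]
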