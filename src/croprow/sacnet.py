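"""SAC-DeepLabV3+: a lightweight encoder--decoder crop-row segmentation net.

Encoder: a MobileNetV2 backbone whose inverted-residual bottlenecks replace
the 3x3 depthwise convolution with split-attention convolution (SAC): the
depthwise stage is duplicated into ``radix`` parallel branches whose outputs
are re-weighted by a softmax attention vector computed from a globally pooled
descriptor.  The deep branch runs at output stride 16 (stride-2 stages past
that point switch to dilation), and a shallow tap at output stride 4 feeds
the decoder.

Head: DenseASPP with dilation rates 3/6/12/18/24 — each dilated 3x3 branch
consumes the concatenation of the input and all previous branch outputs —
plus horizontal and vertical strip pooling, fused by a 1x1 convolution.  A
plain ASPP head is available as the ablation fallback.

Decoder: 1x1-projected shallow features are concatenated with the 4x
upsampled head output, refined by CBAM (channel then spatial attention),
compressed by two 3x3 convolutions and upsampled 4x to the input size.

Ablation presets mirror the four incremental configurations: A (MobileNetV2
encoder + plain ASPP), A+B (+SAC), A+B+C (+DenseASPP/strip pooling), and
A+B+C+D (+CBAM).  Module widths follow the canonical MobileNetV2 table with
a 1280-channel top convolution; the dense-branch bottleneck width defaults to
a quarter of the head input so the full configuration lands on the ~8.35 M
trainable-parameter budget this architecture is designed to.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

# (expansion t, output channels c, repeats n, stride s) — the inverted
# residual schedule; the stem (3->32, stride 2) and the 1x1 top convolution
# (320->1280) bracket these stages.
MOBILENETV2_STAGES: tuple[tuple[int, int, int, int], ...] = (
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
)


def _make_divisible(v: float, divisor: int = 8) -> int:
    out = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if out < 0.9 * v:  # never round down by more than 10%
        out += divisor
    return out


@dataclass(frozen=True)
class BackboneSpec:
    """Inverted-residual stage schedule and width multiplier."""

    stages: tuple[tuple[int, int, int, int], ...] = MOBILENETV2_STAGES
    width_mult: float = 1.0
    stem_channels: int = 32
    top_channels: int = 1280  # 1x1 expansion closing the encoder

    def __post_init__(self):
        for t, c, n, s in self.stages:
            if s not in (1, 2):
                raise ValueError("stage strides must be 1 or 2")
            if c <= 0 or n <= 0 or t <= 0:
                raise ValueError("stage parameters must be positive")

    def scaled(self, c: int) -> int:
        return _make_divisible(c * self.width_mult) if self.width_mult != 1.0 else c


@dataclass(frozen=True)
class SACSpec:
    """Split-attention convolution parameters.

    ``reduction`` sets the attention bottleneck width to ``channels //
    reduction``; the default 16 keeps the attention MLPs small enough that
    enabling SAC adds roughly one million parameters across the backbone.
    """

    radix: int = 2
    cardinality: int = 1
    reduction: int = 16

    def __post_init__(self):
        if self.radix < 1 or self.reduction < 1:
            raise ValueError("radix and reduction must be >= 1")
        if self.cardinality != 1:
            raise ValueError("only cardinality = 1 is implemented")


@dataclass(frozen=True)
class DenseASPPSpec:
    """Densely connected dilated-convolution head with strip pooling."""

    dilation_rates: tuple[int, ...] = (3, 6, 12, 18, 24)
    growth_channels: int = 64
    bottleneck_channels: int | None = None  # default: head input // 4
    strip_pooling: bool = True
    output_channels: int = 256

    def __post_init__(self):
        if list(self.dilation_rates) != sorted(set(self.dilation_rates)):
            raise ValueError("dilation rates must be strictly increasing")


@dataclass(frozen=True)
class CBAMSpec:
    """Channel + spatial attention parameters."""

    reduction: int = 16
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial attention kernel size must be odd")


@dataclass(frozen=True)
class NetConfig:
    """Full network description with ablation toggles."""

    num_classes: int = 2
    backbone: BackboneSpec = BackboneSpec()
    sac: SACSpec | None = SACSpec()
    head: DenseASPPSpec | None = DenseASPPSpec()   # None -> plain ASPP fallback
    cbam: CBAMSpec | None = CBAMSpec()
    decoder_channels: int = 256
    low_level_project: int = 48
    head_channels: int = 256

    @staticmethod
    def ablation(name: str) -> "NetConfig":
        """Presets 'A', 'A+B', 'A+B+C', 'A+B+C+D' (incremental toggles)."""
        key = name.replace(" ", "").upper()
        presets = {
            "A": dict(sac=None, head=None, cbam=None),
            "A+B": dict(head=None, cbam=None),
            "A+B+C": dict(cbam=None),
            "A+B+C+D": dict(),
        }
        if key not in presets:
            raise ValueError(f"unknown ablation preset {name!r}")
        return NetConfig(**presets[key])

    @staticmethod
    def desk_scale(width_mult: float = 0.35) -> "NetConfig":
        """A width-reduced configuration for CPU-scale experiments."""
        return NetConfig(
            backbone=BackboneSpec(width_mult=width_mult),
            head=DenseASPPSpec(growth_channels=24, bottleneck_channels=96,
                               output_channels=96),
            decoder_channels=64,
            low_level_project=24,
            head_channels=96,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @staticmethod
    def from_json(text: str) -> "NetConfig":
        raw = json.loads(text)

        def tupled(d):
            return {k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
                    if isinstance(v, list) else v for k, v in d.items()}

        backbone = BackboneSpec(**tupled(raw.pop("backbone")))
        sac = raw.pop("sac")
        head = raw.pop("head")
        cbam = raw.pop("cbam")
        return NetConfig(
            backbone=backbone,
            sac=SACSpec(**sac) if sac else None,
            head=DenseASPPSpec(**tupled(head)) if head else None,
            cbam=CBAMSpec(**cbam) if cbam else None,
            **raw,
        )


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

class SACBlock(nn.Module):
    """Split-attention convolution replacing a 3x3 depthwise stage.

    ``radix`` parallel depthwise 3x3 branches are summed into a descriptor,
    globally average-pooled, passed through a bottleneck MLP, and re-expanded
    into per-branch logits; a softmax across the radix axis yields attention
    weights that recombine the branches.  With radix = 1 the softmax is
    identically one and the block degenerates to a single depthwise path.
    """

    def __init__(self, channels: int, spec: SACSpec, stride: int = 1,
                 dilation: int = 1):
        super().__init__()
        if channels % (spec.radix * spec.cardinality) != 0:
            raise ValueError(
                f"channels ({channels}) must be divisible by radix*cardinality "
                f"({spec.radix * spec.cardinality})")
        self.radix = spec.radix
        self.channels = channels
        self.splits = [nn.DepthwiseConv2d(channels, 3, stride=stride,
                                          dilation=dilation)
                       for _ in range(spec.radix)]
        inter = max(channels // spec.reduction, 1)
        self.fc1 = nn.Conv2d(channels, inter, 1, bias=True)
        self.fc1_bn = nn.BatchNorm2d(inter)
        self.fc2 = nn.Conv2d(inter, spec.radix * channels, 1, bias=True)
        self.out_bn = nn.BatchNorm2d(channels)

    def attention_weights(self, x) -> Tensor:
        """Per-split softmax weights (B, radix, C, 1, 1); sums to 1 over radix."""
        branches = [split(x) for split in self.splits]
        return self._weights(branches)

    def _weights(self, branches) -> Tensor:
        total = branches[0]
        for b in branches[1:]:
            total = nn.add(total, b)
        pooled = nn.tmean(total, axis=(2, 3), keepdims=True)     # (B,C,1,1)
        z = nn.relu(self.fc1_bn(self.fc1(pooled)))
        logits = self.fc2(z)                                     # (B,radix*C,1,1)
        b = logits.shape[0]
        logits = nn.reshape(logits, (b, self.radix, self.channels, 1, 1))
        return nn.softmax(logits, axis=1)

    def forward(self, x):
        branches = [split(x) for split in self.splits]
        weights = self._weights(branches)
        b = branches[0].shape[0]
        out = None
        for r, branch in enumerate(branches):
            w_r = nn.reshape(
                nn.tsum(nn.mul(weights, _radix_selector(self.radix, r)),
                        axis=1, keepdims=False),
                (b, self.channels, 1, 1))
            term = nn.mul(branch, w_r)
            out = term if out is None else nn.add(out, term)
        return nn.relu6(self.out_bn(out))


def _radix_selector(radix: int, r: int) -> np.ndarray:
    sel = np.zeros((1, radix, 1, 1, 1), dtype=np.float32)
    sel[0, r] = 1.0
    return sel


class InvertedResidual(nn.Module):
    """MobileNetV2 bottleneck: 1x1 expand -> 3x3 depthwise (or SAC) -> 1x1
    project, with a residual connection at matching dims and stride 1."""

    def __init__(self, cin: int, cout: int, expansion: int, stride: int,
                 dilation: int = 1, sac: SACSpec | None = None):
        super().__init__()
        ce = cin * expansion
        self.use_res = stride == 1 and cin == cout
        self.expand = (nn.ConvBNAct(cin, ce, 1) if expansion != 1 else None)
        if sac is not None:
            self.middle = SACBlock(ce, sac, stride=stride, dilation=dilation)
        else:
            self.middle = nn.Sequential(
                nn.DepthwiseConv2d(ce, 3, stride=stride, dilation=dilation),
                nn.BatchNorm2d(ce), nn.ReLU6())
        self.project = nn.ConvBNAct(ce, cout, 1, act=False)

    def forward(self, x):
        y = x if self.expand is None else self.expand(x)
        y = self.project(self.middle(y))
        return nn.add(y, x) if self.use_res else y


class Backbone(nn.Module):
    """MobileNetV2 encoder with a shallow tap at output stride 4 and a deep
    1280-channel output at stride 16 (later stride-2 stages are dilated)."""

    def __init__(self, spec: BackboneSpec, sac: SACSpec | None):
        super().__init__()
        stem_c = spec.scaled(spec.stem_channels)
        self.stem = nn.ConvBNAct(3, stem_c, 3, stride=2)
        self.blocks: list[InvertedResidual] = []
        self.low_tap_index = -1
        cin = stem_c
        os, dilation = 2, 1
        for stage_idx, (t, c, n, s) in enumerate(spec.stages):
            cout = spec.scaled(c)
            for i in range(n):
                stride = s if i == 0 else 1
                d = dilation
                if stride == 2:
                    if os >= 16:
                        stride, d = 1, dilation
                        dilation *= 2
                    else:
                        os *= 2
                self.blocks.append(InvertedResidual(cin, cout, t, stride,
                                                    dilation=d, sac=sac))
                cin = cout
            if os == 4 and self.low_tap_index < 0:
                self.low_tap_index = len(self.blocks) - 1
                self.low_channels = cin
        self.top = nn.ConvBNAct(cin, spec.scaled(spec.top_channels), 1)
        self.deep_channels = spec.scaled(spec.top_channels)

    def forward(self, x) -> tuple[Tensor, Tensor]:
        y = self.stem(x)
        low = None
        for i, block in enumerate(self.blocks):
            y = block(y)
            if i == self.low_tap_index:
                low = y
        return low, self.top(y)


class StripPool(nn.Module):
    """Pool along one full spatial axis, 1x1-project, broadcast back."""

    def __init__(self, cin: int, cout: int, axis: int):
        super().__init__()
        self.axis = axis  # 2: vertical strips (pool over H); 3: horizontal
        self.proj = nn.ConvBNAct(cin, cout, 1)

    def forward(self, x):
        pooled = nn.tmean(x, axis=self.axis, keepdims=True)
        y = self.proj(pooled)
        b, c = y.shape[0], y.shape[1]
        h = x.shape[2] if self.axis == 2 else y.shape[2]
        w = x.shape[3] if self.axis == 3 else y.shape[3]
        return nn.broadcast_to(y, (b, c, h, w))


class DenseASPPSP(nn.Module):
    """Densely connected dilated branches + strip pooling, fused 1x1."""

    def __init__(self, cin: int, spec: DenseASPPSpec):
        super().__init__()
        self.spec = spec
        g = spec.growth_channels
        mid = spec.bottleneck_channels or max(cin // 4, g)
        self.branches = []
        for l, d in enumerate(spec.dilation_rates):
            c_in_l = cin + l * g
            self.branches.append(nn.Sequential(
                nn.ConvBNAct(c_in_l, mid, 1),
                nn.ConvBNAct(mid, g, 3, dilation=d)))
        n_strip = 2 if spec.strip_pooling else 0
        if spec.strip_pooling:
            self.strip_h = StripPool(cin, g, axis=3)
            self.strip_v = StripPool(cin, g, axis=2)
        self.fuse = nn.ConvBNAct(cin + (len(spec.dilation_rates) + n_strip) * g,
                                 spec.output_channels, 1)

    def forward(self, x):
        feats = [x]
        for branch in self.branches:
            inp = feats[0] if len(feats) == 1 else nn.concat(feats, axis=1)
            feats.append(branch(inp))
        if self.spec.strip_pooling:
            feats.append(self.strip_h(x))
            feats.append(self.strip_v(x))
        return self.fuse(nn.concat(feats, axis=1))


class PlainASPP(nn.Module):
    """Standard atrous spatial pyramid pooling (ablation fallback)."""

    def __init__(self, cin: int, out: int = 256, rates: tuple[int, ...] = (6, 12, 18)):
        super().__init__()
        self.reduce = nn.ConvBNAct(cin, out, 1)
        self.branch1 = nn.ConvBNAct(out, out, 1)
        self.dilated = [nn.ConvBNAct(out, out, 3, dilation=r) for r in rates]
        self.pool_proj = nn.ConvBNAct(out, out, 1)
        self.project = nn.ConvBNAct((len(rates) + 2) * out, out, 1)

    def forward(self, x):
        y = self.reduce(x)
        feats = [self.branch1(y)] + [b(y) for b in self.dilated]
        pooled = self.pool_proj(nn.tmean(y, axis=(2, 3), keepdims=True))
        feats.append(nn.broadcast_to(pooled, feats[0].shape))
        return self.project(nn.concat(feats, axis=1))


class CBAM(nn.Module):
    """Sequential channel-then-spatial multiplicative attention."""

    def __init__(self, channels: int, spec: CBAMSpec):
        super().__init__()
        inter = max(channels // spec.reduction, 1)
        self.fc1 = nn.Conv2d(channels, inter, 1, bias=True)
        self.fc2 = nn.Conv2d(inter, channels, 1, bias=True)
        k = spec.spatial_kernel
        self.spatial = nn.Conv2d(2, 1, k, padding=k // 2, bias=True)

    def channel_attention(self, x) -> Tensor:
        avg = nn.tmean(x, axis=(2, 3), keepdims=True)
        mx = nn.reduce_max(nn.reduce_max(x, axis=3), axis=2)
        mlp = lambda v: self.fc2(nn.relu(self.fc1(v)))
        return nn.sigmoid(nn.add(mlp(avg), mlp(mx)))

    def spatial_attention(self, x) -> Tensor:
        avg = nn.tmean(x, axis=1, keepdims=True)
        mx = nn.reduce_max(x, axis=1)
        return nn.sigmoid(self.spatial(nn.concat([avg, mx], axis=1)))

    def forward(self, x):
        x = nn.mul(x, self.channel_attention(x))
        return nn.mul(x, self.spatial_attention(x))


class Decoder(nn.Module):
    def __init__(self, head_channels: int, low_channels: int, config: NetConfig):
        super().__init__()
        self.low_proj = nn.ConvBNAct(low_channels, config.low_level_project, 1)
        merged = head_channels + config.low_level_project
        self.cbam = CBAM(merged, config.cbam) if config.cbam else None
        dec = config.decoder_channels
        self.refine1 = nn.ConvBNAct(merged, dec, 3)
        self.refine2 = nn.ConvBNAct(dec, dec, 3)
        self.classifier = nn.Conv2d(dec, config.num_classes, 1, bias=True)

    def forward(self, head, low, out_hw):
        low = self.low_proj(low)
        head = nn.bilinear_resize(head, (low.shape[2], low.shape[3]))
        y = nn.concat([head, low], axis=1)
        if self.cbam is not None:
            y = self.cbam(y)
        y = self.refine2(self.refine1(y))
        return nn.bilinear_resize(self.classifier(y), out_hw)


class SACDeepLabV3Plus(nn.Module):
    """The assembled network; forward maps (B,3,H,W) to (B,num_classes,H,W)."""

    def __init__(self, config: NetConfig):
        super().__init__()
        self.config = config
        self.backbone = Backbone(config.backbone, config.sac)
        if config.head is not None:
            self.head = DenseASPPSP(self.backbone.deep_channels, config.head)
            head_out = config.head.output_channels
        else:
            self.head = PlainASPP(self.backbone.deep_channels,
                                  out=config.head_channels)
            head_out = config.head_channels
        self.decoder = Decoder(head_out, self.backbone.low_channels, config)

    def forward(self, x):
        x = nn.as_tensor(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected a (B, 3, H, W) batch, got {x.shape}")
        h, w = x.shape[2], x.shape[3]
        if h % 16 != 0 or w % 16 != 0:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by 16 "
                "(the deep branch runs at output stride 16)")
        low, deep = self.backbone(x)
        return self.decoder(self.head(deep), low, (h, w))

    def predict_mask(self, x) -> np.ndarray:
        """Argmax foreground masks (B,H,W) uint8, graph-free."""
        self.eval()
        with nn.no_grad():
            logits = self.forward(x)
        return (logits.data.argmax(axis=1)).astype(np.uint8)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def build_model(config: NetConfig = NetConfig(), seed: int = 0) -> SACDeepLabV3Plus:
    """Instantiate the network with seeded weight initialisation."""
    nn.seed(seed)
    return SACDeepLabV3Plus(config)


def forward(model: SACDeepLabV3Plus, batch) -> Tensor:
    return model(batch)


def sac_block(features, spec: SACSpec, seed: int = 0) -> Tensor:
    """Apply a freshly initialised SAC block to a feature tensor."""
    features = nn.as_tensor(features)
    nn.seed(seed)
    return SACBlock(features.shape[1], spec)(features)


def dense_aspp_sp(deep_features, spec: DenseASPPSpec, seed: int = 0) -> Tensor:
    deep_features = nn.as_tensor(deep_features)
    nn.seed(seed)
    return DenseASPPSP(deep_features.shape[1], spec)(deep_features)


def cbam(features, spec: CBAMSpec, seed: int = 0) -> Tensor:
    features = nn.as_tensor(features)
    nn.seed(seed)
    return CBAM(features.shape[1], spec)(features)


def count_parameters(model: nn.Module) -> int:
    return nn.count_parameters(model)


def save_checkpoint(model: SACDeepLabV3Plus, path: str | Path) -> None:
    """Serialise weights + config to an .npz archive with embedded JSON."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8).copy()
    buf = io.BytesIO()
    np.savez(buf, **state)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> SACDeepLabV3Plus:
    with np.load(Path(path), allow_pickle=False) as archive:
        state = {k: archive[k] for k in archive.files}
    config = NetConfig.from_json(bytes(state.pop("__config__")).decode())
    model = build_model(config)
    model.load_state_dict(state)
    return model
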