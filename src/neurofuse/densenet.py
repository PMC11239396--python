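"""3D DenseNet-121 morphological feature encoder.

Maps a grey-matter density volume to a 1024-dimensional feature vector.
The network follows the canonical DenseNet-121 recipe lifted to 3D: a
7x7x7 stride-2 stem convolution with max pooling, four dense blocks of
(6, 12, 24, 16) layers with growth rate 32, compressing transitions
(ReLU, batch normalization, 1x1x1 compression convolution, reduction
pooling), and a concluding global average pool. Inside a dense block every
layer receives the channel-wise concatenation of the block entry and all
previous layer outputs; each layer is a 1x1x1 bottleneck convolution
followed by a 3x3x3 convolution producing ``growth_rate`` channels.

The encoder is used as a fixed feature extractor: weights are either
seeded-random (He initialisation, convolutions bias-free, batch norm at
identity) or loaded from a DenseNet-121 checkpoint, optionally inflating
2D kernels along the third axis (mean-preserving). Forward passes run in
float32 and are deterministic in evaluation mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EncoderConfig",
    "MorphFeatures",
    "Encoder3D",
    "build_encoder",
    "extract_features",
    "load_pretrained",
    "conv3d",
]

# memory cap (bytes) below which conv3d materializes the full im2col stack
_IM2COL_BUDGET = 500 * 1024**2


def conv3d(x, W, stride=1, pad=0):
    """Valid/zero-padded 3D convolution of ``x`` (c_in, D, H, W) with
    kernel ``W`` (c_out, c_in, kz, ky, kx); returns (c_out, Do, Ho, Wo).

    Implemented as GEMMs over kernel-offset slices; when the stacked
    im2col tensor fits a fixed memory budget the offsets are fused into a
    single GEMM (important for the wide-kernel stem).
    """
    x = np.ascontiguousarray(x, dtype=np.float32)
    W = np.asarray(W, dtype=np.float32)
    c_out, c_in, kz, ky, kx = W.shape
    if x.shape[0] != c_in:
        raise ValueError(f"input has {x.shape[0]} channels, kernel wants {c_in}")
    if pad:
        x = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
    dims = x.shape[1:]
    out_dims = tuple((d - k) // stride + 1 for d, k in zip(dims, (kz, ky, kx)))
    if any(d < 1 for d in out_dims):
        raise ValueError(
            f"spatial input {dims} smaller than kernel ({kz},{ky},{kx})"
        )
    n_out = int(np.prod(out_dims))
    s = stride

    def _slice(dz, dy, dx):
        return x[
            :,
            dz : dz + out_dims[0] * s : s,
            dy : dy + out_dims[1] * s : s,
            dx : dx + out_dims[2] * s : s,
        ].reshape(c_in, n_out)

    offsets = [(dz, dy, dx) for dz in range(kz) for dy in range(ky) for dx in range(kx)]
    if c_in * len(offsets) * n_out * 4 <= _IM2COL_BUDGET:
        # offset-major stack matches W flattened as (kz, ky, kx, c_in)
        cols = np.concatenate([_slice(*o) for o in offsets], axis=0)
        out = W.transpose(0, 2, 3, 4, 1).reshape(c_out, -1) @ cols
    else:
        out = np.zeros((c_out, n_out), dtype=np.float32)
        for (dz, dy, dx) in offsets:
            out += W[:, :, dz, dy, dx] @ _slice(dz, dy, dx)
    return out.reshape((c_out,) + out_dims)


def maxpool3d(x, kernel=3, stride=2, pad=1):
    """Max pooling via shifted maxima; zero padding (inputs are post-ReLU)."""
    if pad:
        x = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
    dims = x.shape[1:]
    out_dims = tuple((d - kernel) // stride + 1 for d in dims)
    out = None
    for dz in range(kernel):
        for dy in range(kernel):
            for dx in range(kernel):
                sl = x[
                    :,
                    dz : dz + out_dims[0] * stride : stride,
                    dy : dy + out_dims[1] * stride : stride,
                    dx : dx + out_dims[2] * stride : stride,
                ]
                out = sl.copy() if out is None else np.maximum(out, sl)
    return out


def avgpool3d_2(x):
    """2x2x2 stride-2 average pooling with ceil mode (edge cells average
    over the elements actually present)."""
    c = x.shape[0]
    dims = x.shape[1:]
    out_dims = tuple(-(-d // 2) for d in dims)
    padded = np.zeros((c,) + tuple(2 * d for d in out_dims), dtype=x.dtype)
    padded[:, : dims[0], : dims[1], : dims[2]] = x
    summed = (
        padded.reshape(c, out_dims[0], 2, out_dims[1], 2, out_dims[2], 2)
        .sum(axis=(2, 4, 6))
    )
    counts = [np.minimum(np.arange(d) * 2 + 2, full) - np.arange(d) * 2
              for d, full in zip(out_dims, dims)]
    denom = counts[0][:, None, None] * counts[1][None, :, None] * counts[2][None, None, :]
    return summed / denom.astype(x.dtype)


def _relu(x):
    return np.maximum(x, 0.0)


class _Conv:
    def __init__(self, name, c_in, c_out, kernel, stride, pad, rng):
        self.name = name
        fan_in = c_in * kernel**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, kernel, kernel, kernel)).astype(np.float32)
        self.stride = stride
        self.pad = pad

    def __call__(self, x):
        return conv3d(x, self.W, self.stride, self.pad)


class _BatchNorm:
    """Evaluation-mode batch normalization; identity at initialisation."""

    def __init__(self, name, channels):
        self.name = name
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.mean = np.zeros(channels, dtype=np.float32)
        self.var = np.ones(channels, dtype=np.float32)
        self.eps = 1e-5

    def __call__(self, x):
        scale = self.gamma / np.sqrt(self.var + self.eps)
        shift = self.beta - self.mean * scale
        return x * scale[:, None, None, None] + shift[:, None, None, None]


@dataclass
class EncoderConfig:
    growth_rate: int = 32
    block_layers: tuple = (6, 12, 24, 16)
    compression: float = 0.5
    stem_channels: int = 64
    bottleneck_factor: int = 4
    normalize_input: bool = False
    seed: int = 0

    def validate(self):
        if len(self.block_layers) != 4:
            raise ValueError("block_layers must list 4 dense blocks")
        if not 0.0 < self.compression <= 1.0:
            raise ValueError("compression must lie in (0, 1]")
        return self

    @property
    def feature_width(self):
        ch = self.stem_channels
        for i, n_layers in enumerate(self.block_layers):
            ch += n_layers * self.growth_rate
            if i < len(self.block_layers) - 1:
                ch = int(ch * self.compression)
        return ch


@dataclass
class MorphFeatures:
    """Subject-by-feature morphological matrix, rows aligned with the
    cohort manifest order."""

    matrix: np.ndarray
    subject_ids: list = field(default_factory=list)

    @property
    def width(self):
        return self.matrix.shape[1]


class _DenseLayer:
    """Bottleneck layer: BN-ReLU-conv1 (4k channels) then BN-ReLU-conv3 (k)."""

    def __init__(self, name, c_in, growth, factor, rng):
        inter = factor * growth
        self.bn1 = _BatchNorm(f"{name}.norm1", c_in)
        self.conv1 = _Conv(f"{name}.conv1", c_in, inter, 1, 1, 0, rng)
        self.bn2 = _BatchNorm(f"{name}.norm2", inter)
        self.conv2 = _Conv(f"{name}.conv2", inter, growth, 3, 1, 1, rng)

    def __call__(self, x):
        h = self.conv1(_relu(self.bn1(x)))
        return self.conv2(_relu(self.bn2(h)))


class _Transition:
    """Between-block reduction: ReLU, batch norm, compression convolution,
    2x average pooling."""

    def __init__(self, name, c_in, c_out, rng):
        self.bn = _BatchNorm(f"{name}.norm", c_in)
        self.conv = _Conv(f"{name}.conv", c_in, c_out, 1, 1, 0, rng)

    def __call__(self, x):
        return avgpool3d_2(self.conv(self.bn(_relu(x))))


class Encoder3D:
    def __init__(self, config: EncoderConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        g, f = config.growth_rate, config.bottleneck_factor
        self.stem_conv = _Conv("features.conv0", 1, config.stem_channels, 7, 2, 3, rng)
        self.stem_bn = _BatchNorm("features.norm0", config.stem_channels)
        self.blocks = []
        self.transitions = []
        ch = config.stem_channels
        for b, n_layers in enumerate(config.block_layers):
            layers = []
            for i in range(n_layers):
                layers.append(
                    _DenseLayer(
                        f"features.denseblock{b + 1}.denselayer{i + 1}",
                        ch + i * g, g, f, rng,
                    )
                )
            self.blocks.append(layers)
            ch += n_layers * g
            if b < len(config.block_layers) - 1:
                out_ch = int(ch * config.compression)
                self.transitions.append(
                    _Transition(f"features.transition{b + 1}", ch, out_ch, rng)
                )
                ch = out_ch
        self.final_bn = _BatchNorm("features.norm5", ch)
        self.feature_width = ch
        #: populated on forward passes with record_trace=True
        self.trace = None

    # -- forward -----------------------------------------------------------

    def forward_one(self, volume, record_trace=False):
        """Encode one volume (3D array) to a ``feature_width`` vector."""
        volume = np.asarray(volume, dtype=np.float32)
        if volume.ndim != 3:
            raise ValueError("volume must be a 3D array")
        if min(volume.shape) < 8:
            raise ValueError(
                f"volume {volume.shape} below the stem's minimum extent (8)"
            )
        if not np.isfinite(volume).all():
            raise ValueError("volume contains non-finite voxels")
        if self.config.normalize_input:
            sd = volume.std()
            volume = (volume - volume.mean()) / (sd if sd > 0 else 1.0)
        trace = {"dense_inputs": [], "dense_outputs": []} if record_trace else None
        x = self.stem_conv(volume[None])
        x = maxpool3d(_relu(self.stem_bn(x)))
        for b, layers in enumerate(self.blocks):
            feats = [x]
            for layer in layers:
                concat = np.concatenate(feats, axis=0)
                if record_trace:
                    trace["dense_inputs"].append(concat)
                new = layer(concat)
                if record_trace:
                    trace["dense_outputs"].append(new)
                feats.append(new)
            x = np.concatenate(feats, axis=0)
            if b < len(self.transitions):
                x = self.transitions[b](x)
        x = _relu(self.final_bn(x))
        if record_trace:
            self.trace = trace
        return x.mean(axis=(1, 2, 3)).astype(np.float64)

    # -- parameter access --------------------------------------------------

    def named_parameters(self):
        """Flat {name: array} view over all convolution and norm tensors."""
        out = {}

        def _add_bn(bn):
            out[f"{bn.name}.weight"] = bn.gamma
            out[f"{bn.name}.bias"] = bn.beta
            out[f"{bn.name}.running_mean"] = bn.mean
            out[f"{bn.name}.running_var"] = bn.var

        out[f"{self.stem_conv.name}.weight"] = self.stem_conv.W
        _add_bn(self.stem_bn)
        for layers in self.blocks:
            for layer in layers:
                out[f"{layer.conv1.name}.weight"] = layer.conv1.W
                out[f"{layer.conv2.name}.weight"] = layer.conv2.W
                _add_bn(layer.bn1)
                _add_bn(layer.bn2)
        for tr in self.transitions:
            out[f"{tr.conv.name}.weight"] = tr.conv.W
            _add_bn(tr.bn)
        _add_bn(self.final_bn)
        return out


def build_encoder(config: EncoderConfig | None = None) -> Encoder3D:
    """Construct the 3D DenseNet encoder; seeded-random initialisation."""
    return Encoder3D(config or EncoderConfig())


def extract_features(network: Encoder3D, volumes, subject_ids=None) -> MorphFeatures:
    """Encode a stack of equally-shaped volumes to an (n, width) matrix."""
    volumes = np.asarray(volumes)
    if volumes.ndim != 4:
        raise ValueError("volumes must be a 4D (n, dz, dy, dx) array")
    rows = [network.forward_one(v) for v in volumes]
    matrix = np.stack(rows)
    if not np.isfinite(matrix).all():
        raise ValueError("non-finite features produced")
    return MorphFeatures(matrix=matrix, subject_ids=list(subject_ids or []))


def inflate_kernel_2d(kernel2d, depth):
    """Mean-preserving inflation of a 2D kernel (o, c, kh, kw) to 3D:
    replicate along the new depth axis and divide by the depth."""
    kernel2d = np.asarray(kernel2d, dtype=np.float32)
    if kernel2d.ndim != 4:
        raise ValueError("expected a 4D (out, in, kh, kw) kernel")
    return np.repeat(kernel2d[:, :, None], depth, axis=2) / float(depth)


def load_pretrained(network: Encoder3D, source, mode="native3d") -> Encoder3D:
    """Load checkpoint weights from an .npz file into the encoder.

    ``native3d`` expects 5D convolution kernels matching the 3D topology;
    ``inflate2d`` expects 4D kernels from a 2D DenseNet-121 and inflates
    them along the third axis (mean-preserving). Any unmatched or
    shape-incompatible entries abort with an explicit diff.
    """
    if mode not in ("native3d", "inflate2d"):
        raise ValueError(f"unknown weight-loading mode {mode!r}")
    source = dict(np.load(Path(source))) if not isinstance(source, dict) else source
    params = network.named_parameters()
    missing = sorted(set(params) - set(source))
    unexpected = sorted(set(source) - set(params))
    mismatched = []
    staged = {}
    for name, target in params.items():
        if name not in source:
            continue
        value = np.asarray(source[name], dtype=np.float32)
        if mode == "inflate2d" and name.endswith("conv0.weight"):
            # stem kernel is wide (7x7 -> 7x7x7)
            value = inflate_kernel_2d(value, target.shape[2])
        elif mode == "inflate2d" and value.ndim == 4:
            value = inflate_kernel_2d(value, target.shape[2])
        if value.shape != target.shape:
            mismatched.append(f"{name}: checkpoint {value.shape} vs model {target.shape}")
            continue
        staged[name] = value
    if missing or unexpected or mismatched:
        raise ValueError(
            "checkpoint does not match encoder topology\n"
            + "\n".join(
                [f"  missing: {m}" for m in missing]
                + [f"  unexpected: {u}" for u in unexpected]
                + [f"  mismatched: {m}" for m in mismatched]
            )
        )
    for name, value in staged.items():
        params[name][...] = value
    return network
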