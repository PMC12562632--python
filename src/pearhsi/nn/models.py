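"""Spectral regression architectures: multiscale CNN, CNN-LSTM, ResNet18-1D.

The multiscale network runs three parallel branches over the input spectrum
with kernel sizes 3, 5 and 7 (channel plans 1->16->128, 1->64->128 and
1->128->128, stride 2, paddings 1/2/3, each conv followed by batch norm and
ReLU, then a 2x1 max pool).  For a 421-band spectrum every branch emits a
128 x 53 map.  The branches are fused by learnable per-channel weight vectors

    F_fusion = w1 * F_small + w2 * F_medium + w3 * F_large

(broadcast over positions), flattened to 6784 features, reduced by a fully
connected 6784->128 layer with ReLU, and read out by a linear head.  The
CNN-LSTM variant feeds the 128-dim fused feature to a single-layer LSTM
(hidden size 128) as a length-1 sequence before the head, letting gate
dynamics re-weight the fused representation.  The ResNet18-1D baseline is the
standard 18-layer residual stack transposed to one dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import GeometryError
from .layers import (
    DTYPE,
    Adam,
    BatchNorm1d,
    Conv1d,
    Flatten,
    GlobalAvgPool1d,
    Linear,
    LSTMCell,
    MaxPool1d,
    Module,
    Parameter,
    ReLU,
    Sequential,
    conv1d_output_length,
)

__all__ = [
    "BranchSpec",
    "MSCNNConfig",
    "MSCNN",
    "MSCNNLSTM",
    "ResNet18_1D",
    "branch_output_shape",
]


@dataclass(frozen=True)
class BranchSpec:
    kernel: int
    mid_channels: int
    out_channels: int
    padding: int
    stride: int = 2


@dataclass
class MSCNNConfig:
    """Geometry of the multiscale trunk; defaults give 128 x 53 per branch
    (flattened fused dimension 6784) for 421 input bands."""

    input_length: int = 421
    branches: tuple[BranchSpec, BranchSpec, BranchSpec] = (
        BranchSpec(kernel=3, mid_channels=16, out_channels=128, padding=1),
        BranchSpec(kernel=5, mid_channels=64, out_channels=128, padding=2),
        BranchSpec(kernel=7, mid_channels=128, out_channels=128, padding=3),
    )
    pool_kernel: int = 2
    pool_stride: int = 2
    hidden: int = 128
    fusion_init: float = 1.0 / 3.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "input_length": self.input_length,
            "branches": [vars(b) for b in self.branches],
            "pool_kernel": self.pool_kernel,
            "pool_stride": self.pool_stride,
            "hidden": self.hidden,
            "fusion_init": self.fusion_init,
            "seed": self.seed,
        }


def branch_output_shape(cfg: MSCNNConfig, spec: BranchSpec) -> tuple[int, int]:
    """(channels, positions) a branch emits for cfg.input_length."""
    L = conv1d_output_length(cfg.input_length, spec.kernel, spec.stride, spec.padding)
    L = conv1d_output_length(L, spec.kernel, spec.stride, spec.padding)
    L = conv1d_output_length(L, cfg.pool_kernel, cfg.pool_stride, 0)
    return spec.out_channels, L


def _branch(spec: BranchSpec, pool_kernel: int, pool_stride: int,
            rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv1d(1, spec.mid_channels, spec.kernel, spec.stride, spec.padding, rng=rng),
        BatchNorm1d(spec.mid_channels),
        ReLU(),
        Conv1d(spec.mid_channels, spec.out_channels, spec.kernel, spec.stride,
               spec.padding, rng=rng),
        BatchNorm1d(spec.out_channels),
        ReLU(),
        MaxPool1d(pool_kernel, pool_stride),
    )


class MSCNN(Module):
    """Three-branch multiscale CNN with learnable per-channel fusion."""

    def __init__(self, cfg: MSCNNConfig | None = None):
        cfg = cfg or MSCNNConfig()
        self.cfg = cfg
        shapes = [branch_output_shape(cfg, spec) for spec in cfg.branches]
        if len(set(shapes)) != 1:
            raise GeometryError(
                f"branch output shapes differ ({shapes}); elementwise fusion "
                "requires identical (channels, positions) maps"
            )
        self.map_shape = shapes[0]
        self.flat_dim = shapes[0][0] * shapes[0][1]
        rng = np.random.default_rng(cfg.seed)
        self.branches = [_branch(spec, cfg.pool_kernel, cfg.pool_stride, rng)
                         for spec in cfg.branches]
        c = self.map_shape[0]
        self.fusion_weights = [
            Parameter(np.full(c, cfg.fusion_init, dtype=DTYPE), f"fusion.w{i + 1}")
            for i in range(3)
        ]
        self.flatten = Flatten()
        self.fc = Linear(self.flat_dim, cfg.hidden, rng=rng)
        self.relu = ReLU()
        self.head = Linear(cfg.hidden, 1, rng=rng)

    # -- trunk shared with the LSTM variant ---------------------------------

    def _trunk_forward(self, x: np.ndarray) -> np.ndarray:
        """(N, L) spectra -> (N, hidden) fused feature H_fusion."""
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if x.ndim != 2 or x.shape[1] != self.cfg.input_length:
            raise GeometryError(
                f"expected (N, {self.cfg.input_length}) input, got {x.shape}"
            )
        xin = x[:, None, :]
        self._maps = [branch(xin) for branch in self.branches]
        fused = np.zeros_like(self._maps[0])
        for w, fmap in zip(self.fusion_weights, self._maps):
            fused += w.value[None, :, None] * fmap
        flat = self.flatten(fused)
        return self.relu(self.fc(flat))

    def _trunk_backward(self, dh: np.ndarray) -> None:
        dflat = self.fc.backward(self.relu.backward(dh))
        dfused = self.flatten.backward(dflat)
        for w, fmap, branch in zip(self.fusion_weights, self._maps, self.branches):
            w.grad += (dfused * fmap).sum(axis=(0, 2))
            branch.backward(w.value[None, :, None] * dfused)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self._trunk_forward(x)
        return self.head(h)[:, 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.head.backward(np.asarray(dout, dtype=DTYPE)[:, None])
        self._trunk_backward(dh)
        return dh  # input gradient unused for spectra


class MSCNNLSTM(MSCNN):
    """Multiscale trunk followed by a single-step LSTM re-weighting stage."""

    def __init__(self, cfg: MSCNNConfig | None = None, hidden: int = 128):
        super().__init__(cfg)
        rng = np.random.default_rng(self.cfg.seed + 104729)
        self.lstm = LSTMCell(self.cfg.hidden, hidden, rng=rng)
        self.head = Linear(hidden, 1, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self._trunk_forward(x)          # H_fusion, length-1 sequence
        hl = self.lstm(h)                   # H_lstm
        return self.head(hl)[:, 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dhl = self.head.backward(np.asarray(dout, dtype=DTYPE)[:, None])
        dh = self.lstm.backward(dhl)
        self._trunk_backward(dh)
        return dh


class _BasicBlock(Module):
    """Two 3x1 convs with batch norm; 1x1 projection when shape changes."""

    def __init__(self, in_channels: int, out_channels: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = Conv1d(in_channels, out_channels, 3, stride, 1, rng=rng)
        self.bn1 = BatchNorm1d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(out_channels, out_channels, 3, 1, 1, rng=rng)
        self.bn2 = BatchNorm1d(out_channels)
        self.relu2 = ReLU()
        if stride != 1 or in_channels != out_channels:
            self.proj: Sequential | None = Sequential(
                Conv1d(in_channels, out_channels, 1, stride, 0, rng=rng),
                BatchNorm1d(out_channels),
            )
        else:
            self.proj = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.bn1(self.conv1(x))
        out = self.relu1(out)
        out = self.bn2(self.conv2(out))
        skip = self.proj(x) if self.proj is not None else x
        return self.relu2(out + skip)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = self.relu2.backward(dout)
        dmain = self.conv1.backward(self.relu1.backward(
            self.bn1.backward(self.conv2.backward(self.bn2.backward(dsum)))))
        dskip = self.proj.backward(dsum) if self.proj is not None else dsum
        return dmain + dskip


class ResNet18_1D(Module):
    """18-layer residual network over single-channel spectra.

    Stem: Conv(1->64, k=7, s=2, p=3) + BN + ReLU + MaxPool(k=3, s=2, p=1).
    Four groups of two blocks with 64/128/256/512 channels; global average
    pooling to 512 features; linear head.
    """

    GROUP_CHANNELS = (64, 128, 256, 512)

    def __init__(self, input_length: int = 421, seed: int = 0):
        if input_length < 32:
            raise GeometryError("ResNet18-1D needs input length >= 32")
        rng = np.random.default_rng(seed)
        self.input_length = input_length
        self.stem = Sequential(
            Conv1d(1, 64, 7, 2, 3, rng=rng),
            BatchNorm1d(64),
            ReLU(),
            MaxPool1d(3, 2, 1),
        )
        blocks: list[Module] = []
        in_ch = 64
        for gi, ch in enumerate(self.GROUP_CHANNELS):
            for bi in range(2):
                stride = 2 if (gi > 0 and bi == 0) else 1
                blocks.append(_BasicBlock(in_ch, ch, stride, rng))
                in_ch = ch
        self.blocks = blocks
        self.gap = GlobalAvgPool1d()
        self.head = Linear(512, 1, rng=rng)
        # validate the downsampling chain for this input length
        L = conv1d_output_length(input_length, 7, 2, 3)
        L = conv1d_output_length(L, 3, 2, 1)
        for gi in range(1, 4):
            L = conv1d_output_length(L, 3, 2, 1)
        self.final_length = L

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if x.ndim != 2 or x.shape[1] != self.input_length:
            raise GeometryError(
                f"expected (N, {self.input_length}) input, got {x.shape}")
        out = self.stem(x[:, None, :])
        for block in self.blocks:
            out = block(out)
        feats = self.gap(out)
        return self.head(feats)[:, 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.head.backward(np.asarray(dout, dtype=DTYPE)[:, None])
        d = self.gap.backward(d)
        for block in reversed(self.blocks):
            d = block.backward(d)
        return self.stem.backward(d)
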