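"""Residual branches and the fused multi-domain classifier.

The time-domain branch is a 1D SE-ResNet18: first convolution of kernel 15
(stride 2, 64 filters), residual blocks with kernel-7 convolutions, a
squeeze-and-excitation unit in every block (bottleneck widths 4/8/16/32 at
stage widths 64/128/256/512) and dropout 0.2 between each block's two
convolutions. The two image branches are plain 2D ResNet18 trunks
(7x7 stem, 3x3 blocks) over single-channel inputs. Each branch ends in
global average pooling; the fused head concatenates the branch feature
vectors and maps them to class logits through one fully connected layer
(softmax applied in the loss / predict path).

``width_multiplier`` scales every stage width for desk-scale experiments;
feature widths and SE bottlenecks scale with it.
"""
from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm,
    Conv1d,
    Conv2d,
    Dropout,
    GlobalAvgPool,
    Linear,
    MaxPool1d,
    MaxPool2d,
    Module,
    ReLU,
    SEBlock,
    Sequential,
    softmax,
)

STAGE_WIDTHS = (64, 128, 256, 512)
SE_REDUCTION = 16  # bottleneck widths 4, 8, 16, 32 at the full stage widths


def _scaled(width: int, multiplier: float) -> int:
    return max(4, int(round(width * multiplier)))


class _BasicBlock(Module):
    """Two-convolution residual block, optionally with SE and dropout."""

    conv_cls: type
    pool_dims: int

    def __init__(self, in_ch, out_ch, kernel, stride, use_se, dropout_rate,
                 rng, drop_rng):
        conv = self.conv_cls
        self.conv1 = conv(in_ch, out_ch, kernel, stride=stride, rng=rng,
                          bias=False)
        self.bn1 = BatchNorm(out_ch)
        self.relu1 = ReLU()
        self.drop = (
            Dropout(dropout_rate, drop_rng) if dropout_rate > 0 else None
        )
        self.conv2 = conv(out_ch, out_ch, kernel, stride=1, rng=rng,
                          bias=False)
        self.bn2 = BatchNorm(out_ch)
        self.se = (
            SEBlock(out_ch, max(1, out_ch // SE_REDUCTION), rng=rng)
            if use_se
            else None
        )
        if stride != 1 or in_ch != out_ch:
            self.down_conv = conv(in_ch, out_ch, 1, stride=stride, padding=0,
                                  rng=rng, bias=False)
            self.down_bn = BatchNorm(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None
        self.relu_out = ReLU()

    def forward(self, x, train: bool = False):
        out = self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x, train), train)
        )
        if self.drop is not None:
            out = self.drop.forward(out, train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.se is not None:
            out = self.se.forward(out, train)
        if self.down_conv is not None:
            identity = self.down_bn.forward(
                self.down_conv.forward(x, train), train
            )
        else:
            identity = x
        return self.relu_out.forward(out + identity)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        d_res, d_id = d, d
        if self.se is not None:
            d_res = self.se.backward(d_res)
        d_res = self.conv2.backward(self.bn2.backward(d_res))
        if self.drop is not None:
            d_res = self.drop.backward(d_res)
        d_res = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(d_res))
        )
        if self.down_conv is not None:
            d_id = self.down_conv.backward(self.down_bn.backward(d_id))
        return d_res + d_id


class BasicBlock1d(_BasicBlock):
    conv_cls = Conv1d


class BasicBlock2d(_BasicBlock):
    conv_cls = Conv2d


class _Branch(Module):
    """ResNet18 trunk ending in global average pooling."""

    conv_cls: type
    pool_cls: type
    block_cls: type

    def __init__(self, in_channels, first_kernel, block_kernel, use_se=False,
                 dropout_rate=0.0, width_multiplier=1.0, rng=None,
                 drop_rng=None):
        rng = rng or np.random.default_rng(0)
        drop_rng = drop_rng or np.random.default_rng(1)
        widths = [_scaled(w, width_multiplier) for w in STAGE_WIDTHS]
        self.stem = Sequential(
            self.conv_cls(in_channels, widths[0], first_kernel, stride=2,
                          rng=rng, bias=False),
            BatchNorm(widths[0]),
            ReLU(),
            self.pool_cls(3, 2, 1),
        )
        blocks = []
        in_ch = widths[0]
        for stage, w in enumerate(widths):
            for j in range(2):
                stride = 2 if (stage > 0 and j == 0) else 1
                blocks.append(
                    self.block_cls(in_ch, w, block_kernel, stride, use_se,
                                   dropout_rate, rng, drop_rng)
                )
                in_ch = w
        self.blocks = Sequential(*blocks)
        self.gap = GlobalAvgPool()
        self.feature_width = widths[-1]

    def forward(self, x, train: bool = False):
        return self.gap.forward(
            self.blocks.forward(self.stem.forward(x, train), train)
        )

    def backward(self, dy):
        return self.stem.backward(self.blocks.backward(self.gap.backward(dy)))


class Branch1d(_Branch):
    """1D SE-ResNet18 over 12-lead beats: kernel-15 stem, kernel-7 blocks."""

    conv_cls = Conv1d
    pool_cls = MaxPool1d
    block_cls = BasicBlock1d

    def __init__(self, in_channels=12, width_multiplier=1.0, rng=None,
                 drop_rng=None, use_se=True, dropout_rate=0.2):
        super().__init__(in_channels, first_kernel=15, block_kernel=7,
                         use_se=use_se, dropout_rate=dropout_rate,
                         width_multiplier=width_multiplier, rng=rng,
                         drop_rng=drop_rng)


class Branch2d(_Branch):
    """2D ResNet18 over single-channel images: 7x7 stem, 3x3 blocks."""

    conv_cls = Conv2d
    pool_cls = MaxPool2d
    block_cls = BasicBlock2d

    def __init__(self, in_channels=1, width_multiplier=1.0, rng=None,
                 drop_rng=None):
        super().__init__(in_channels, first_kernel=7, block_kernel=3,
                         use_se=False, dropout_rate=0.0,
                         width_multiplier=width_multiplier, rng=rng,
                         drop_rng=drop_rng)


BRANCH_NAMES = ("beat", "gaf", "st")


class MffNet(Module):
    """Fused multi-domain classifier.

    ``branches`` selects any non-empty subset of ``("beat", "gaf", "st")``;
    dropped branches shrink the fusion head accordingly (used by the
    ablation study). The beat branch's feature vector passes through a
    dropout (rate 0.2) before the head, mirroring the 1D network's
    pool-dropout-fc tail.
    """

    def __init__(self, n_classes, branches=BRANCH_NAMES, width_multiplier=1.0,
                 beat_channels=12, image_channels=1, seed=0):
        branches = tuple(branches)
        if not branches or any(b not in BRANCH_NAMES for b in branches):
            raise ValueError(f"branches must be a non-empty subset of {BRANCH_NAMES}")
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(seed + 1)
        self.branch_names = branches
        self.branches = {}
        if "beat" in branches:
            self.branches["beat"] = Branch1d(
                beat_channels, width_multiplier, rng=rng,
                drop_rng=self.drop_rng,
            )
        if "gaf" in branches:
            self.branches["gaf"] = Branch2d(
                image_channels, width_multiplier, rng=rng,
                drop_rng=self.drop_rng,
            )
        if "st" in branches:
            self.branches["st"] = Branch2d(
                image_channels, width_multiplier, rng=rng,
                drop_rng=self.drop_rng,
            )
        self.head_drop = Dropout(0.2, self.drop_rng)
        total = sum(self.branches[b].feature_width for b in branches)
        self.head = Linear(total, n_classes, rng=rng)
        self.n_classes = n_classes

    def forward(self, inputs: dict, train: bool = False) -> np.ndarray:
        """Map a dict of branch inputs to class logits."""
        feats = []
        self._widths = []
        batch_sizes = {inputs[b].shape[0] for b in self.branch_names}
        if len(batch_sizes) != 1:
            raise ValueError("branch inputs must share one batch size")
        for name in self.branch_names:
            f = self.branches[name].forward(
                np.asarray(inputs[name], dtype=np.float64), train
            )
            if name == "beat":
                f = self.head_drop.forward(f, train)
            feats.append(f)
            self._widths.append(f.shape[1])
        return self.head.forward(np.concatenate(feats, axis=1))

    def backward(self, dlogits) -> None:
        dfeat = self.head.backward(dlogits)
        offset = 0
        for name, w in zip(self.branch_names, self._widths):
            d = dfeat[:, offset : offset + w]
            if name == "beat":
                d = self.head_drop.backward(d)
            self.branches[name].backward(d)
            offset += w

    def predict_proba(self, inputs: dict) -> np.ndarray:
        return softmax(self.forward(inputs, train=False))

    def predict(self, inputs: dict) -> np.ndarray:
        return np.argmax(self.forward(inputs, train=False), axis=1)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))
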