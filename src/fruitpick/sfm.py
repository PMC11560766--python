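"""Spatial-relationship feature module (SFM) and an SCNN-style baseline.

The SFM operator re-weights a C×H×W feature map with two 1-D attention masks
derived from strip pooling, so that slender, axis-aligned structures (stems,
wires) receive more attention than their tiny pixel count would earn them:

    mask_h = ReLU(channel-mean(row-mean(F)))          # length H
    mask_v = ReLU(channel-mean(col-mean(F)))          # length W
    F_h[c, h, w] = F[c, h, w] * mask_h[h]
    F_v[c, h, w] = F[c, h, w] * mask_v[w]
    F_t = Conv(Concat(F, F_h, F_v))                   # 3C -> C fusion

The module is a pure array operation with no trainable state; integrating it
after a segmentation backbone is an adapter concern for the host framework.
The analytic FLOPs counters use a fixed convention of one FLOP per scalar
add, multiply, divide or ReLU comparison (no MAC fusing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.signal import correlate2d

Axis = Literal["horizontal", "vertical"]
Direction = Literal["down", "up", "right", "left"]

# Full SCNN pass applies its four directional sweeps in this order.
SCNN_DIRECTIONS: tuple[Direction, ...] = ("down", "up", "left", "right")


def _as_feature(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.ndim != 3:
        raise ValueError("feature map must have shape (C, H, W)")
    if not np.all(np.isfinite(F)):
        raise ValueError("feature map must be finite")
    return F


@dataclass
class AttentionMask:
    """1-D directional attention weights (non-negative, post-ReLU).

    `horizontal` masks have length H (one weight per row, conceptually a
    1×H×1 tensor); `vertical` masks have length W (1×1×W).
    """

    axis: Axis
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if np.any(self.weights < 0):
            raise ValueError("attention weights must be non-negative")


@dataclass
class SfmConfig:
    """Fusion-convolution settings for :func:`sfm_forward`.

    fusion_weights maps 3C input channels to C outputs with an odd
    `fusion_kernel`; `None` selects the default averaging fusion (each output
    channel is the mean of its three concatenated counterparts).  The fusion
    conv is excluded from the FLOPs budget unless `include_fusion_in_flops`.
    """

    fusion_kernel: int = 1
    fusion_weights: Optional[np.ndarray] = None
    include_fusion_in_flops: bool = False

    def __post_init__(self) -> None:
        if self.fusion_kernel < 1 or self.fusion_kernel % 2 == 0:
            raise ValueError("fusion_kernel must be a positive odd integer")
        if self.fusion_weights is not None:
            self.fusion_weights = np.asarray(self.fusion_weights, dtype=float)
            if self.fusion_weights.ndim != 4:
                raise ValueError("fusion_weights must have shape (C, 3C, k, k)")

    @classmethod
    def identity(cls, channels: int) -> "SfmConfig":
        """1×1 fusion that passes the original F_o block through unchanged."""
        w = np.zeros((channels, 3 * channels, 1, 1))
        for c in range(channels):
            w[c, c, 0, 0] = 1.0
        return cls(fusion_kernel=1, fusion_weights=w)

    @classmethod
    def average(cls, channels: int) -> "SfmConfig":
        """1×1 fusion: output channel c = (F_o + F_h + F_v)[c] / 3."""
        w = np.zeros((channels, 3 * channels, 1, 1))
        for c in range(channels):
            w[c, c, 0, 0] = w[c, channels + c, 0, 0] = w[c, 2 * channels + c, 0, 0] = 1 / 3
        return cls(fusion_kernel=1, fusion_weights=w)


def strip_pool(F: np.ndarray, axis: Axis) -> np.ndarray:
    """Average-pool one spatial axis away.

    `horizontal` pools each row with a 1×W kernel → shape (C, H, 1);
    `vertical` pools each column with an H×1 kernel → shape (C, 1, W).
    """
    F = _as_feature(F)
    if axis == "horizontal":
        return F.mean(axis=2, keepdims=True)
    if axis == "vertical":
        return F.mean(axis=1, keepdims=True)
    raise ValueError(f"unknown axis {axis!r}")


def directional_mask(F: np.ndarray, axis: Axis) -> AttentionMask:
    """ReLU(channel-average(strip_pool(F))) — the 1-D attention mask."""
    pooled = strip_pool(F, axis)  # (C,H,1) or (C,1,W)
    weights = np.maximum(pooled.mean(axis=0).ravel(), 0.0)
    return AttentionMask(axis=axis, weights=weights)


def apply_mask(F: np.ndarray, mask: AttentionMask) -> np.ndarray:
    """Broadcast-multiply the mask along its axis; shape is preserved."""
    F = _as_feature(F)
    _, h, w = F.shape
    if mask.axis == "horizontal":
        if len(mask.weights) != h:
            raise ValueError(f"horizontal mask length {len(mask.weights)} != H={h}")
        return F * mask.weights[None, :, None]
    if len(mask.weights) != w:
        raise ValueError(f"vertical mask length {len(mask.weights)} != W={w}")
    return F * mask.weights[None, None, :]


def _conv2d_zero_pad(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """(C_in,H,W) ⊛ (C_out,C_in,k,k) cross-correlation, zero padded, stride 1."""
    c_out = weights.shape[0]
    out = np.zeros((c_out, x.shape[1], x.shape[2]))
    for o in range(c_out):
        for i in range(x.shape[0]):
            out[o] += correlate2d(x[i], weights[o, i], mode="same", fillvalue=0.0)
    return out


def sfm_forward(F: np.ndarray, cfg: Optional[SfmConfig] = None) -> np.ndarray:
    """Full SFM: mask both axes, concatenate (F, F_h, F_v), fuse to C channels."""
    F = _as_feature(F)
    c = F.shape[0]
    if cfg is None:
        cfg = SfmConfig.average(c)
    weights = cfg.fusion_weights
    if weights is None:
        weights = SfmConfig.average(c).fusion_weights
    if weights.shape[1] != 3 * c or weights.shape[2] != weights.shape[3]:
        raise ValueError(
            f"fusion weights {weights.shape} inconsistent with C={c}"
        )
    f_h = apply_mask(F, directional_mask(F, "horizontal"))
    f_v = apply_mask(F, directional_mask(F, "vertical"))
    stacked = np.concatenate([F, f_h, f_v], axis=0)
    if weights.shape[2] == 1:
        return np.tensordot(weights[:, :, 0, 0], stacked, axes=(1, 0))
    return _conv2d_zero_pad(stacked, weights)


# ---------------------------------------------------------------------------
# SCNN-style slice-by-slice message passing (the heavier baseline)


def scnn_message_pass(
    F: np.ndarray,
    kernel_width: int,
    direction: Direction,
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One directional sweep of slice convolution + addition.

    Along the sweep direction, each slice receives the convolved previous
    (already-updated) slice:  slice_i <- slice_i + conv(slice_{i-1}).  The
    per-slice convolution mixes channels with a (C_out=C, C_in=C, k) kernel
    across the slice's spatial axis, zero padded.  `weights=None` uses an
    all-ones kernel (with C=1, k=1 this reduces to a running cumulative sum).
    """
    F = _as_feature(F).copy()
    if kernel_width < 1 or kernel_width % 2 == 0:
        raise ValueError("kernel_width must be a positive odd integer")
    c = F.shape[0]
    if weights is None:
        weights = np.ones((c, c, kernel_width))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (c, c, kernel_width):
        raise ValueError(f"weights must have shape ({c},{c},{kernel_width})")

    if direction in ("down", "up"):
        work = F if direction == "down" else F[:, ::-1, :]
        n_slices = work.shape[1]
        slice_axis = 1
    else:
        work = F if direction == "right" else F[:, :, ::-1]
        n_slices = work.shape[2]
        slice_axis = 2

    half = kernel_width // 2
    for i in range(1, n_slices):
        prev = work[:, i - 1, :] if slice_axis == 1 else work[:, :, i - 1]
        padded = np.pad(prev, ((0, 0), (half, half)))
        win = np.lib.stride_tricks.sliding_window_view(padded, kernel_width, axis=1)
        msg = np.einsum("oik,iwk->ow", weights, win)
        if slice_axis == 1:
            work[:, i, :] += msg
        else:
            work[:, :, i] += msg
    if direction == "up":
        work = work[:, ::-1, :]
    elif direction == "left":
        work = work[:, :, ::-1]
    return work


def scnn_full_pass(
    F: np.ndarray, kernel_width: int, weights: Optional[np.ndarray] = None
) -> np.ndarray:
    """All four directional sweeps, in the canonical order."""
    out = F
    for d in SCNN_DIRECTIONS:
        out = scnn_message_pass(out, kernel_width, d, weights)
    return out


# ---------------------------------------------------------------------------
# Analytic FLOPs counters (1 FLOP per scalar add/mul/div/comparison)


def count_flops_sfm(
    C: int, H: int, W: int, cfg: Optional[SfmConfig] = None
) -> int:
    """Exact operation count of the two SFM directional branches.

    Per branch: strip pooling (a mean over the pooled axis: length-1 adds plus
    one divide per output), channel averaging, one ReLU comparison per mask
    entry, and the C×H×W elementwise mask product.  The fusion convolution is
    excluded unless ``cfg.include_fusion_in_flops``.
    """
    if min(C, H, W) < 1:
        raise ValueError("dimensions must be positive")
    # horizontal branch: pool over W, average C, ReLU over H, multiply
    horiz = C * H * W + H * C + H + C * H * W
    vert = C * H * W + W * C + W + C * H * W
    total = horiz + vert
    if cfg is not None and cfg.include_fusion_in_flops:
        k = cfg.fusion_kernel
        # per output scalar: 3C·k² multiplies + (3C·k² − 1) adds
        total += C * H * W * (2 * 3 * C * k * k - 1)
    return total


def count_flops_scnn(C: int, H: int, W: int, kernel_width: int = 9) -> int:
    """Exact operation count of one full four-direction SCNN pass.

    Each of the two vertical sweeps updates H−1 slices of shape C×W; each
    horizontal sweep updates W−1 slices of shape C×H.  A slice update costs,
    per output scalar, C·k multiplies and (C·k − 1) adds for the channel-mixing
    convolution plus one add for the slice accumulation: 2·C·k ops in total.
    """
    if min(C, H, W, kernel_width) < 1:
        raise ValueError("dimensions must be positive")
    per_scalar = 2 * C * kernel_width
    vertical = 2 * (H - 1) * C * W * per_scalar
    horizontal = 2 * (W - 1) * C * H * per_scalar
    return vertical + horizontal
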