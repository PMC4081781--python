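"""Differential box-counting (DBC) fractal dimension of gray-level blocks.

The gray surface z = f(x, y) over an M x M block is covered, at each scale
s, by a grid of s x s pixel columns of boxes of height s' = s * G / M
(G gray levels).  A column needs ``floor(l_max/s') - floor(l_min/s') + 1``
boxes to span its min/max gray values; the dimension D is the least-squares
slope of log N_s against log(M/s).  Rough blocks approach D = 3, flat
blocks give exactly D = 2, and D serves as the per-block weight of the
WRHOG descriptor (rough, information-dense blocks count for more).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DBCParams:
    """Scale set (each s must divide the block side, 2 <= s <= M/2) and gray range."""

    scales: tuple = (2, 4, 8)
    gray_levels: int = 256

    @classmethod
    def for_block_size(cls, b: int, gray_levels: int = 256) -> "DBCParams":
        """All power-of-two divisors of ``b`` leaving at least a 2x2 grid."""
        scales = tuple(s for s in (2, 4, 8, 16, 32) if b % s == 0 and s <= b // 2)
        return cls(scales=scales, gray_levels=gray_levels)


def dbc_box_count(block: np.ndarray, s: int, gray_levels: int = 256) -> int:
    """Number of boxes N_s covering the gray surface at scale ``s``."""
    arr = np.asarray(block, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"block must be square, got {arr.shape}")
    m = arr.shape[0]
    if s < 2 or m % s != 0:
        raise ValueError(f"scale {s} must be >= 2 and divide the side {m}")
    sp = s * gray_levels / m  # box height s'
    cells = arr.reshape(m // s, s, m // s, s)
    lmax = cells.max(axis=(1, 3))
    lmin = cells.min(axis=(1, 3))
    n = np.floor(lmax / sp) - np.floor(lmin / sp) + 1
    return int(n.sum())


def fractal_dimension(block: np.ndarray, params: DBCParams | None = None) -> float:
    """DBC dimension: OLS slope of log N_s versus log(M/s) over the scales."""
    arr = np.asarray(block, dtype=np.float64)
    if params is None:
        params = DBCParams.for_block_size(arr.shape[0])
    if len(params.scales) < 2:
        raise ValueError("need at least 2 scales for the log-log regression")
    m = arr.shape[0]
    xs = np.log([m / s for s in params.scales])
    ys = np.log([dbc_box_count(arr, s, params.gray_levels) for s in params.scales])
    slope, _ = np.polyfit(xs, ys, 1)
    return float(slope)
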