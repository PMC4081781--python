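"""Raster I/O, block partitioning and shared image conventions.

Images are plain 2-D ``float64`` numpy arrays of gray values in the nominal
range [0, 255] ("GrayImage").  Coordinates are row-major and 0-based with
pixel centers at integer coordinates; the +x axis is the increasing-column
direction and +y the increasing-row direction, so angles measured by
``atan2`` run counter-clockwise on screen from the +x axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

# ITU-R BT.601 luminance weights, the convention used for RGB -> gray.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

MIN_SIDE = 8


def as_gray_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to the canonical GrayImage form."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {arr.shape}")
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise ValueError(
            f"image sides must be >= {MIN_SIDE}, got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def read_image(path) -> np.ndarray:
    """Read a PNG/BMP/PGM raster as a float GrayImage in [0, 255].

    Multi-channel input is converted to gray by the fixed BT.601 luminance
    weights (0.299, 0.587, 0.114); an alpha channel, if present, is dropped.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise IOError(f"cannot decode raster file {path!r}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path!r}")
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr @ np.asarray(LUMA_WEIGHTS)
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"unsupported channel count {arr.shape[2]}")
    elif arr.ndim != 2:
        raise ValueError(f"unsupported raster shape {arr.shape}")
    return np.clip(arr, 0.0, 255.0)


def write_image(path, img: np.ndarray) -> None:
    """Write a GrayImage as an 8-bit grayscale raster (format from suffix)."""
    arr = np.asarray(img, dtype=np.float64)
    out = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    iio.imwrite(path, out)


@dataclass(frozen=True)
class BlockGrid:
    """Non-overlapping ``b``x``b`` tiling of the top-left b-multiple region.

    ``blocks`` is a row-major list of ``(row, col, sub-image)`` entries where
    ``(row, col)`` is the block index (not pixel coordinates).
    """

    block_size: int
    n_rows: int
    n_cols: int
    blocks: list

    def __len__(self) -> int:
        return len(self.blocks)


def partition_blocks(img: np.ndarray, b: int) -> BlockGrid:
    """Partition an image into non-overlapping ``b``x``b`` blocks.

    Trailing rows/columns that do not fill a whole block are dropped, so
    every block has full size and block histograms stay comparable.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {arr.shape}")
    h, w = arr.shape
    if b < 4:
        raise ValueError(f"block size must be >= 4, got {b}")
    if b > min(h, w):
        raise ValueError(f"block size {b} exceeds image extent {arr.shape}")
    n_rows, n_cols = h // b, w // b
    blocks = [
        (i, j, arr[i * b : (i + 1) * b, j * b : (j + 1) * b])
        for i in range(n_rows)
        for j in range(n_cols)
    ]
    return BlockGrid(block_size=b, n_rows=n_rows, n_cols=n_cols, blocks=blocks)
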