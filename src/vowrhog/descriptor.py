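"""Oriented-gradient descriptors: HOG, RIHOG, RHOG and the fractal-weighted WRHOG.

The plain HOG uses the ``[-1, 0, 1]`` gradient mask and bins the gradient
vector orientation (GVO, the full [0, 2pi) circle) weighted by gradient
magnitude.  The rotation-invariant variant (RIGO/RIHOG) replaces the fixed
image-axis gradient with gradients measured in a local frame attached to
each of K sample points on a radius-r circle around the pixel, so rotating
the image rotates the frames with it and the histogram is (exactly, for
90-degree grid rotations) unchanged.  Blockwise concatenation gives RHOG;
scaling each block's histogram by the block's differential box-counting
fractal dimension gives the final WRHOG feature.

Conventions: +x is the increasing-column direction, +y the increasing-row
direction; angles from ``atan2(Gy, Gx)`` are mapped into [0, 2pi); bins are
the half-open intervals [2*pi*i/N, 2*pi*(i+1)/N) with 2*pi wrapping to bin
0; histograms are L1-normalized (all-zero histograms stay zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fractal import DBCParams, fractal_dimension
from .imaging import partition_blocks


@dataclass(frozen=True)
class OrientationMap:
    """Per-pixel gradient magnitude and angle in [0, 2pi)."""

    mag: np.ndarray
    ang: np.ndarray


@dataclass(frozen=True)
class FeatureVector:
    """Concatenated block histograms (row-major block order)."""

    values: np.ndarray
    block_size: int
    n_bins: int
    weighted: bool

    def __len__(self) -> int:
        return self.values.size


def feature_values(x) -> np.ndarray:
    """Accept a FeatureVector or a plain array; return the flat values."""
    return np.asarray(getattr(x, "values", x), dtype=np.float64).ravel()


def gradient_map(img: np.ndarray) -> OrientationMap:
    """Gradient magnitude/angle from the [-1, 0, 1] mask (GVO convention)."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 3:
        raise ValueError(f"image must be at least 3x3, got {arr.shape}")
    mask = np.array([-1.0, 0.0, 1.0])
    gx = ndimage.correlate1d(arr, mask, axis=1, mode="reflect")
    gy = ndimage.correlate1d(arr, mask, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), 2.0 * np.pi)
    return OrientationMap(mag=mag, ang=ang)


def _accumulate(mag: np.ndarray, ang: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.floor(ang * n_bins / (2.0 * np.pi)).astype(np.intp)
    idx = np.clip(idx, 0, n_bins - 1)  # 2*pi (rounding) wraps onto bin N-1->0 edge
    idx[ang >= 2.0 * np.pi] = 0
    return np.bincount(idx.ravel(), weights=mag.ravel(), minlength=n_bins)[
        :n_bins
    ].astype(np.float64)


def _normalize(bins: np.ndarray) -> np.ndarray:
    s = bins.sum()
    return bins / s if s > 0 else bins


def hog(omap: OrientationMap, n_bins: int) -> np.ndarray:
    """Magnitude-weighted orientation histogram, L1-normalized."""
    if n_bins < 2:
        raise ValueError(f"need at least 2 orientation bins, got {n_bins}")
    return _normalize(_accumulate(omap.mag, omap.ang, n_bins))


def _bilinear(arr: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation, exact at integer coordinates.

    Upper indices are clamped; their weight is zero whenever clamping can
    occur for in-range coordinates, so grid values are reproduced exactly.
    """
    h, w = arr.shape
    r0 = np.floor(rows).astype(np.intp)
    c0 = np.floor(cols).astype(np.intp)
    r0 = np.clip(r0, 0, h - 1)
    c0 = np.clip(c0, 0, w - 1)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = rows - r0
    fc = cols - c0
    a, b, c, d = arr[r0, c0], arr[r0, c1], arr[r1, c0], arr[r1, c1]
    # incremental form: exact on constants and at integer coordinates
    return a + fr * (c - a) + fc * (b - a) + fr * fc * (a + d - b - c)


def _rigo_fields(img: np.ndarray, r: float, K: int):
    """Local-frame gradient (mag, ang) fields for every pixel and sample point.

    Returns arrays of shape (K, H, W); entries are only valid for pixels at
    least ``r + 1`` from every border (callers must restrict to those).
    """
    arr = np.asarray(img, dtype=np.float64)
    h, w = arr.shape
    m = int(np.ceil(r)) + 2  # sample offsets stay within r + 1
    pad = np.pad(arr, m, mode="edge")

    def samp(dr: float, dc: float) -> np.ndarray:
        # the offset is constant across pixels, so bilinear interpolation is
        # a fixed-weight blend of four integer-shifted views
        r0, c0 = int(np.floor(dr)), int(np.floor(dc))
        fr, fc = dr - r0, dc - c0
        a = pad[m + r0 : m + r0 + h, m + c0 : m + c0 + w]
        b = pad[m + r0 : m + r0 + h, m + c0 + 1 : m + c0 + 1 + w]
        c = pad[m + r0 + 1 : m + r0 + 1 + h, m + c0 : m + c0 + w]
        d = pad[m + r0 + 1 : m + r0 + 1 + h, m + c0 + 1 : m + c0 + 1 + w]
        # incremental form: exact on constants and at integer coordinates
        return a + fr * (c - a) + fc * (b - a) + (fr * fc) * (a + d - b - c)

    mags = np.empty((K, h, w))
    angs = np.empty((K, h, w))
    for k in range(K):
        theta = 2.0 * np.pi * k / K
        dx, dy = np.cos(theta), np.sin(theta)  # local x axis, along P -> p_k
        ex, ey = -dy, dx  # local y axis
        gx = samp(r * dy + dy, r * dx + dx) - samp(r * dy - dy, r * dx - dx)
        gy = samp(r * dy + ey, r * dx + ex) - samp(r * dy - ey, r * dx - ex)
        mags[k] = np.hypot(gx, gy)
        angs[k] = np.mod(np.arctan2(gy, gx), 2.0 * np.pi)
    return mags, angs


def rigo_at(img: np.ndarray, pixel: tuple, r: float = 2.0, K: int = 8) -> list:
    """Rotation-invariant gradient samples at one pixel.

    Returns K ``(magnitude, local_angle)`` pairs, one per sample point on
    the radius-r circle; the pixel must be at least ``r + 1`` from every
    border (closer pixels contribute nothing to RIHOG and raise here).
    """
    arr = np.asarray(img, dtype=np.float64)
    i, j = pixel
    m = int(np.ceil(r)) + 1
    if not (m <= i < arr.shape[0] - m and m <= j < arr.shape[1] - m):
        raise ValueError(f"pixel {pixel} is within {m} of the border")
    out = []
    for k in range(K):
        theta = 2.0 * np.pi * k / K
        dx, dy = np.cos(theta), np.sin(theta)
        ex, ey = -dy, dx
        cr, cc = i + r * dy, j + r * dx
        pt = lambda rr, cci: float(
            _bilinear(arr, np.array([rr]), np.array([cci]))[0]
        )
        gx = pt(cr + dy, cc + dx) - pt(cr - dy, cc - dx)
        gy = pt(cr + ey, cc + ex) - pt(cr - ey, cc - ex)
        out.append((float(np.hypot(gx, gy)), float(np.mod(np.arctan2(gy, gx), 2 * np.pi))))
    return out


def _interior_margin(r: float) -> int:
    return int(np.ceil(r)) + 1


def rihog(img: np.ndarray, n_bins: int, r: float = 2.0, K: int = 8) -> np.ndarray:
    """Rotation-invariant HOG: RIGO contributions of all interior pixels."""
    if n_bins < 2:
        raise ValueError(f"need at least 2 orientation bins, got {n_bins}")
    arr = np.asarray(img, dtype=np.float64)
    m = _interior_margin(r)
    if arr.shape[0] <= 2 * m or arr.shape[1] <= 2 * m:
        return np.zeros(n_bins)
    mags, angs = _rigo_fields(arr, r, K)
    sl = (slice(None), slice(m, -m), slice(m, -m))
    return _normalize(_accumulate(mags[sl], angs[sl], n_bins))


def _block_histograms(
    img: np.ndarray, b: int, n_bins: int, r: float, K: int
) -> np.ndarray:
    """Per-block RIHOGs, computed from shared whole-image RIGO fields.

    Block-interior sample circles never leave the block (margin r+1 >= r+1),
    so slicing the full-image fields is identical to per-block evaluation.
    """
    arr = np.asarray(img, dtype=np.float64)
    grid = partition_blocks(arr, b)
    m = _interior_margin(r)
    if b <= 2 * m:
        raise ValueError(f"block size {b} too small for RIGO radius {r}")
    mags, angs = _rigo_fields(arr, r, K)
    out = np.empty((len(grid.blocks), n_bins))
    for n, (i, j, _) in enumerate(grid.blocks):
        rs = slice(i * b + m, (i + 1) * b - m)
        cs = slice(j * b + m, (j + 1) * b - m)
        out[n] = _normalize(_accumulate(mags[:, rs, cs], angs[:, rs, cs], n_bins))
    return out


def rhog(
    img: np.ndarray, b: int = 16, n_bins: int = 12, r: float = 2.0, K: int = 8
) -> FeatureVector:
    """Blockwise RIHOG concatenation (row-major block order)."""
    hists = _block_histograms(img, b, n_bins, r, K)
    return FeatureVector(
        values=hists.ravel(), block_size=b, n_bins=n_bins, weighted=False
    )


def wrhog(
    img: np.ndarray,
    b: int = 16,
    n_bins: int = 12,
    r: float = 2.0,
    K: int = 8,
    fd_params: DBCParams | None = None,
) -> FeatureVector:
    """Fractal-weighted RHOG: block histograms scaled by each block's DBC dimension."""
    hists = _block_histograms(img, b, n_bins, r, K)
    if fd_params is None:
        fd_params = DBCParams.for_block_size(b)
    grid = partition_blocks(np.asarray(img, dtype=np.float64), b)
    weights = np.array(
        [fractal_dimension(blk, fd_params) for _, _, blk in grid.blocks]
    )
    return FeatureVector(
        values=(hists * weights[:, None]).ravel(),
        block_size=b,
        n_bins=n_bins,
        weighted=True,
    )


def hog_features(img: np.ndarray, b: int = 16, n_bins: int = 12) -> FeatureVector:
    """Plain blockwise HOG vector (the non-rotation-invariant baseline)."""
    grid = partition_blocks(np.asarray(img, dtype=np.float64), b)
    hists = [hog(gradient_map(blk), n_bins) for _, _, blk in grid.blocks]
    return FeatureVector(
        values=np.concatenate(hists), block_size=b, n_bins=n_bins, weighted=False
    )
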