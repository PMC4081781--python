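"""Synthetic palmprint-like ROI generator with labeled identities.

Each identity is a template: a smooth random orientation field driving a
quasi-periodic ridge texture, plus 2-3 dark principal lines (quadratic
Bezier curves with Gaussian cross-profiles) — the coarse, blur-surviving
structure real palms carry.  Samples of an identity add the residual
misalignment left after ROI preprocessing (small rotation and integer
shift), Gaussian defocus blur of chosen sigma and optional additive noise.
Everything is deterministic given seeds, so whole labeled gallery/probe
databases regenerate bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .blur import DegradationSpec, apply_gddm

_PAD = 8  # template canvas margin consumed by rotation/shift before cropping


@dataclass(frozen=True)
class PrincipalLine:
    """Quadratic Bezier control points (row, col), Gaussian width and depth."""

    control_points: np.ndarray  # (3, 2)
    width: float  # gray-level trough half-width, px
    depth: float  # gray levels removed at the line center


@dataclass(frozen=True)
class IdentityTemplate:
    orientation_field: np.ndarray  # per-pixel ridge angle, padded canvas
    ridge_frequency: float  # cycles / pixel
    ridge_amplitude: float  # mean ridge contrast, gray levels
    amplitude_field: np.ndarray  # smooth spatial modulation of the contrast
    base_level: float
    principal_lines: tuple
    seed: int
    size: int

    @property
    def padded(self) -> np.ndarray:
        cached = getattr(self, "_padded", None)
        if cached is None:  # render once; templates are immutable
            cached = _render_base(self)
            object.__setattr__(self, "_padded", cached)
        return cached

    def base_image(self) -> np.ndarray:
        """The clean, unrotated, unshifted sample (center crop)."""
        return _crop_center(self.padded, self.size, 0, 0)


@dataclass(frozen=True)
class SampleSpec:
    """Intra-class degradation of one captured sample."""

    rotation_deg: float = 0.0
    shift_px: tuple = (0, 0)
    blur_sigma: float = 0.0
    noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (-3.0 <= self.rotation_deg <= 3.0):
            raise ValueError("rotation_deg outside the residual-offset range [-3, 3]")
        if max(abs(int(self.shift_px[0])), abs(int(self.shift_px[1]))) > 2:
            raise ValueError("shift_px outside the residual-offset range [-2, 2]")
        if self.blur_sigma < 0 or self.noise_std < 0:
            raise ValueError("blur_sigma and noise_std must be >= 0")


def _quadratic_bezier(cp: np.ndarray, n: int = 160) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * cp[0] + 2 * (1 - t) * t * cp[1] + t**2 * cp[2]


def _line_trough(shape, line: PrincipalLine) -> np.ndarray:
    pts = _quadratic_bezier(line.control_points)
    rows, cols = np.indices(shape)
    pix = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(np.float64)
    # nearest sampled curve point per pixel (dense sampling, coarse curve)
    d2 = np.min(
        ((pix[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2), axis=1
    ).reshape(shape)
    return line.depth * np.exp(-d2 / (2.0 * line.width**2))


def _render_base(tpl: IdentityTemplate) -> np.ndarray:
    theta = tpl.orientation_field
    h, w = theta.shape
    rows, cols = np.indices((h, w)).astype(np.float64)
    # projected coordinate along the local ridge-normal direction
    proj = cols * np.cos(theta) + rows * np.sin(theta)
    img = tpl.base_level + tpl.ridge_amplitude * tpl.amplitude_field * np.cos(
        2.0 * np.pi * tpl.ridge_frequency * proj
    )
    for line in tpl.principal_lines:
        img = img - _line_trough((h, w), line)
    return np.clip(img, 0.0, 255.0)


def make_identity(seed: int, size: int = 128) -> IdentityTemplate:
    """Draw an identity template deterministically from ``seed``."""
    rng = np.random.default_rng(seed)
    n = size + 2 * _PAD
    # palm ridge flow is anatomically similar across people: a common base
    # direction with a small identity offset plus a smooth identity-specific
    # perturbation field, rather than an arbitrary per-identity direction
    theta0 = np.pi / 2 + rng.normal(0.0, 0.15)
    bump = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=n / 8.0)
    bump = bump / max(bump.std(), 1e-12)
    theta = theta0 + rng.uniform(0.1, 0.2) * bump
    # ridge contrast varies smoothly across the palm (identity-specific
    # layout of strong/faint ridge regions)
    amod = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=n / 6.0)
    amod = amod / max(amod.std(), 1e-12)
    amplitude_field = np.clip(1.0 + 0.6 * amod, 0.2, 1.8)
    n_lines = int(rng.integers(2, 4))
    lines = []
    for _ in range(n_lines):
        # spread control points across the canvas so lines cross the ROI
        cp = np.column_stack(
            [rng.uniform(0.1 * n, 0.9 * n, 3), rng.uniform(0.1 * n, 0.9 * n, 3)]
        )
        lines.append(
            PrincipalLine(
                control_points=cp,
                width=float(rng.uniform(3.0, 5.0)),
                depth=float(rng.uniform(40.0, 80.0)),
            )
        )
    return IdentityTemplate(
        orientation_field=theta,
        ridge_frequency=float(rng.uniform(0.1, 0.25)),
        ridge_amplitude=float(rng.uniform(20.0, 40.0)),
        amplitude_field=amplitude_field,
        base_level=float(rng.uniform(120.0, 140.0)),
        principal_lines=tuple(lines),
        seed=int(seed),
        size=int(size),
    )


def _crop_center(padded: np.ndarray, size: int, dr: int, dc: int) -> np.ndarray:
    h, w = padded.shape
    r0 = (h - size) // 2 - dr  # shifting content by +dr = cropping higher up
    c0 = (w - size) // 2 - dc
    return padded[r0 : r0 + size, c0 : c0 + size]


def render_sample(
    tpl: IdentityTemplate, spec: SampleSpec, size: int | None = None
) -> np.ndarray:
    """Render one degraded sample of an identity.

    Rotation is bilinear about the padded-canvas center before the crop, so
    no border artifacts enter the ROI; integer shifts are exact crops.
    """
    if size is None:
        size = tpl.size
    canvas = tpl.padded
    if spec.rotation_deg != 0.0:
        canvas = ndimage.rotate(
            canvas, spec.rotation_deg, reshape=False, order=1, mode="nearest"
        )
    img = _crop_center(canvas, size, int(spec.shift_px[0]), int(spec.shift_px[1]))
    if spec.blur_sigma > 0:
        img = apply_gddm(
            img,
            DegradationSpec(
                sigma=spec.blur_sigma, noise_std=spec.noise_std, seed=spec.seed
            ),
        )
    elif spec.noise_std > 0:
        rng = np.random.default_rng(spec.seed)
        img = np.clip(img + rng.normal(0.0, spec.noise_std, img.shape), 0.0, 255.0)
    return np.asarray(img, dtype=np.float64)


@dataclass(frozen=True)
class Database:
    """Labeled gallery and probe image sets plus the specs that made them."""

    gallery_images: list
    gallery_labels: np.ndarray
    probe_images: list
    probe_labels: np.ndarray
    master_seed: int

    @property
    def n_identities(self) -> int:
        return int(np.unique(self.gallery_labels).size)


def make_database(
    n_identities: int,
    n_gallery_per: int,
    n_probe_per: int,
    blur_range: tuple = (1.0, 7.0),
    master_seed: int = 0,
    size: int = 128,
    noise_std: float = 0.0,
) -> Database:
    """Two-session style database: mild gallery, blurred probes.

    Gallery samples carry only the residual rotation/shift misalignment;
    probe samples additionally draw ``blur_sigma ~ Uniform(blur_range)``,
    emulating defocused capture in the second session.
    """
    lo, hi = blur_range
    if not (0 <= lo <= hi):
        raise ValueError(f"invalid blur range {blur_range}")
    rng = np.random.default_rng(master_seed)
    gallery, g_labels, probe, p_labels = [], [], [], []
    for ident in range(n_identities):
        tpl = make_identity(int(rng.integers(0, 2**31 - 1)), size=size)
        for _ in range(n_gallery_per):
            spec = SampleSpec(
                rotation_deg=float(rng.uniform(-3.0, 3.0)),
                shift_px=(int(rng.integers(-2, 3)), int(rng.integers(-2, 3))),
                blur_sigma=0.0,
                noise_std=noise_std,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            gallery.append(render_sample(tpl, spec))
            g_labels.append(ident)
        for _ in range(n_probe_per):
            spec = SampleSpec(
                rotation_deg=float(rng.uniform(-3.0, 3.0)),
                shift_px=(int(rng.integers(-2, 3)), int(rng.integers(-2, 3))),
                blur_sigma=float(rng.uniform(lo, hi)),
                noise_std=noise_std,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            probe.append(render_sample(tpl, spec))
            p_labels.append(ident)
    return Database(
        gallery_images=gallery,
        gallery_labels=np.asarray(g_labels),
        probe_images=probe,
        probe_labels=np.asarray(p_labels),
        master_seed=int(master_seed),
    )
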