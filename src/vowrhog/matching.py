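"""NCC feature matching and biometric verification evaluation.

Scores are normalized correlation coefficients (Pearson correlation with
population standard deviations), so they live in [-1, 1] and a threshold
on the score gives an accept/reject rule: accept iff score >= threshold
(ties accept).  Genuine scores come from probe/gallery pairs of the same
palm, imposter scores from different palms; sweeping the threshold yields
FAR/FRR curves, their crossing the equal error rate, and the decidability
index d' summarizes the separation of the two score distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .descriptor import feature_values


@dataclass(frozen=True)
class ScoreSet:
    """Genuine and imposter NCC scores."""

    genuine: np.ndarray
    imposter: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "genuine", np.asarray(self.genuine, dtype=np.float64))
        object.__setattr__(self, "imposter", np.asarray(self.imposter, dtype=np.float64))


@dataclass(frozen=True)
class RocCurve:
    """FAR/FRR sampled on a decreasing threshold grid."""

    thresholds: np.ndarray
    far: np.ndarray
    frr: np.ndarray


@dataclass(frozen=True)
class EvalSummary:
    eer: float
    eer_threshold: float
    decidability: float
    n_genuine: int
    n_imposter: int


def ncc(a, b) -> float:
    """Normalized correlation coefficient of two equal-length vectors.

    ``sum((a - mean a)(b - mean b)) / (n * sigma_a * sigma_b)`` with
    population (divide-by-n) standard deviations; symmetric, in [-1, 1].
    A zero-variance vector is degenerate: the score is defined as 0 and a
    warning is emitted.
    """
    va = feature_values(a)
    vb = feature_values(b)
    if va.size != vb.size:
        raise ValueError(f"length mismatch: {va.size} vs {vb.size}")
    if va.size < 2:
        raise ValueError("need vectors of length >= 2")
    da = va - va.mean()
    db = vb - vb.mean()
    sa = np.sqrt(np.mean(da**2))
    sb = np.sqrt(np.mean(db**2))
    if sa == 0.0 or sb == 0.0:
        warnings.warn("zero-variance feature vector in NCC; score set to 0")
        return 0.0
    return float(np.clip(np.mean(da * db) / (sa * sb), -1.0, 1.0))


def ncc_matrix(probe_features: np.ndarray, gallery_features: np.ndarray) -> np.ndarray:
    """All-vs-all NCC between rows of two feature matrices."""
    p = np.atleast_2d(np.asarray(probe_features, dtype=np.float64))
    g = np.atleast_2d(np.asarray(gallery_features, dtype=np.float64))
    pz = p - p.mean(axis=1, keepdims=True)
    gz = g - g.mean(axis=1, keepdims=True)
    ps = np.sqrt(np.mean(pz**2, axis=1))
    gs = np.sqrt(np.mean(gz**2, axis=1))
    ps[ps == 0] = np.inf  # degenerate rows score 0 against everything
    gs[gs == 0] = np.inf
    out = (pz @ gz.T) / p.shape[1] / np.outer(ps, gs)
    return np.clip(out, -1.0, 1.0)


def match_counts(n_palms: int, n_gallery_per: int, n_probe_per: int):
    """Total/genuine/imposter match counts for an all-vs-all protocol.

    Every probe image is matched against every gallery image; a pair is
    genuine when both come from the same palm.
    """
    if min(n_palms, n_gallery_per, n_probe_per) < 1:
        raise ValueError("counts must be positive")
    total = (n_palms * n_probe_per) * (n_palms * n_gallery_per)
    genuine = n_palms * n_probe_per * n_gallery_per
    return total, genuine, total - genuine


def default_thresholds(scores: ScoreSet) -> np.ndarray:
    """Decreasing grid: all distinct observed scores plus +/-inf sentinels."""
    alls = np.concatenate([scores.genuine, scores.imposter])
    uniq = np.unique(alls)
    return np.concatenate(([np.inf], uniq[::-1], [-np.inf]))


def far_frr(scores: ScoreSet, thresholds=None) -> RocCurve:
    """FAR/FRR at each threshold: accept iff score >= t.

    FRR(t) = #(genuine < t) / NEA,  FAR(t) = #(imposter >= t) / NIA.
    """
    if scores.genuine.size == 0 or scores.imposter.size == 0:
        raise ValueError("both genuine and imposter score lists must be non-empty")
    if thresholds is None:
        thresholds = default_thresholds(scores)
    t = np.asarray(thresholds, dtype=np.float64)
    frr = (scores.genuine[None, :] < t[:, None]).mean(axis=1)
    far = (scores.imposter[None, :] >= t[:, None]).mean(axis=1)
    return RocCurve(thresholds=t, far=far, frr=frr)


def eer(curve: RocCurve):
    """Equal error rate: the FAR/FRR crossing, linearly interpolated.

    With the +/-inf sentinels FAR-FRR runs from -1 to +1 as the threshold
    decreases, so a sign change always exists.  Returns ``(eer, threshold)``.
    """
    d = curve.far - curve.frr
    idx = np.flatnonzero(d >= 0)
    if idx.size == 0:  # cannot happen with sentinel grids
        return float(curve.frr[-1]), float(curve.thresholds[-1])
    k = idx[0]
    if k == 0 or d[k] == 0:
        return float((curve.far[k] + curve.frr[k]) / 2.0), float(curve.thresholds[k])
    # interpolate between grid points k-1 (d<0) and k (d>0)
    w = -d[k - 1] / (d[k] - d[k - 1])
    e = (1 - w) * (curve.far[k - 1] + curve.frr[k - 1]) / 2 + w * (
        curve.far[k] + curve.frr[k]
    ) / 2
    t0, t1 = curve.thresholds[k - 1], curve.thresholds[k]
    if np.isfinite(t0) and np.isfinite(t1):
        thr = (1 - w) * t0 + w * t1
    else:
        thr = t1 if np.isfinite(t1) else t0
    return float(e), float(thr)


def decidability(scores: ScoreSet) -> float:
    """Decidability index d' = |mu_g - mu_i| / sqrt((var_g + var_i) / 2).

    Population variances; larger d' means better-separated genuine and
    imposter score distributions.
    """
    g, i = scores.genuine, scores.imposter
    if g.size < 2 or i.size < 2:
        raise ValueError("need at least 2 scores per class")
    vg, vi = np.var(g), np.var(i)
    if vg == 0 and vi == 0:
        raise ValueError("both score distributions are degenerate (zero variance)")
    return float(abs(g.mean() - i.mean()) / np.sqrt((vg + vi) / 2.0))


def evaluate(scores: ScoreSet, thresholds=None):
    """FAR/FRR curve plus the scalar summary (EER, d', counts)."""
    curve = far_frr(scores, thresholds)
    e, t = eer(curve)
    return (
        EvalSummary(
            eer=e,
            eer_threshold=t,
            decidability=decidability(scores),
            n_genuine=int(scores.genuine.size),
            n_imposter=int(scores.imposter.size),
        ),
        curve,
    )
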