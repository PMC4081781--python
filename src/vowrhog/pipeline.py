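"""End-to-end verification pipeline: decompose -> describe -> match -> evaluate.

The full method runs the VO decomposition, computes the fractal-weighted
rotation-invariant descriptor (WRHOG) on the structure layer, scores
probe/gallery pairs by NCC and summarizes FAR/FRR/EER/decidability.  Three
switches (``use_vo``, ``use_rigo``, ``use_weights``) select the ablation
arms: plain HOG, RHOG and WRHOG, each on the raw image or on the VO
structure layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import imaging
from .descriptor import FeatureVector, _block_histograms, gradient_map, hog
from .fractal import DBCParams, fractal_dimension
from .imaging import partition_blocks
from .matching import ScoreSet, evaluate, ncc, ncc_matrix
from .vo import VOParams, structure_layer


@dataclass(frozen=True)
class PipelineConfig:
    vo: VOParams = field(default_factory=VOParams)
    block_size: int = 16
    n_bins: int = 12
    rigo_radius: float = 2.0
    rigo_samples: int = 8
    dbc: DBCParams | None = None
    use_vo: bool = True
    use_rigo: bool = True
    use_weights: bool = True
    decision_threshold: float = 0.5

    def describe(self) -> str:
        name = "WRHOG" if self.use_weights else ("RHOG" if self.use_rigo else "HOG")
        if self.use_weights and not self.use_rigo:
            name = "W-HOG"
        return ("VO-" if self.use_vo else "") + name


def _descriptor_histograms(img: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    if cfg.use_rigo:
        return _block_histograms(
            img, cfg.block_size, cfg.n_bins, cfg.rigo_radius, cfg.rigo_samples
        )
    # the plain-HOG baseline is the whole-image orientation histogram;
    # block division belongs to the robust (RIGO) variants
    return hog(gradient_map(img), cfg.n_bins)[None, :]


def extract_features(img: np.ndarray, cfg: PipelineConfig) -> FeatureVector:
    """Feature vector of one ROI under the configured ablation arm."""
    arr = np.asarray(img, dtype=np.float64)
    if cfg.use_vo:
        arr = structure_layer(arr, cfg.vo)
    if cfg.use_weights and not cfg.use_rigo:
        raise ValueError(
            "fractal weights apply to the blockwise RIGO descriptor; "
            "the plain-HOG arm has no block structure to weight"
        )
    hists = _descriptor_histograms(arr, cfg)
    if cfg.use_weights:
        dbc = cfg.dbc or DBCParams.for_block_size(cfg.block_size)
        grid = partition_blocks(arr, cfg.block_size)
        w = np.array([fractal_dimension(blk, dbc) for _, _, blk in grid.blocks])
        hists = hists * w[:, None]
    return FeatureVector(
        values=hists.ravel(),
        block_size=cfg.block_size,
        n_bins=cfg.n_bins,
        weighted=cfg.use_weights,
    )


def extract_feature_matrix(images, cfg: PipelineConfig) -> np.ndarray:
    """Row-stacked feature vectors of a list of images."""
    return np.stack([extract_features(im, cfg).values for im in images])


def verify(probe_feature, gallery_entries, claimed_label, threshold: float):
    """Claimed-identity verification against a labeled gallery.

    ``gallery_entries`` is a sequence of ``(label, feature)`` pairs; the
    best score is the max NCC over entries of the claimed identity and the
    probe is accepted iff it reaches the threshold.
    """
    candidates = [f for lab, f in gallery_entries if lab == claimed_label]
    if not candidates:
        raise ValueError(f"no gallery entries for claimed identity {claimed_label!r}")
    best = max(ncc(probe_feature, f) for f in candidates)
    return best >= threshold, best


def score_database(db, cfg: PipelineConfig, probe_features=None, gallery_features=None):
    """All-vs-all probe x gallery NCC scores split genuine/imposter by label."""
    if gallery_features is None:
        gallery_features = extract_feature_matrix(db.gallery_images, cfg)
    if probe_features is None:
        probe_features = extract_feature_matrix(db.probe_images, cfg)
    scores = ncc_matrix(probe_features, gallery_features)
    same = db.probe_labels[:, None] == db.gallery_labels[None, :]
    return ScoreSet(genuine=scores[same], imposter=scores[~same]), scores


def run_experiment(db, cfg: PipelineConfig, thresholds=None, scores_csv=None):
    """Full verification experiment on a labeled database.

    ``db`` is a :class:`vowrhog.synth.Database` or a manifest DataFrame /
    CSV path with columns ``path, identity, role`` (role gallery|probe).
    Returns ``(EvalSummary, RocCurve)``; optionally caches the raw scores
    as a CSV of (probe, gallery, genuine, score).
    """
    db = _coerce_database(db)
    scoreset, matrix = score_database(db, cfg)
    if scores_csv is not None:
        pi, gi = np.meshgrid(
            np.arange(len(db.probe_images)),
            np.arange(len(db.gallery_images)),
            indexing="ij",
        )
        pd.DataFrame(
            {
                "probe": pi.ravel(),
                "gallery": gi.ravel(),
                "genuine": (
                    db.probe_labels[pi] == db.gallery_labels[gi]
                ).ravel(),
                "score": matrix.ravel(),
            }
        ).to_csv(scores_csv, index=False)
    return evaluate(scoreset, thresholds)


@dataclass(frozen=True)
class _LoadedDatabase:
    gallery_images: list
    gallery_labels: np.ndarray
    probe_images: list
    probe_labels: np.ndarray


def _coerce_database(db):
    if hasattr(db, "gallery_images"):
        return db
    if isinstance(db, (str, bytes)) or hasattr(db, "read"):
        df = pd.read_csv(db)
    else:
        df = pd.DataFrame(db)
    missing = {"path", "identity", "role"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = [p for p in df["path"] if not _readable(p)]
    if bad:
        raise FileNotFoundError(f"unreadable manifest entries: {bad}")
    g = df[df["role"] == "gallery"]
    p = df[df["role"] == "probe"]
    return _LoadedDatabase(
        gallery_images=[imaging.read_image(x) for x in g["path"]],
        gallery_labels=g["identity"].to_numpy(),
        probe_images=[imaging.read_image(x) for x in p["path"]],
        probe_labels=p["identity"].to_numpy(),
    )


def _readable(path) -> bool:
    import os

    return os.path.isfile(path)
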