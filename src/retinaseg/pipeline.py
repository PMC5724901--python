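"""End-to-end orchestration: enhancement chain, training-pixel sampling,
train / segment / evaluate flows and the cross-training harness.

A full run is a pure function of (images, config, seed): re-running with the
same inputs reproduces masks, tables and models bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import adaboost, enhance, eval_post, io_fov, matched_filters, selection
from .enhance import EnhanceConfig
from .features import GaborParams, GlcmParams, extract_pixel_features
from .matched_filters import (
    CosfireConfig,
    FrangiParams,
    default_asymmetric_config,
    default_symmetric_config,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ModelBundle",
    "enhance_image",
    "sample_training_pixels",
    "train_pipeline",
    "segment_image",
    "evaluate_images",
    "cross_train_eval",
    "config_hash",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline in one place.

    ``sampling_fraction`` is the per-image fraction of FOV pixels used for
    training (0.05 for a DRIVE-style train split, 0.01 for STARE/CHASE-style
    sets).  ``use_mrmr`` re-ranks features from the training table; when off
    the shipped incremental-combination ordering is used.  ``rounds`` is the
    boosting budget; the validated prefix length is what segments.
    """

    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    cosfire_symmetric: CosfireConfig = field(default_factory=default_symmetric_config)
    cosfire_asymmetric: CosfireConfig = field(default_factory=default_asymmetric_config)
    frangi: FrangiParams = field(default_factory=FrangiParams)
    window: int = 3
    glcm: GlcmParams = field(default_factory=GlcmParams)
    gabor: GaborParams = field(default_factory=GaborParams)
    n_features: int = 10
    use_mrmr: bool = False
    mrmr_bins: int = 8
    rounds: int = 200
    max_depth: int = 3
    validation_fraction: float = 0.10
    sampling_fraction: float = 0.05
    fov_luminance_threshold: float = 0.10
    postprocess_min_size: int = 30
    postprocess_elongation: float = 0.85


@dataclass
class ModelBundle:
    """Trained classifier plus everything needed to reproduce inference.

    ``selected_length`` is the holdout-optimal prefix length of the
    ensemble (first minimum of ``validation_errors``); it documents where
    the error-vs-length curve bottoms out.  Inference uses the full
    ensemble: at desk-scale holdout sizes the misclassification curve is
    flat over wide ranges, and truncating at its first minimum would
    collapse the margin resolution the ROC needs.
    """

    model: adaboost.EnsembleModel
    ranking: tuple
    config: PipelineConfig
    seed: int
    config_digest: str
    selected_length: int
    validation_errors: np.ndarray


def config_hash(cfg: PipelineConfig, seed: int) -> str:
    """Stable digest of the full configuration plus the run seed."""
    blob = json.dumps(
        dataclasses.asdict(cfg), sort_keys=True, default=lambda o: list(o)
    )
    return hashlib.sha256(f"{blob}|seed={seed}".encode()).hexdigest()[:16]


def enhance_image(
    rgb: np.ndarray, fov: np.ndarray | None = None, cfg: PipelineConfig = PipelineConfig()
) -> dict:
    """Run the full enhancement chain on one fundus image.

    Returns every intermediate stage keyed by name; ``"final"`` is the
    multi-scale vesselness map (rescaled to [0, 1] over the FOV), the image
    on which pixel features are computed.  The matched filters receive the
    complement of the background-subtracted image, in which vessels are
    dark, matching the polarity of the DoG kernel.
    """
    ec = cfg.enhance
    if fov is None:
        fov = io_fov.compute_fov_mask(rgb, cfg.fov_luminance_threshold)
    gray = io_fov.extract_green(rgb)
    stages: dict = {"green": gray, "fov": fov}

    stage_fns = {
        "median": lambda x: enhance.median_denoise(x, ec.median_size),
        "border": lambda x: io_fov.smooth_fov_border(x, fov, ec.border_iterations),
        "clahe": lambda x: enhance.clahe(x, ec.clahe_clip, ec.clahe_tiles),
        "retinex": lambda x: enhance.retinex_reflectance(x, ec.retinex, fov=fov),
        "morph": lambda x: enhance.morph_enhance(x, ec.open_radius, ec.hat_radius),
        "background": lambda x: enhance.subtract_background(x, ec.background_kernel),
        "tophat": lambda x: enhance.final_tophat(x, ec.hat_radius),
    }
    x = gray
    for name in ec.stage_order:
        x = stage_fns[name](x)
        stages[name] = x

    complement = 1.0 - x
    bcos = matched_filters.combined_bcosfire(
        complement, cfg.cosfire_symmetric, cfg.cosfire_asymmetric
    )
    stages["bcosfire"] = bcos
    peak = bcos[fov].max()
    vessels = matched_filters.frangi_vesselness(
        bcos / peak if peak > 0 else bcos, cfg.frangi
    )
    stages["frangi"] = vessels
    peak = vessels[fov].max()
    stages["final"] = vessels / peak if peak > 0 else vessels
    return stages


def sample_training_pixels(
    fovs: list, fraction: float, seed: int
) -> list:
    """Per-image uniform sample of FOV coordinates, without replacement.

    Image i uses the sub-seed ``seed + i``; each draw has
    ``floor(fraction * fov_pixel_count)`` coordinates.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    out = []
    for i, fov in enumerate(fovs):
        coords = np.argwhere(np.asarray(fov, bool))
        count = int(np.floor(fraction * len(coords)))
        if count == 0:
            raise ValueError(
                f"fraction {fraction} yields zero training pixels on image {i}"
            )
        rng = np.random.default_rng(seed + i)
        out.append(coords[rng.choice(len(coords), size=count, replace=False)])
    return out


def _feature_matrix(table: pd.DataFrame, names) -> np.ndarray:
    return table[list(names)].to_numpy(float)


def train_pipeline(images: list, cfg: PipelineConfig, seed: int) -> ModelBundle:
    """Train the classifier from a list of (rgb, truth, fov) triples.

    Enhancement runs per image; features are extracted at the sampled FOV
    pixels with labels read from the truth mask; the feature set is reduced
    to the configured top-k (mRMR-ranked when ``use_mrmr``, else the shipped
    ordering); boosting runs for ``rounds``, and a seeded 90/10
    train/validation split records the error-vs-length curve and the
    holdout-optimal ensemble length.
    """
    if not images:
        raise ValueError("training set is empty")
    fovs = [fov for _, _, fov in images]
    pixel_lists = sample_training_pixels(fovs, cfg.sampling_fraction, seed)
    tables = []
    for i, ((rgb, truth, fov), pixels) in enumerate(zip(images, pixel_lists)):
        stages = enhance_image(rgb, fov, cfg)
        tables.append(
            extract_pixel_features(
                stages["final"], fov, cfg.window, cfg.glcm, cfg.gabor,
                pixels=pixels, labels=truth, image_id=f"train_{i:02d}",
            )
        )
        logger.info("extracted %d training pixels from image %d", len(pixels), i)
    table = pd.concat(tables, ignore_index=True)

    if cfg.use_mrmr:
        ranking = selection.mrmr_rank(table, cfg.n_features, bins=cfg.mrmr_bins)
        selected = selection.select_top(table, ranking, cfg.n_features)
    else:
        ranking = None
        selected = selection.select_top(table, None, cfg.n_features)
    names = tuple(
        c for c in selected.columns if c not in ("image_id", "row", "col", "label")
    )

    X = _feature_matrix(selected, names)
    y = selected["label"].to_numpy(int)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_val = max(1, int(np.floor(cfg.validation_fraction * len(y))))
    val_idx, train_idx = order[:n_val], order[n_val:]

    model = adaboost.adaboost_train(
        X[train_idx], y[train_idx], cfg.rounds, max_depth=cfg.max_depth, seed=seed
    )
    best_t = adaboost.validate_length(model, X[val_idx], y[val_idx])
    errors = np.array(
        [
            float((np.where(m >= 0, 1, -1) != y[val_idx]).mean())
            for m in adaboost.staged_scores(model, X[val_idx])
        ]
    )
    logger.info(
        "trained %d rounds, validated length %d (holdout error %.4f)",
        model.n_rounds, best_t, errors[best_t - 1],
    )
    return ModelBundle(
        model=model,
        ranking=names,
        config=cfg,
        seed=seed,
        config_digest=config_hash(cfg, seed),
        selected_length=best_t,
        validation_errors=errors,
    )


def segment_image(
    bundle: ModelBundle, rgb: np.ndarray, fov: np.ndarray | None = None
):
    """Segment one image: returns (postprocessed mask, margin score map).

    Every FOV pixel is classified; the binary mask is sign(margin) (ties to
    vessel) restricted to the FOV and cleaned by the small-component rule.
    The margin map holds the continuous scores for ROC analysis (non-FOV
    pixels are 0).
    """
    cfg = bundle.config
    if fov is None:
        fov = io_fov.compute_fov_mask(rgb, cfg.fov_luminance_threshold)
    stages = enhance_image(rgb, fov, cfg)
    table = extract_pixel_features(
        stages["final"], fov, cfg.window, cfg.glcm, cfg.gabor, image_id="segment"
    )
    margins = adaboost.ensemble_score(
        bundle.model, _feature_matrix(table, bundle.ranking)
    )
    rows = table["row"].to_numpy(int)
    cols = table["col"].to_numpy(int)
    score_map = np.zeros(fov.shape)
    score_map[rows, cols] = margins
    mask = np.zeros(fov.shape, dtype=bool)
    mask[rows, cols] = margins >= 0
    mask = eval_post.postprocess(
        mask, cfg.postprocess_min_size, cfg.postprocess_elongation
    )
    return mask, score_map


def evaluate_images(bundle: ModelBundle, images: list):
    """Segment and score a list of (rgb, truth, fov) triples.

    Returns (pooled EvaluationReport over all FOV pixels, per-image list of
    (mask, score_map)).
    """
    preds = []
    pred_all, truth_all, fov_all, score_all = [], [], [], []
    for rgb, truth, fov in images:
        mask, scores = segment_image(bundle, rgb, fov)
        preds.append((mask, scores))
        pred_all.append(mask)
        truth_all.append(truth)
        fov_all.append(fov)
        score_all.append(scores)
    report = eval_post.evaluate(
        np.concatenate([p.ravel() for p in pred_all]),
        np.concatenate([t.ravel() for t in truth_all]),
        np.concatenate([f.ravel() for f in fov_all]),
        np.concatenate([s.ravel() for s in score_all]),
    )
    return report, preds


def cross_train_eval(datasets: dict, cfg: PipelineConfig, seed: int) -> pd.DataFrame:
    """Train on each named dataset, evaluate on every other.

    ``datasets`` maps name -> list of (rgb, truth, fov).  Returns a tidy
    DataFrame with columns train, test, sensitivity, specificity, accuracy,
    auc covering every ordered pair (including the diagonal).
    """
    if len(datasets) < 2:
        raise ValueError("cross-training needs at least two datasets")
    rows = []
    for train_name, train_images in datasets.items():
        bundle = train_pipeline(train_images, cfg, seed)
        for test_name, test_images in datasets.items():
            report, _ = evaluate_images(bundle, test_images)
            rows.append(
                {
                    "train": train_name,
                    "test": test_name,
                    "sensitivity": report.sensitivity,
                    "specificity": report.specificity,
                    "accuracy": report.accuracy,
                    "auc": report.auc,
                }
            )
    return pd.DataFrame(rows)
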