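"""End-to-end orchestration: preprocess -> features -> tune -> train -> evaluate.

For each train/test ratio the pipeline stratifies a holdout split,
min-max scales features on the training portion only (test features are
clipped into [0, 1] and the clip count logged), tunes DBN
hyperparameters with the grasshopper optimizer on the training portion
(inner stratified validation split — test rows are never touched before
the final evaluation), trains the final DBN with the tuned settings, and
emits a :class:`~orascreen.evaluation.SplitReport` plus serialized model
and CSV/JSON reports.  One master seed derives every stage seed by a
fixed offset, so a re-run with the same config is bitwise identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import evaluation
from .dbn import DBNClassifier, save_dbn
from .egoa import Bounds, GOAConfig
from .evaluation import SplitReport, confusion, metrics_from_confusion
from .features import FeatureExtractorSpec, extract_features
from .gabor import GaborParams, default_bank, preprocess
from .synthetic import SyntheticConfig, make_texture_dataset, read_image_folder
from .tuning import tune_dbn

__all__ = ["PipelineConfig", "split_dataset", "run_pipeline", "fit_minmax", "apply_minmax"]

logger = logging.getLogger("orascreen")

# fixed stage offsets applied to the master seed
SEED_OFFSETS = {"data": 0, "features": 1, "split": 100, "tune": 200, "train": 300}


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    ``split_ratios`` are training fractions; the defaults sweep the
    standard 90:10 / 80:20 / 70:30 / 60:40 holdout grid.  The feature
    extractor works at the native synthetic image resolution to avoid
    upscaling interpolation.
    """

    synthetic: bool = True
    data_path: str | None = None
    synthetic_config: SyntheticConfig | None = None
    bank: list[GaborParams] | None = None
    extractor: FeatureExtractorSpec | None = None
    split_ratios: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6)
    tune_population: int = 8
    tune_iterations: int = 10
    search_space: Bounds | None = None
    epochs_finetune: int = 30
    seed: int = 7
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for r in self.split_ratios:
            if not 0.0 < r < 1.0:
                raise ValueError(f"split ratio {r} outside (0, 1)")
        if not self.synthetic and self.data_path is None:
            raise ValueError("either synthetic=True or a data_path is required")


def split_dataset(
    labels, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified holdout split; returns (train_idx, test_idx).

    Per-class test counts are round(class size x test fraction), adjusted
    by +-1 on the classes with the largest rounding error to hit the
    global total round(n x test fraction).  Every class must appear on
    both sides.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction {train_fraction} outside (0, 1)")
    labels = np.asarray(labels)
    n = labels.size
    test_fraction = 1.0 - train_fraction
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least two samples")

    def round_half_up(x: float) -> int:
        return int(np.floor(x + 0.5))

    target_total = round_half_up(n * test_fraction)
    raw = counts * test_fraction
    test_counts = np.array([round_half_up(x) for x in raw])
    # nudge the counts with the largest residuals until the total matches
    while test_counts.sum() != target_total:
        residual = raw - test_counts
        if test_counts.sum() < target_total:
            k = int(np.argmax(residual))
            test_counts[k] += 1
        else:
            k = int(np.argmin(residual))
            test_counts[k] -= 1
    test_counts = np.clip(test_counts, 1, counts - 1)

    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls, n_test in zip(classes, test_counts):
        members = np.flatnonzero(labels == cls)
        perm = rng.permutation(members)
        test_idx.extend(perm[:n_test].tolist())
        train_idx.extend(perm[n_test:].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def fit_minmax(train_features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension (lo, hi) from training rows only."""
    X = np.asarray(train_features, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    return lo, np.where(hi - lo > 0, hi, lo + 1.0)


def apply_minmax(
    features: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> tuple[np.ndarray, int]:
    """Scale into [0, 1] and clip; returns (scaled, n_clipped_entries)."""
    scaled = (np.asarray(features, dtype=float) - lo) / (hi - lo)
    n_clipped = int(np.sum((scaled < 0) | (scaled > 1)))
    return np.clip(scaled, 0.0, 1.0), n_clipped


def _ratio_label(train_fraction: float) -> str:
    return f"{round(train_fraction * 100)}:{round((1 - train_fraction) * 100)}"


def _load_inputs(config: PipelineConfig):
    if config.synthetic:
        syn = config.synthetic_config or SyntheticConfig(
            seed=config.seed + SEED_OFFSETS["data"]
        )
        return make_texture_dataset(syn)
    return read_image_folder(config.data_path)


def compute_features(config: PipelineConfig):
    """Shared preprocessing + feature extraction (split independent)."""
    images, labels, ids = _load_inputs(config)
    bank = config.bank or default_bank()
    size = images[0].shape[:2]
    spec = config.extractor or FeatureExtractorSpec(
        kind="pooled_gabor",
        output_dim=128,
        target_size=size,
        seed=config.seed + SEED_OFFSETS["features"],
    )
    logger.info("[preprocess] filtering %d images with a %d-filter bank", len(images), len(bank))
    filtered = [preprocess(img, bank) for img in images]
    logger.info("[extract] %s features, output_dim=%d", spec.kind, spec.output_dim)
    features = np.vstack([extract_features(img, spec, bank) for img in filtered])
    return features, np.asarray(labels), ids


def run_pipeline(config: PipelineConfig) -> list[SplitReport]:
    """Run every configured split ratio; returns one report per ratio."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    features, labels, ids = compute_features(config)
    class_order = tuple(sorted(set(labels.tolist())))

    reports: list[SplitReport] = []
    for k, ratio in enumerate(config.split_ratios):
        label = _ratio_label(ratio)
        logger.info("[split %s] stratified holdout", label)
        train_idx, test_idx = split_dataset(
            labels, ratio, config.seed + SEED_OFFSETS["split"] + k
        )
        lo, hi = fit_minmax(features[train_idx])
        X_train, _ = apply_minmax(features[train_idx], lo, hi)
        X_test, n_clipped = apply_minmax(features[test_idx], lo, hi)
        if n_clipped:
            logger.info("[split %s] %d test feature entries clipped into [0,1]", label, n_clipped)
        y_train, y_test = labels[train_idx], labels[test_idx]

        logger.info("[tune %s] grasshopper search N=%d t_max=%d", label, config.tune_population, config.tune_iterations)
        tune = tune_dbn(
            X_train,
            y_train,
            search_space=config.search_space,
            goa_config=GOAConfig(
                population=config.tune_population,
                max_iterations=config.tune_iterations,
                seed=config.seed + SEED_OFFSETS["tune"] + k,
            ),
            epochs_finetune=config.epochs_finetune,
            train_seed=config.seed + SEED_OFFSETS["train"] + k,
        )
        cfg = tune.config
        logger.info(
            "[train %s] arch=%s lr=%.4g batch=%d pretrain=%d",
            label, tune.architecture, cfg.learning_rate, cfg.batch_size, cfg.epochs_pretrain,
        )
        model = DBNClassifier(
            hidden_layer_sizes=tune.architecture,
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            cd_steps=cfg.cd_steps,
            epochs_pretrain=cfg.epochs_pretrain,
            epochs_finetune=cfg.epochs_finetune,
            random_state=cfg.seed,
        ).fit(X_train, y_train)

        y_pred = model.predict(X_test)
        probs = model.predict_proba(X_test)
        positive = class_order[0]
        pos_col = int(np.flatnonzero(model.classes_ == positive)[0])
        cm = confusion(y_test.tolist(), y_pred.tolist(), class_order=class_order)
        metrics = metrics_from_confusion(cm)
        scores = probs[:, pos_col]
        report = SplitReport(
            split_label=label,
            confusion_matrix=cm,
            metrics=metrics,
            roc=evaluation.roc_points(scores, y_test.tolist(), positive),
            pr=evaluation.pr_points(scores, y_test.tolist(), positive),
            extra={
                "n_train": int(train_idx.size),
                "n_test": int(test_idx.size),
                "tuned": {
                    "architecture": list(tune.architecture),
                    "learning_rate": cfg.learning_rate,
                    "batch_size": cfg.batch_size,
                    "epochs_pretrain": cfg.epochs_pretrain,
                    "epochs_finetune": cfg.epochs_finetune,
                },
                "tune_best_fitness": tune.best_fitness,
                "n_clipped_test_entries": n_clipped,
                "scaler_lo": lo.tolist(),
                "scaler_hi": hi.tolist(),
            },
        )
        reports.append(report)
        logger.info("[evaluate %s] accuracy %.2f%%", label, metrics.accuracy)
        if out_dir:
            tag = label.replace(":", "-")
            report.to_csv(out_dir / f"report_{tag}.csv")
            with open(out_dir / f"report_{tag}.json", "w") as fh:
                json.dump(report.to_json_dict(), fh, indent=2)
            save_dbn(model, out_dir / f"model_{tag}.json")
    return reports
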