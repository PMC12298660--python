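"""End-to-end orchestration: mask -> grid -> features -> SVM -> vote -> metrics.

This module wires the stages together for whole images and datasets.  The
default operating point is the preferred parameter setting of the screening
system: 80 x 80 blocks, LBP(8, 1), LBP + RGB features, RBF SVM with C = 64
and gamma = 1, medium (75%) ROI mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .color_features import color_stats
from .decision_metrics import MetricsReport, block_metrics, image_metrics, vote_image
from .feature_assembly import (
    COMBINATIONS,
    DEFAULT_COMBINATION,
    FeatureScaler,
    expected_length,
)
from .geometry import BlockGrid, enumerate_valid_blocks, make_ellipse_mask
from .svm_classifier import BeefClass, SVMConfig, TrainedModel, train_svm
from .synthetic_data import PerturbationSpec, SyntheticDataset, perturb
from .texture_lbp import LBPConfig, lbp_histogram
from .feature_assembly import assemble_features


@dataclass(frozen=True)
class PipelineConfig:
    """Preferred parameter settings of the detection pipeline."""

    block_size: int = 80
    lbp: LBPConfig = field(default_factory=lambda: LBPConfig(8, 1))
    combination: str = DEFAULT_COMBINATION
    svm: SVMConfig = field(default_factory=SVMConfig)
    mask_scale: float = 0.75
    seed: int = 0

    def feature_length(self) -> int:
        return expected_length(self.combination, self.lbp.n_bins)

    def as_dict(self) -> dict:
        return {
            "block_size": self.block_size,
            "lbp_P": self.lbp.P,
            "lbp_R": self.lbp.R,
            "combination": self.combination,
            "svm_C": self.svm.C,
            "svm_gamma": self.svm.gamma,
            "mask_scale": self.mask_scale,
            "seed": self.seed,
        }


@lru_cache(maxsize=8)
def _grid_for(width: int, height: int, mask_scale: float, block_size: int) -> BlockGrid:
    mask = make_ellipse_mask(width, height, mask_scale)
    return enumerate_valid_blocks(mask, block_size)


def extract_image_features(image: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """(n_blocks, d) unscaled feature matrix for one image's valid blocks."""
    image = np.asarray(image, dtype=np.uint8)
    grid = _grid_for(image.shape[1], image.shape[0], config.mask_scale, config.block_size)
    spaces = COMBINATIONS[config.combination]
    rows = []
    for i in range(len(grid)):
        block = grid.extract(image, i)
        hist = lbp_histogram(block, config.lbp)
        stats = [color_stats(block, space) for space in spaces]
        rows.append(assemble_features(hist, stats, config.combination).values)
    return np.vstack(rows)


def extract_split_features(
    dataset: SyntheticDataset,
    split: str,
    config: PipelineConfig,
    perturbation: PerturbationSpec | None = None,
):
    """Features and labels for every block of every image in a split.

    Returns ``(X, block_labels, image_ids, image_labels)`` where block truth
    labels inherit each image's class label.  An optional perturbation is
    applied to every image before feature extraction (robustness sweeps).
    """
    rows = dataset.subset(split)
    if rows.empty:
        raise ValueError(f"dataset has no images in split {split!r}")
    feats, block_labels, image_ids, image_labels = [], [], [], []
    for _, row in rows.iterrows():
        image, _ = dataset.render(int(row["id"]))
        if perturbation is not None:
            image = perturb(image, perturbation, seed=int(row["seed"]) ^ 0x5EED)
        f = extract_image_features(image, config)
        feats.append(f)
        block_labels.extend([int(row["label"])] * f.shape[0])
        image_ids.extend([int(row["id"])] * f.shape[0])
        image_labels.append(int(row["label"]))
    return (
        np.vstack(feats),
        np.asarray(block_labels, dtype=int),
        np.asarray(image_ids, dtype=int),
        np.asarray(image_labels, dtype=int),
    )


def train_pipeline(dataset: SyntheticDataset, config: PipelineConfig) -> TrainedModel:
    """Fit the scaler on training blocks and train the block SVM."""
    X, y, _, _ = extract_split_features(dataset, "train", config)
    scaler = FeatureScaler().fit(X)
    return train_svm(scaler.transform(X), y, config.svm, scaler=scaler)


def evaluate_split(
    model: TrainedModel,
    dataset: SyntheticDataset,
    split: str,
    config: PipelineConfig,
    perturbation: PerturbationSpec | None = None,
) -> dict[str, MetricsReport]:
    """Block- and image-level metric reports on one split."""
    X, block_truth, image_ids, image_truth = extract_split_features(
        dataset, split, config, perturbation
    )
    predicted = model.predict(model.scaler.transform(X))
    image_pred = []
    for img_id in dict.fromkeys(image_ids.tolist()):  # preserves order
        image_pred.append(int(vote_image(predicted[image_ids == img_id]).final))
    return {
        "block": block_metrics(predicted, block_truth),
        "image": image_metrics(image_pred, image_truth),
    }


def predict_image(model: TrainedModel, image: np.ndarray, config: PipelineConfig):
    """(image label, per-block labels) for one image."""
    X = extract_image_features(image, config)
    block_labels = model.predict(model.scaler.transform(X))
    return BeefClass(int(vote_image(block_labels).final)), block_labels
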