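"""Canned experiment protocols: large-sample benchmark and robustness sweeps.

The large-sample design uses 200 synthetic images per class split
120/40/40 into train/validation/test (600 images, 21,600 grid blocks at
80 x 80).  Robustness sweeps follow the sensitivity protocol: a 60-image
subset of the test split (20 per class) re-evaluated under capture
perturbations — camera tilt at small (~3 deg) and large (~12 deg) angles
and the extreme rungs (k = +/-3) of the brightness ladder.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .pipeline import PipelineConfig, evaluate_split, train_pipeline
from .svm_classifier import BeefClass, TrainedModel
from .synthetic_data import (
    PerturbationKind,
    PerturbationSpec,
    SyntheticDataset,
    TiltDirection,
    generate_dataset,
)

SMALL_TILT_DEG = 3.0
LARGE_TILT_DEG = 12.0


def _sensitivity_subset(dataset: SyntheticDataset, per_class: int) -> SyntheticDataset:
    """First ``per_class`` test images of each class, as their own dataset."""
    test = dataset.subset("test")
    keep = []
    for cls in BeefClass:
        keep.extend(test[test["label"] == int(cls)].head(per_class)["id"].tolist())
    manifest = dataset.manifest[dataset.manifest["id"].isin(keep)]
    return replace(dataset, manifest=manifest.reset_index(drop=True))


def run_large_sample_benchmark(
    seed: int,
    n_per_class: int = 200,
    config: PipelineConfig | None = None,
    sweep_per_class: int = 20,
) -> dict:
    """Train and evaluate the default pipeline on the large-sample design.

    Returns baseline block/image metric reports plus block-level
    classification rates under the robustness sweeps, all computed from
    scratch from the given seed.
    """
    config = config or PipelineConfig(seed=seed)
    dataset = generate_dataset(n_per_class, split=(0.6, 0.2, 0.2), seed=seed)
    model = train_pipeline(dataset, config)
    baseline = evaluate_split(model, dataset, "test", config)

    sweep = _sensitivity_subset(dataset, sweep_per_class)
    conditions = {
        "none": None,
        "tilt_small": PerturbationSpec(
            kind=PerturbationKind.TILT, tilt_angle=SMALL_TILT_DEG,
            tilt_direction=TiltDirection.FORWARD,
        ),
        "tilt_large": PerturbationSpec(
            kind=PerturbationKind.TILT, tilt_angle=LARGE_TILT_DEG,
            tilt_direction=TiltDirection.FORWARD,
        ),
        "brightness_low": PerturbationSpec(
            kind=PerturbationKind.BRIGHTNESS, brightness_level=-3
        ),
        "brightness_high": PerturbationSpec(
            kind=PerturbationKind.BRIGHTNESS, brightness_level=3
        ),
    }
    sweep_cr = {
        name: evaluate_split(model, sweep, "test", config, spec)["block"].cr
        for name, spec in conditions.items()
    }
    return {
        "config": config,
        "dataset": dataset,
        "model": model,
        "block": baseline["block"],
        "image": baseline["image"],
        "sweep_block_cr": sweep_cr,
    }


def total_block_count(dataset: SyntheticDataset, config: PipelineConfig,
                      render: bool = True) -> int:
    """Total number of valid grid blocks across a dataset's images.

    With ``render=True`` every image is actually generated and its valid
    blocks enumerated from its own frame geometry.
    """
    from .pipeline import _grid_for

    total = 0
    for _, row in dataset.manifest.iterrows():
        if render:
            image, _ = dataset.render(int(row["id"]))
            h, w = image.shape[:2]
        else:
            h, w = 720, 960
        total += len(_grid_for(w, h, config.mask_scale, config.block_size))
    return total
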