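"""Command-line interface and run orchestration.

Workflow stages map onto subcommands of the ``marblesense`` CLI::

    marblesense simulate  --out data/        # synthetic dataset on disk
    marblesense extract   --data data/ --out features.csv
    marblesense train     --data data/ --model model.joblib [--grid-search]
    marblesense evaluate  --data data/ --model model.joblib --out report.json
    marblesense predict   --model model.joblib image.png [--overlay out.png]

A YAML config file supplies the pipeline parameters; CLI flags override
individual fields.  Every report embeds the exact configuration used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from .feature_assembly import COMBINATIONS
from .geometry import load_image_rgb, make_ellipse_mask, enumerate_valid_blocks, save_image_rgb
from .pipeline import (
    PipelineConfig,
    evaluate_split,
    extract_split_features,
    predict_image,
    train_pipeline,
)
from .svm_classifier import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    BeefClass,
    SVMConfig,
    TrainedModel,
    grid_search,
)
from .synthetic_data import SyntheticDataset, generate_dataset, DEFAULT_SPECS
from .texture_lbp import LBPConfig

log = logging.getLogger("marblesense")

#: per-class overlay colours for block label maps
OVERLAY_COLORS = {
    BeefClass.WAGYU: (60, 160, 255),
    BeefClass.REGULAR: (60, 220, 90),
    BeefClass.FAT_INJECTED: (235, 60, 60),
}


def load_config(path: str | None, **overrides) -> PipelineConfig:
    """PipelineConfig from an optional YAML file plus non-None CLI overrides."""
    raw: dict = {}
    if path:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in overrides.items():
        if value is not None:
            raw[key] = value
    lbp = raw.get("lbp", "8,1")
    if isinstance(lbp, str):
        p, r = (int(v) for v in lbp.split(","))
    else:
        p, r = int(lbp[0]), int(lbp[1])
    combination = str(raw.get("combination", "LBP_RGB")).upper()
    if combination not in COMBINATIONS:
        raise click.BadParameter(f"unknown combination {combination}")
    return PipelineConfig(
        block_size=int(raw.get("block_size", 80)),
        lbp=LBPConfig(p, r),
        combination=combination,
        svm=SVMConfig(C=float(raw.get("C", 64)), gamma=float(raw.get("gamma", 1.0))),
        mask_scale=float(raw.get("mask_scale", 0.75)),
        seed=int(raw.get("seed", 0)),
    )


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(config.as_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _dataset_from_dir(data_dir: str, config: PipelineConfig) -> SyntheticDataset:
    manifest = pd.read_csv(Path(data_dir) / "manifest.csv")
    return SyntheticDataset(
        manifest=manifest,
        specs=dict(DEFAULT_SPECS),
        seed=config.seed,
        scale_fraction=config.mask_scale,
    )


_config_options = [
    click.option("--config", "config_path", type=click.Path(exists=True), default=None,
                 help="YAML config file."),
    click.option("--block-size", type=int, default=None),
    click.option("--lbp", default=None, help="P,R e.g. 8,1"),
    click.option("--combination", default=None),
    click.option("--C", "C", type=float, default=None),
    click.option("--gamma", type=float, default=None),
    click.option("--mask-scale", type=float, default=None),
    click.option("--seed", type=int, default=None),
]


def _with_config(fn):
    for opt in reversed(_config_options):
        fn = opt(fn)
    return fn


@click.group()
@click.option("--verbose", is_flag=True, help="DEBUG logging (per-stage detail).")
def cli(verbose: bool):
    """Screening of artificially marbled (fat-injected) beef from surface images."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        stream=sys.stderr,
    )


@cli.command()
@_with_config
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--n-per-class", type=int, default=200, show_default=True)
def simulate(config_path, out_dir, n_per_class, **overrides):
    """Generate a labeled synthetic dataset (images, fat masks, manifest)."""
    config = load_config(config_path, **overrides)
    log.info("simulate: n_per_class=%d seed=%d -> %s", n_per_class, config.seed, out_dir)
    dataset = generate_dataset(n_per_class, seed=config.seed, scale_fraction=config.mask_scale)
    dataset.save(out_dir)
    log.info("simulate: wrote %d images", len(dataset))


@cli.command()
@_with_config
@click.option("--data", "data_dir", required=True, type=click.Path(exists=True))
@click.option("--out", "out_csv", required=True, type=click.Path())
@click.option("--split", default="train", show_default=True)
def extract(config_path, data_dir, out_csv, split, **overrides):
    """Extract per-block feature vectors of one split to CSV."""
    config = load_config(config_path, **overrides)
    dataset = _dataset_from_dir(data_dir, config)
    X, y, image_ids, _ = extract_split_features(dataset, split, config)
    d = X.shape[1]
    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(d)])
    frame.insert(0, "label", y)
    frame.insert(0, "image_id", image_ids)
    frame.to_csv(out_csv, index=False)
    log.info("extract: wrote %d blocks x %d features to %s", len(frame), d, out_csv)


@cli.command()
@_with_config
@click.option("--data", "data_dir", required=True, type=click.Path(exists=True))
@click.option("--model", "model_path", required=True, type=click.Path())
@click.option("--grid-search", "do_grid", is_flag=True,
              help="Tune (C, gamma) on the validation split before the final fit.")
@click.option("--grid-csv", type=click.Path(), default=None,
              help="Where to write the validation-CR table when --grid-search is on.")
def train(config_path, data_dir, model_path, do_grid, grid_csv, **overrides):
    """Train the block-level SVM (optionally after a (C, gamma) grid search)."""
    config = load_config(config_path, **overrides)
    dataset = _dataset_from_dir(data_dir, config)
    if do_grid:
        from .feature_assembly import FeatureScaler
        from .svm_classifier import train_svm

        Xtr, ytr, _, _ = extract_split_features(dataset, "train", config)
        Xva, yva, _, _ = extract_split_features(dataset, "validation", config)
        scaler = FeatureScaler().fit(Xtr)
        result = grid_search(
            scaler.transform(Xtr), ytr, scaler.transform(Xva), yva,
            DEFAULT_C_GRID, DEFAULT_GAMMA_GRID,
        )
        log.info("grid search best: C=%g gamma=%g (validation CR %.2f%%)",
                 result.best_C, result.best_gamma, result.best_cr)
        if grid_csv:
            result.pivot().to_csv(grid_csv)
        config = PipelineConfig(
            block_size=config.block_size, lbp=config.lbp, combination=config.combination,
            svm=SVMConfig(C=result.best_C, gamma=result.best_gamma),
            mask_scale=config.mask_scale, seed=config.seed,
        )
        model = train_svm(scaler.transform(Xtr), ytr, config.svm, scaler=scaler)
    else:
        model = train_pipeline(dataset, config)
    model.save(model_path)
    log.info("train: model saved to %s (config %s)", model_path, config_hash(config))


@cli.command()
@_with_config
@click.option("--data", "data_dir", required=True, type=click.Path(exists=True))
@click.option("--model", "model_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_json", required=True, type=click.Path())
@click.option("--split", default="test", show_default=True)
def evaluate(config_path, data_dir, model_path, out_json, split, **overrides):
    """Evaluate a trained model; writes block- and image-level metrics as JSON."""
    config = load_config(config_path, **overrides)
    dataset = _dataset_from_dir(data_dir, config)
    model = TrainedModel.load(model_path)
    reports = evaluate_split(model, dataset, split, config)
    payload = {
        "config": config.as_dict(),
        "config_hash": config_hash(config),
        "split": split,
        "block": reports["block"].as_dict(),
        "image": reports["image"].as_dict(),
    }
    Path(out_json).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    log.info("evaluate: %s | %s", reports["block"], reports["image"])


@cli.command()
@_with_config
@click.option("--model", "model_path", required=True, type=click.Path(exists=True))
@click.option("--overlay", type=click.Path(), default=None,
              help="Write a per-block label map painted over the image.")
@click.argument("image_path", type=click.Path(exists=True))
def predict(config_path, model_path, overlay, image_path, **overrides):
    """Classify one image; prints the image label and per-block labels."""
    config = load_config(config_path, **overrides)
    model = TrainedModel.load(model_path)
    try:
        image = load_image_rgb(image_path)
    except Exception as exc:  # unreadable file: warn and fail this input
        log.warning("unreadable image %s: %s", image_path, exc)
        raise click.ClickException(f"cannot read {image_path}") from exc
    label, block_labels = predict_image(model, image, config)
    click.echo(json.dumps({
        "image": str(image_path),
        "label": int(label),
        "class_name": label.name,
        "block_labels": [int(v) for v in block_labels],
    }))
    if overlay:
        mask = make_ellipse_mask(image.shape[1], image.shape[0], config.mask_scale)
        grid = enumerate_valid_blocks(mask, config.block_size)
        painted = image.copy()
        for i, (x, y) in enumerate(grid.origins):
            color = np.array(OVERLAY_COLORS[BeefClass(int(block_labels[i]))])
            s = config.block_size
            painted[y : y + s, x : x + s] = (
                0.65 * painted[y : y + s, x : x + s] + 0.35 * color
            ).astype(np.uint8)
        save_image_rgb(overlay, painted)
        log.info("predict: overlay written to %s", overlay)


if __name__ == "__main__":
    cli()
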