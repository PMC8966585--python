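"""Run configuration and the end-to-end pipeline.

``RunConfig`` collects every stage's tunables in one nested, YAML-
serializable structure with strict key checking (an unknown key raises
``ConfigError`` naming it).  ``run_pipeline`` wires the stages together:
simulate phantom data, segment each slice with the automatic random walker,
extract handcrafted features from the nodule volumes, train/evaluate the
classifiers, and emit a JSON report.  Everything is seeded, so the same
config produces an identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify, features, metrics, phantom, randomwalk
from .errors import ConfigError
from .io_preprocess import write_image, write_mask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhantomConfig:
    n_slices: int = 5
    image_height: int = 128
    image_width: int = 128
    noise_sigma: float = 0.02
    n_nodules: int = 2
    n_per_class: int = 25
    volume_size: int = 9
    contrast: float = 0.7


@dataclass(frozen=True)
class SeedingConfigSection:
    median_kernel: int = 3
    min_area: int = 100
    erode_radius: int = 3
    dilate_radius: int = 3


@dataclass(frozen=True)
class WalkConfig:
    beta1: float = randomwalk.DEFAULT_BETA1
    beta2: float = randomwalk.DEFAULT_BETA2
    partial: float = randomwalk.DEFAULT_PARTIAL
    connectivity: int = 4
    g_combine: str = "min"
    compare_beta2_zero: bool = False


@dataclass(frozen=True)
class FeatureConfig:
    k: float = 1.0
    bins: int = 256


@dataclass(frozen=True)
class ClassifyConfig:
    split_ratio: float = 0.8
    hidden_units: int = 32
    max_iter: int = 1500
    learning_rate_init: float = 0.01
    backbone: str = "random-conv"   # random-conv | constant | none
    n_filters: int = 16
    run_fusion: bool = True


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    seeding: SeedingConfigSection = field(default_factory=SeedingConfigSection)
    walk: WalkConfig = field(default_factory=WalkConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)


_SECTION_TYPES = {
    "phantom": PhantomConfig,
    "seeding": SeedingConfigSection,
    "walk": WalkConfig,
    "features": FeatureConfig,
    "classify": ClassifyConfig,
}


def _build_section(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} in section {path!r}")
    return cls(**data)


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    """Build a RunConfig from a nested dict, rejecting unknown keys."""
    data = dict(data)
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            section = data.pop(name)
            if not isinstance(section, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, section, name)
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    if data:
        raise ConfigError(f"unknown config key(s) {sorted(data)} at top level")
    return RunConfig(**kwargs)


def config_to_dict(config: RunConfig) -> dict[str, Any]:
    return dataclasses.asdict(config)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_stage(config: RunConfig, outdir: Path) -> dict[str, Any]:
    """Write phantom slices, masks, volumes and a CSV manifest under ``outdir``."""
    outdir.mkdir(parents=True, exist_ok=True)
    pc = config.phantom
    rows = []
    samples = []
    for i in range(pc.n_slices):
        spec = phantom.PhantomSpec(
            image_height=pc.image_height, image_width=pc.image_width,
            noise_sigma=pc.noise_sigma, n_nodules=pc.n_nodules,
            rng_seed=config.seed + i,
        )
        sample = phantom.generate_slice(spec)
        img_path = outdir / f"slice_{i:03d}.png"
        mask_path = outdir / f"slice_{i:03d}_mask.png"
        write_image(sample.image, img_path)
        write_mask(sample.lung_mask, mask_path)
        rows.append({"path": img_path.name, "label": sample.label,
                     "seed": spec.rng_seed})
        samples.append(sample)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return {"samples": samples, "manifest": manifest,
            "hashes": {p.name: _sha256(p) for p in sorted(outdir.glob("*.png"))}}


def segment_stage(config: RunConfig, samples) -> dict[str, Any]:
    """Segment each slice; report per-slice and mean IOU/FPR."""
    wc, sc = config.walk, config.seeding
    seeding_config = randomwalk.SeedingConfig(
        median_kernel=sc.median_kernel, min_area=sc.min_area,
        erode_radius=sc.erode_radius, dilate_radius=sc.dilate_radius,
    )
    variants = {"improved": wc.beta2}
    if wc.compare_beta2_zero and wc.beta2 != 0:
        variants["classical"] = 0.0
    out: dict[str, Any] = {}
    for name, beta2 in variants.items():
        params = randomwalk.WeightParams(
            beta1=wc.beta1, beta2=beta2, partial=wc.partial,
            connectivity=wc.connectivity, g_combine=wc.g_combine,
        )
        per_slice = []
        for sample in samples:
            mask, _, _ = randomwalk.segment_lung(sample.image, params, seeding_config)
            rep = metrics.segmentation_metrics(mask, sample.lung_mask)
            per_slice.append({"iou": rep.iou, "fpr": rep.fpr})
        out[name] = {
            "per_slice": per_slice,
            "mean_iou": float(np.mean([r["iou"] for r in per_slice])),
            "mean_fpr": float(np.mean([r["fpr"] for r in per_slice])),
        }
    return out


def feature_stage(config: RunConfig, outdir: Path) -> dict[str, Any]:
    """Generate the volume dataset and write the 51-column feature table."""
    pc = config.phantom
    template = phantom.NoduleVolumeSpec(
        depth=pc.volume_size, height=pc.volume_size, width=pc.volume_size,
        contrast=pc.contrast,
    )
    dataset = phantom.generate_dataset(pc.n_per_class, template, rng_seed=config.seed)
    volumes = [v for v, _ in dataset]
    labels = [lab for _, lab in dataset]
    X = np.stack([features.handcrafted(v, k=config.features.k) for v in volumes])
    table = pd.DataFrame(X, columns=features.handcrafted_feature_names())
    table.insert(0, "sample_id", [f"vol_{i:04d}" for i in range(len(volumes))])
    table["label"] = labels
    csv_path = outdir / "features.csv"
    table.to_csv(csv_path, index=False)
    return {"volumes": volumes, "labels": np.asarray(labels), "X": X,
            "csv": csv_path, "hash": _sha256(csv_path)}


def classify_stage(config: RunConfig, volumes, labels, X) -> dict[str, Any]:
    cc = config.classify
    mlp_config = classify.MLPConfig(
        hidden_units=cc.hidden_units, max_iter=cc.max_iter,
        learning_rate_init=cc.learning_rate_init, seed=config.seed,
    )
    out: dict[str, Any] = {}
    result = classify.train_and_evaluate(
        X, labels, mlp_config, ratio=cc.split_ratio, seed=config.seed,
        feature_names=features.handcrafted_feature_names(),
    )
    out["mlp"] = result.report.to_dict()
    if cc.run_fusion and cc.backbone != "none":
        if cc.backbone == "random-conv":
            backbone = classify.RandomConvBackbone(n_filters=cc.n_filters,
                                                   seed=config.seed)
        elif cc.backbone == "constant":
            backbone = classify.ConstantBackbone()
        else:
            raise ConfigError(f"unknown backbone {cc.backbone!r}")
        fusion = classify.train_fusion(volumes, labels, backbone, mlp_config,
                                       ratio=cc.split_ratio, seed=config.seed)
        out["fusion"] = fusion.report.to_dict()
    return out


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute simulate -> segment -> extract-features -> classify -> evaluate.

    Returns the report dict (also written to ``outdir/report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": config_to_dict(config)}

    logger.info("stage: simulate")
    sim = simulate_stage(config, outdir / "phantom")
    report["simulate"] = {"n_slices": len(sim["samples"]), "hashes": sim["hashes"]}

    logger.info("stage: segment")
    report["segment"] = segment_stage(config, sim["samples"])

    logger.info("stage: extract-features")
    feat = feature_stage(config, outdir)
    report["features"] = {"n_samples": len(feat["labels"]),
                          "n_features": int(feat["X"].shape[1]),
                          "hash": feat["hash"]}

    logger.info("stage: classify")
    report["classify"] = classify_stage(config, feat["volumes"], feat["labels"],
                                        feat["X"])

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
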