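"""End-to-end orchestration: generate → preprocess → segment → extract →
train → evaluate, as one seeded, configured, logged run.

Every stage writes its artifacts under the run directory together with a
config snapshot; stages are cached by a hash of their config section, so
re-running with an unchanged config skips completed work.  Two runs with
identical config and seed produce byte-identical metrics files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import evaluation, features, preprocess, segmentation
from . import synthetic_data as synth

__all__ = ["RunConfig", "RunResult", "PipelineStageError", "run_all",
           "extract_features_for_manifest"]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run."""

    out_dir: str
    seed: int = 17
    n_per_class: int = 100
    image_size: int = 128
    generator: dict = field(default_factory=dict)
    contrast_method: str = "stretch"
    segmentation: dict = field(default_factory=dict)
    hog_cell: int = 8
    hog_block: int = 2
    hog_bins: int = 9
    use_mask_features: bool = True
    variance_retained: float = 0.95
    kernel: str = "rbf"
    C: float = 1.0
    decomposition: str = "one_vs_one"
    train_fraction: float = 0.7
    stratified: bool = True

    def validate(self) -> None:
        """Fail fast: check every field against its stage's constraints."""
        if self.n_per_class < 1:
            raise ValueError("invalid config field 'n_per_class': must be >= 1")
        if self.image_size % self.hog_cell:
            raise ValueError(
                "invalid config: image_size must be divisible by hog_cell")
        if self.contrast_method not in preprocess.CONTRAST_METHODS:
            raise ValueError(
                f"invalid config field 'contrast_method': "
                f"{self.contrast_method!r}")
        # constructing the stage configs runs their own validators
        self.base_spec()
        self.segmentation_params()
        self.split_config()
        self.train_params()

    def base_spec(self) -> synth.VesselTreeSpec:
        return synth.VesselTreeSpec(image_size=self.image_size,
                                    **self.generator)

    def segmentation_params(self) -> segmentation.SegmentationParams:
        return segmentation.SegmentationParams(**self.segmentation)

    def split_config(self) -> clf.SplitConfig:
        return clf.SplitConfig(train_fraction=self.train_fraction,
                               stratified=self.stratified, seed=self.seed)

    def train_params(self) -> clf.TrainParams:
        from .features import hog_length

        hog_dims = hog_length(self.image_size, self.hog_cell, self.hog_block,
                              self.hog_bins)
        return clf.TrainParams(kernel=self.kernel, C=self.C,
                               decomposition=self.decomposition,
                               variance_retained=self.variance_retained,
                               descriptor_blocks=(256, hog_dims),
                               seed=self.seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunResult:
    out_dir: Path
    metrics: evaluation.MetricsReport
    manifest: synth.DatasetManifest
    model_path: Path
    features_path: Path


def _section_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _cached(out_dir: Path, stage: str, section_hash: str) -> bool:
    marker = out_dir / f".done_{stage}"
    return marker.exists() and marker.read_text().strip() == section_hash


def _mark(out_dir: Path, stage: str, section_hash: str) -> None:
    (out_dir / f".done_{stage}").write_text(section_hash + "\n")


def extract_features_for_manifest(manifest, image_dir, contrast_method="stretch",
                                  image_size=128, cell=8, block=2, bins=9,
                                  use_mask=True, seg_params=None):
    """Preprocess each manifest image and extract LBP+HOG feature rows.

    Returns a DataFrame with columns ``path``, ``label`` and ``f0..fN``.
    By default (``use_mask``) the descriptors are computed on the segmented
    binary vessel mask — the vessels are segmented first and described
    afterwards, which also keeps background noise out of the texture
    histogram; set ``use_mask=False`` to describe the contrast-adjusted
    grayscale image instead.
    """
    image_dir = Path(image_dir)
    rows = []
    for rec in manifest.records:
        img = preprocess.load_gray(image_dir / rec.path)
        img = preprocess.adjust_contrast(img, contrast_method)
        if img.shape != (image_size, image_size):
            img = preprocess.resize_to_standard(img, image_size)
        if use_mask:
            img = segmentation.segment(img, seg_params).astype(float)
        lbp = features.lbp_histogram(img)
        hog = features.hog_features(img, cell=cell, block=block, bins=bins)
        vec = features.combine_features(lbp, hog, source_image=rec.path)
        rows.append((rec.path, rec.label.value, vec.values))
    mat = np.vstack([v for _, _, v in rows])
    df = pd.DataFrame(mat, columns=[f"f{i}" for i in range(mat.shape[1])])
    df.insert(0, "label", [l for _, l, _ in rows])
    df.insert(0, "path", [p for p, _, _ in rows])
    return df


def run_all(config: RunConfig) -> RunResult:
    """Execute the whole pipeline per ``config``; returns the run artifacts."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    config.save_yaml(out_dir / "config.yaml")
    log_lines = [f"seed={config.seed}", f"config_hash={_section_hash(cfg)}"]

    def run_stage(name, section_keys, fn):
        h = _section_hash({k: cfg[k] for k in section_keys} | {"seed": cfg["seed"]})
        t0 = time.perf_counter()
        if _cached(out_dir, name, h):
            log_lines.append(f"stage={name} cached=true")
            return
        try:
            fn()
        except Exception as exc:
            raise PipelineStageError(name, str(exc)) from exc
        _mark(out_dir, name, h)
        log_lines.append(
            f"stage={name} cached=false seconds={time.perf_counter() - t0:.3f}")

    gen_keys = ["n_per_class", "image_size", "generator"]
    run_stage("generate", gen_keys, lambda: synth.generate_dataset(
        out_dir / "data", n_per_class=config.n_per_class, seed=config.seed,
        image_size=config.image_size, base_spec=config.base_spec()))
    manifest = synth.DatasetManifest.from_csv(out_dir / "data" / "manifest.csv",
                                              seed=config.seed)

    feat_keys = gen_keys + ["contrast_method", "hog_cell", "hog_block",
                            "hog_bins", "use_mask_features", "segmentation"]
    feat_path = out_dir / "features.csv"

    def _extract():
        df = extract_features_for_manifest(
            manifest, out_dir / "data", contrast_method=config.contrast_method,
            image_size=config.image_size, cell=config.hog_cell,
            block=config.hog_block, bins=config.hog_bins,
            use_mask=config.use_mask_features,
            seg_params=config.segmentation_params())
        df.to_csv(feat_path, index=False, float_format="%.9g")

    run_stage("extract", feat_keys, _extract)

    seg_keys = gen_keys + ["contrast_method", "segmentation"]

    def _segment_all():
        seg_dir = out_dir / "pred_masks"
        params = config.segmentation_params()
        for rec in manifest.records:
            img = preprocess.load_gray(out_dir / "data" / rec.path)
            img = preprocess.adjust_contrast(img, config.contrast_method)
            mask = segmentation.segment(img, params)
            dest = seg_dir / rec.path
            dest.parent.mkdir(parents=True, exist_ok=True)
            preprocess.save_gray(dest, mask.astype(float))

    run_stage("segment", seg_keys, _segment_all)

    train_keys = feat_keys + ["kernel", "C", "decomposition",
                              "variance_retained", "train_fraction",
                              "stratified"]
    model_path = out_dir / "model.bin"
    split_path = out_dir / "manifest_split.csv"

    def _train():
        split = clf.split_dataset(manifest, config.split_config())
        split.to_csv(split_path)
        df = pd.read_csv(feat_path)
        split_map = {r.path: r.split for r in split.records}
        df["split"] = df["path"].map(split_map)
        tr = df[df["split"] == "train"]
        X = tr.filter(regex=r"^f\d+$").to_numpy(float)
        model = clf.train(X, list(tr["label"]), config.train_params(),
                          training_manifest_hash=_section_hash(
                              {"paths": sorted(tr["path"])}))
        clf.save_model(model, model_path)

    run_stage("train", train_keys, _train)

    def _evaluate():
        model = clf.load_model(model_path)
        split = synth.DatasetManifest.from_csv(split_path, seed=config.seed)
        df = pd.read_csv(feat_path)
        split_map = {r.path: r.split for r in split.records}
        df["split"] = df["path"].map(split_map)
        te = df[df["split"] == "test"]
        X = te.filter(regex=r"^f\d+$").to_numpy(float)
        preds = clf.predict(model, X)
        pd.DataFrame({"path": te["path"],
                      "predicted_label": [p.value for p in preds]}
                     ).to_csv(out_dir / "predictions.csv", index=False)
        evaluation.report(list(te["label"]), preds, out_dir=out_dir,
                          classes=list(synth.ClassLabel))

    run_stage("evaluate", train_keys, _evaluate)

    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    with open(out_dir / "metrics.json") as fh:
        rep_dict = json.load(fh)
    metrics = evaluation.MetricsReport(
        per_class=rep_dict["per_class"],
        overall_accuracy=rep_dict["overall_accuracy"],
        n_samples=rep_dict["n_samples"], notes=rep_dict["notes"])
    return RunResult(out_dir=out_dir, metrics=metrics, manifest=manifest,
                     model_path=model_path, features_path=feat_path)
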