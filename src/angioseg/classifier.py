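"""Multiclass SVM training on reduced feature vectors.

The classifier is an assembly of binary support vector machines —
one-vs-one pairwise voting by default (the decomposition MATLAB's
multiclass SVM uses, and the one that dedicates a classifier to each
confusable class pair), one-vs-rest optionally — fitted on standardized,
PCA-reduced feature vectors.  Standardization (zero mean, unit variance,
statistics from the training split only) matters because the LBP histogram
and the HOG descriptor live on different scales.  The dataset split follows
the 70/30 train/test convention, stratified per class by default.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.multiclass import OneVsOneClassifier, OneVsRestClassifier
from sklearn.svm import SVC

from .features import PCAModel, fit_pca, transform_pca
from .synthetic_data import ClassLabel, DatasetManifest, ManifestRecord

__all__ = [
    "SplitConfig",
    "TrainParams",
    "ModelBundle",
    "ModelFormatError",
    "split_dataset",
    "train",
    "predict",
    "save_model",
    "load_model",
    "read_model_format_version",
]

_MODEL_MAGIC = b"ANGIOSEG-MODEL v1\n"
FORMAT_VERSION = 1


@dataclass(frozen=True)
class SplitConfig:
    """Train/test split: 70/30 by default, stratified, seeded."""

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}")


@dataclass(frozen=True)
class TrainParams:
    """SVM assembly hyperparameters.

    ``descriptor_blocks`` optionally names the sizes of concatenated
    descriptor blocks (e.g. ``(256, 8100)`` for LBP + HOG); each
    standardized block is then scaled by 1/sqrt(block size) so that every
    descriptor contributes equally to distances regardless of its
    dimensionality — otherwise a 8100-dim block drowns a 256-dim one.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    decomposition: str = "one_vs_one"
    variance_retained: float = 0.95
    descriptor_blocks: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.decomposition not in ("one_vs_rest", "one_vs_one"):
            raise ValueError(
                f"unknown decomposition {self.decomposition!r}; "
                "choose 'one_vs_rest' or 'one_vs_one'")
        if self.kernel not in ("rbf", "linear", "poly", "sigmoid"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")


@dataclass
class ModelBundle:
    """Everything needed to reproduce predictions: scaler, PCA, SVMs."""

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    pca: PCAModel
    svm: object
    classes: list
    params: TrainParams
    feature_weights: np.ndarray | None = None
    training_manifest_hash: str | None = None
    format_version: int = FORMAT_VERSION


class ModelFormatError(Exception):
    """Raised when a model file is corrupted or has the wrong format."""


def split_dataset(manifest: DatasetManifest, cfg: SplitConfig | None = None
                  ) -> DatasetManifest:
    """Assign train/test splits; per-class sizes are round(fraction * n).

    Stratified (default): each class is shuffled and split independently,
    so 100-image classes at fraction 0.7 give exactly 70/30.  Record order
    is preserved; no record lands in both splits.  Deterministic per seed.
    """
    cfg = cfg or SplitConfig()
    rng = np.random.default_rng(cfg.seed)
    n = len(manifest.records)
    splits = [""] * n
    if cfg.stratified:
        by_label: dict = {}
        for i, rec in enumerate(manifest.records):
            by_label.setdefault(rec.label, []).append(i)
        for label, idx in by_label.items():
            if len(idx) < 2:
                raise ValueError(
                    f"class {label.value!r} has {len(idx)} record(s); "
                    "stratified split needs at least 2 per class")
            order = rng.permutation(len(idx))
            n_train = int(round(cfg.train_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            for rank, j in enumerate(order):
                splits[idx[j]] = "train" if rank < n_train else "test"
    else:
        order = rng.permutation(n)
        n_train = int(round(cfg.train_fraction * n))
        n_train = min(max(n_train, 1), n - 1) if n >= 2 else n
        for rank, j in enumerate(order):
            splits[j] = "train" if rank < n_train else "test"
    records = [replace_record(r, split=s)
               for r, s in zip(manifest.records, splits)]
    return DatasetManifest(records=records, seed=manifest.seed)


def replace_record(rec: ManifestRecord, **kw) -> ManifestRecord:
    return ManifestRecord(path=kw.get("path", rec.path),
                          label=kw.get("label", rec.label),
                          split=kw.get("split", rec.split))


def _as_matrix(features) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D (samples x features) matrix")
    return X


def train(features, labels, params: TrainParams | None = None,
          training_manifest_hash: str | None = None) -> ModelBundle:
    """Standardize → PCA → SVM assembly, all fitted on the given rows only."""
    params = params or TrainParams()
    X = _as_matrix(features)
    if not np.isfinite(X).all():
        raise ValueError("features contain NaN or infinite values")
    y = [ClassLabel.coerce(l) for l in labels]
    if len(y) != X.shape[0]:
        raise ValueError(
            f"got {X.shape[0]} feature rows but {len(y)} labels")
    if len(set(y)) < 2:
        raise ValueError("training requires at least 2 distinct classes")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Xs = (X - mean) / scale
    weights = None
    if params.descriptor_blocks is not None:
        if sum(params.descriptor_blocks) != X.shape[1]:
            raise ValueError(
                f"descriptor_blocks {params.descriptor_blocks} do not sum to "
                f"the feature dimension {X.shape[1]}")
        weights = np.concatenate(
            [np.full(d, 1.0 / np.sqrt(d)) for d in params.descriptor_blocks])
        Xs = Xs * weights
    pca = fit_pca(Xs, variance_retained=params.variance_retained)
    Z = transform_pca(pca, Xs)

    svc = SVC(kernel=params.kernel, C=params.C, gamma=params.gamma,
              random_state=params.seed)
    wrapper = (OneVsRestClassifier(svc) if params.decomposition == "one_vs_rest"
               else OneVsOneClassifier(svc))
    wrapper.fit(Z, np.array([l.code for l in y]))
    classes = sorted(set(y), key=lambda l: l.code)
    return ModelBundle(scaler_mean=mean, scaler_scale=scale, pca=pca,
                       svm=wrapper, classes=classes, params=params,
                       feature_weights=weights,
                       training_manifest_hash=training_manifest_hash)


def predict(model: ModelBundle, features) -> list:
    """Predict one ClassLabel per feature row (empty input → empty list)."""
    X = _as_matrix(features)
    if X.shape[0] == 0:
        return []
    if X.shape[1] != model.scaler_mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: features have {X.shape[1]} columns, "
            f"model expects {model.scaler_mean.shape[0]}")
    Xs = (X - model.scaler_mean) / model.scaler_scale
    if model.feature_weights is not None:
        Xs = Xs * model.feature_weights
    Z = transform_pca(model.pca, Xs)
    codes = model.svm.predict(Z)
    return [ClassLabel.from_code(c) for c in codes]


def save_model(model: ModelBundle, path) -> None:
    """Serialize with a plain-text magic/version header before the payload."""
    buf = io.BytesIO()
    joblib.dump({"format_version": FORMAT_VERSION, "bundle": model}, buf)
    with open(path, "wb") as fh:
        fh.write(_MODEL_MAGIC)
        fh.write(buf.getvalue())


def read_model_format_version(path) -> int:
    """Read the format version from the header without loading the model."""
    with open(path, "rb") as fh:
        head = fh.read(len(_MODEL_MAGIC))
    if not head.startswith(b"ANGIOSEG-MODEL"):
        raise ModelFormatError(f"{path} is not an angioseg model file")
    try:
        return int(head.split(b"v")[-1].strip())
    except ValueError as exc:
        raise ModelFormatError(f"unreadable version header in {path}") from exc


def load_model(path) -> ModelBundle:
    with open(path, "rb") as fh:
        data = fh.read()
    if not data.startswith(_MODEL_MAGIC):
        raise ModelFormatError(
            f"{path} is not an angioseg model file (bad magic header)")
    try:
        payload = joblib.load(io.BytesIO(data[len(_MODEL_MAGIC):]))
        version = payload["format_version"]
        bundle = payload["bundle"]
    except ModelFormatError:
        raise
    except Exception as exc:
        raise ModelFormatError(f"corrupted model file {path}: {exc}") from exc
    if version != FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {version} (expected "
            f"{FORMAT_VERSION})")
    if not isinstance(bundle, ModelBundle):
        raise ModelFormatError(f"model payload in {path} has the wrong type")
    return bundle
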