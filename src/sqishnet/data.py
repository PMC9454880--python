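"""Dataset handling: CSV ingestion, per-feature standardization, the
class-stratified 80/20 split, and a synthetic generator that reproduces the
structure of the Wisconsin Breast Cancer (WBC) reference schema.

WBC has 569 samples, 30 numeric features on wildly different raw scales
(areas in the thousands next to fractal dimensions below 0.1) and two
imbalanced classes (benign/malignant).  The raw scales are so heterogeneous
that the fixed-point datapath would saturate immediately; every pipeline
therefore standardizes each feature to zero mean and unit standard
deviation — (x - mu)/sigma with the population (divide-by-n) sigma — using
statistics fitted on the training rows only, exactly as the deployed
hardware receives frozen mu/sigma.

The synthetic generator draws two multivariate-normal classes separated in
every feature and then stretches each feature by a fixed log-spaced scale
multiplier spanning four orders of magnitude, so raw features are unusable
without standardization — mirroring the property of the real data that
motivates the standardization stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "StandardizationStats",
    "SyntheticSpec",
    "fit_standardizer",
    "apply_standardizer",
    "stratified_split",
    "load_csv",
    "save_csv",
    "generate_synthetic",
]

MAX_FEATURES = 30


@dataclass
class Dataset:
    """Feature matrix plus binary labels (0 = benign-like, 1 = malignant-like)."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: list

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[1] > MAX_FEATURES:
            raise ValueError(
                f"at most {MAX_FEATURES} features supported, got {self.X.shape[1]}"
            )
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X and labels disagree on sample count")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("missing or non-finite feature values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "Dataset":
        return Dataset(self.X[idx], self.labels[idx], list(self.feature_names))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.labels
        return df


@dataclass
class StandardizationStats:
    """Per-feature mean and (population) standard deviation."""

    mu: np.ndarray
    sigma: np.ndarray
    feature_names: list = field(default_factory=list)


def fit_standardizer(X_train: np.ndarray,
                     feature_names=None,
                     ddof: int = 0) -> StandardizationStats:
    """Fit per-feature mean/sd on training rows only.

    ``ddof=0`` (population sd) is the default convention; a zero-variance
    feature is an error naming the feature, since it cannot be scaled.
    """
    X_train = np.asarray(X_train, dtype=float)
    mu = X_train.mean(axis=0)
    sigma = X_train.std(axis=0, ddof=ddof)
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X_train.shape[1])]
    bad = np.nonzero(sigma <= 0)[0]
    if bad.size:
        raise ValueError(
            f"zero-variance feature(s) cannot be standardized: "
            f"{[names[i] for i in bad]}"
        )
    return StandardizationStats(mu=mu, sigma=sigma, feature_names=names)


def apply_standardizer(X: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """(x - mu)/sigma with the fitted statistics."""
    X = np.asarray(X, dtype=float)
    return (X - stats.mu) / stats.sigma


def stratified_split(dataset: Dataset, train_fraction: float = 0.8,
                     seed: int = 0):
    """Class-stratified train/test partition, reproducible given ``seed``.

    Per-class train counts are ``round(n_class * train_fraction)``, so the
    class proportions of each side match the full data within one sample.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    classes, counts = np.unique(dataset.labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples to split")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.nonzero(dataset.labels == c)[0]
        idx = rng.permutation(idx)
        n_train = int(round(len(idx) * train_fraction))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    return dataset.subset(train_idx), dataset.subset(test_idx)


def load_csv(path, label_column: str = "label",
             positive_label="1") -> Dataset:
    """Read a feature CSV (header row, <= 30 numeric feature columns plus a
    binary label column).

    ``positive_label`` (compared as a string, so ``"M"`` or ``"1"`` both
    work) maps to class 1; exactly one other label value may be present and
    maps to class 0.  Rows with non-numeric feature cells are rejected with
    their line numbers.
    """
    df = pd.read_csv(path, dtype=str)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    feat_cols = [c for c in df.columns if c != label_column]
    if len(feat_cols) > MAX_FEATURES:
        raise ValueError(
            f"{path}: {len(feat_cols)} feature columns exceed the "
            f"{MAX_FEATURES}-feature limit"
        )
    feats = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    bad_rows = np.nonzero(feats.isna().any(axis=1).to_numpy())[0]
    if bad_rows.size:
        # +2: header line and 1-based numbering
        lines = [int(r) + 2 for r in bad_rows[:10]]
        raise ValueError(f"{path}: malformed numeric values on line(s) {lines}")
    raw_labels = df[label_column].astype(str).str.strip()
    values = sorted(raw_labels.unique())
    pos = str(positive_label)
    if pos not in values and len(values) > 1:
        raise ValueError(
            f"{path}: positive label {pos!r} absent (found {values})")
    others = [v for v in values if v != pos]
    if len(others) > 1:
        raise ValueError(f"{path}: more than two label values: {values}")
    labels = (raw_labels == pos).astype(int).to_numpy()
    return Dataset(feats.to_numpy(dtype=float), labels, feat_cols)


def save_csv(dataset: Dataset, path) -> None:
    """Write a dataset in the same schema :func:`load_csv` reads."""
    dataset.to_frame().to_csv(path, index=False)


@dataclass
class SyntheticSpec:
    """Knobs of the WBC-like generator.

    Defaults reproduce the reference shape: 569 samples, 30 features,
    class-1 (malignant-like) fraction 0.37, per-class mean separation of
    0.8 within-class standard deviations per feature, and per-feature scale
    multipliers log-spaced over four orders of magnitude (1e-2 .. 1e2).
    """

    n_samples: int = 569
    n_features: int = 30
    class1_fraction: float = 0.37
    mean_separation: float = 0.8
    scale_decades: float = 4.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.class1_fraction < 1.0:
            raise ValueError("class1_fraction must be in (0, 1)")
        if self.noise_sd <= 0 or self.scale_decades < 0:
            raise ValueError("scales must be positive")
        if self.n_features > MAX_FEATURES:
            raise ValueError(f"at most {MAX_FEATURES} features")

    def scales(self) -> np.ndarray:
        return np.logspace(-self.scale_decades / 2.0, self.scale_decades / 2.0,
                           self.n_features)


def generate_synthetic(spec: SyntheticSpec | None = None,
                       seed: int = 0) -> Dataset:
    """Draw a two-class Gaussian dataset with WBC-like structure.

    Class c has per-feature mean ``(-1)^(1-c) * separation/2`` in noise-sd
    units (alternating sign across features so neither class dominates all
    features), unit within-class sd, then feature f is multiplied by its
    fixed scale so raw standard deviations span the spec's decades.
    Reproducible given ``seed``.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    n1 = int(round(spec.n_samples * spec.class1_fraction))
    n0 = spec.n_samples - n1
    signs = np.where(np.arange(spec.n_features) % 2 == 0, 1.0, -1.0)
    offset = signs * spec.mean_separation / 2.0
    X0 = rng.normal(-offset, spec.noise_sd, (n0, spec.n_features))
    X1 = rng.normal(+offset, spec.noise_sd, (n1, spec.n_features))
    X = np.vstack([X0, X1]) * spec.scales()
    labels = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    perm = rng.permutation(spec.n_samples)
    names = [f"feat_{i:02d}" for i in range(spec.n_features)]
    return Dataset(X[perm], labels[perm], names)
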