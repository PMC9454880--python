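"""statsmodels-style modelling interface.

:class:`SqishNetClassifier` is built from data (arrays, a
:class:`~sqishnet.data.Dataset`, or a DataFrame via
:meth:`~SqishNetClassifier.from_dataframe`); calling :meth:`fit` runs the
momentum-SGD trainer and returns a :class:`SqishNetResults` carrying the
fitted weights, the training history, evaluation helpers and the
deployment path (quantize -> weight-memory image -> fixed-point
inference)::

    ds = generate_synthetic(seed=42)
    model = SqishNetClassifier(ds.X, ds.labels)
    res = model.fit(epochs=200, seed=42)
    print(res.summary())
    report = res.evaluate()              # float datapath
    report_fx = res.evaluate(fixed_point=True)

Standardization statistics are fitted on the training split only and
travel with the results, mirroring the frozen mu/sigma a deployed device
receives.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import data as _data
from . import network as _net
from . import training as _training
from .fixed_point import Q1_6, Q4_7, QFormat, quantize_raw
from .metrics import ClassificationReport, classification_report
from .network import CostReport, Topology, count_operations, forward, forward_fixed, predict

__all__ = ["SqishNetClassifier", "SqishNetResults"]


class SqishNetClassifier:
    """Two-layer Sqish/LogSQNL classifier bound to a two-class dataset.

    Parameters
    ----------
    X, labels : array-like
        Feature matrix (<= 30 columns) and binary labels.
    n_hidden : int
        Hidden-layer width (default 5, the reference topology).
    train_fraction : float
        Stratified train share (default 0.8).
    split_seed : int or None
        Seed of the stratified split; defaults to the fit seed.
    """

    def __init__(self, X, labels, feature_names=None, n_hidden: int = 5,
                 train_fraction: float = 0.8, split_seed: int | None = None):
        X = np.asarray(X, dtype=float)
        names = (list(feature_names) if feature_names is not None
                 else [f"f{i}" for i in range(X.shape[1])])
        self.dataset = _data.Dataset(X, labels, names)
        self.topology = Topology(n_inputs=self.dataset.n_features,
                                 n_hidden=n_hidden)
        self.train_fraction = train_fraction
        self.split_seed = split_seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label",
                       positive_label=1, **kwargs) -> "SqishNetClassifier":
        feat_cols = [c for c in df.columns if c != label_column]
        labels = (df[label_column].astype(str).str.strip()
                  == str(positive_label)).astype(int).to_numpy()
        return cls(df[feat_cols].to_numpy(dtype=float), labels,
                   feature_names=feat_cols, **kwargs)

    @classmethod
    def from_dataset(cls, dataset: _data.Dataset, **kwargs) -> "SqishNetClassifier":
        return cls(dataset.X, dataset.labels, dataset.feature_names, **kwargs)

    def fit(self, config: _training.TrainingConfig | None = None,
            **overrides) -> "SqishNetResults":
        """Standardize, split and train; returns the results object.

        Keyword overrides (``epochs=200, seed=42, ...``) patch the default
        :class:`~sqishnet.training.TrainingConfig`.
        """
        config = config or _training.TrainingConfig()
        if overrides:
            config = replace(config, **overrides)
        split_seed = (self.split_seed if self.split_seed is not None
                      else config.seed)
        train_ds, test_ds = _data.stratified_split(
            self.dataset, self.train_fraction, split_seed)
        stats = _data.fit_standardizer(train_ds.X, train_ds.feature_names)
        train_std = _data.Dataset(
            _data.apply_standardizer(train_ds.X, stats),
            train_ds.labels, train_ds.feature_names)
        params, history = _training.train(train_std, self.topology, config)
        return SqishNetResults(self, config, params, history, stats,
                               train_ds, test_ds)


class SqishNetResults:
    """Fitted classifier: estimates, diagnostics and deployment helpers."""

    def __init__(self, model, config, params, history, stats,
                 train_ds, test_ds):
        self.model = model
        self.config = config
        self.params = params
        self.history = history
        self.standardizer = stats
        self.train_data = train_ds
        self.test_data = test_ds
        self._qparams = None

    # -- inference ---------------------------------------------------------

    def standardize(self, X) -> np.ndarray:
        return _data.apply_standardizer(np.asarray(X, float), self.standardizer)

    def predict(self, X, fixed_point: bool = False,
                weight_format: QFormat = Q1_6) -> np.ndarray:
        """Predicted class labels for raw (unstandardized) features."""
        Xs = self.standardize(X)
        if not fixed_point:
            return np.atleast_1d(predict(forward(self.params, Xs)))
        qp = self.quantized_params(weight_format)
        raws = quantize_raw(Xs, Q4_7)
        out = [predict(forward_fixed(qp, row)) for row in np.atleast_2d(raws)]
        return np.asarray(out, dtype=int)

    def evaluate(self, dataset: _data.Dataset | None = None,
                 fixed_point: bool = False) -> ClassificationReport:
        """Classification report on the held-out test split (default) via
        the float or the emulated fixed-point datapath."""
        ds = dataset if dataset is not None else self.test_data
        pred = self.predict(ds.X, fixed_point=fixed_point)
        return classification_report(pred, ds.labels)

    # -- deployment --------------------------------------------------------

    def quantized_params(self, weight_format: QFormat = Q1_6) -> _net.QuantizedParams:
        if (self._qparams is None
                or self._qparams.weight_format != weight_format):
            self._qparams = _net.quantize_params(self.params, weight_format)
        return self._qparams

    def export_weight_memory(self, path,
                             weight_format: QFormat = Q1_6) -> _net.WeightMemoryImage:
        image = _net.export_weight_memory(self.quantized_params(weight_format))
        _net.write_memory_file(image, path)
        return image

    def cost_report(self, weight_bits: int | None = None) -> CostReport:
        bits = (weight_bits if weight_bits is not None
                else self.quantized_params().weight_format.total_bits)
        return count_operations(self.model.topology, bits)

    # -- diagnostics -------------------------------------------------------

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.history.epoch,
            "loss": self.history.loss,
            "train_acc": self.history.train_accuracy,
        })

    def plot_history(self, ax=None):
        """Loss and train-accuracy curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.history_frame()
        ax.plot(df["epoch"], df["loss"], label="loss")
        ax.plot(df["epoch"], df["train_acc"], label="train accuracy")
        ax.set_xlabel("epoch")
        ax.legend()
        return ax

    def summary(self) -> str:
        t = self.model.topology
        cost = self.cost_report()
        rep = self.evaluate()
        lines = [
            "Sqish/LogSQNL fixed-point MLP classifier",
            "=" * 46,
            f"topology:            {t.n_inputs}-{t.n_hidden}-{t.n_outputs}",
            f"train/test samples:  {self.train_data.n_samples}/"
            f"{self.test_data.n_samples}",
            f"learning rate:       {self.config.learning_rate:.6g}",
            f"momentum:            {self.config.momentum}",
            f"batch size:          {self.config.batch_size}",
            f"epochs:              {self.config.epochs}",
            f"gradient mode:       {self.config.gradient_mode}",
            f"final train loss:    {self.history.loss[-1]:.6f}",
            f"final train acc:     {self.history.train_accuracy[-1]:.4f}",
            f"test accuracy:       {rep.accuracy:.4f}",
            f"macro precision:     {rep.macro_precision:.4f}",
            f"macro recall:        {rep.macro_recall:.4f}",
            f"synapses:            {cost.synapses}",
            f"multiplications:     {cost.multiplications}",
            f"additions:           {cost.accumulation_additions}",
            f"weight memory bits:  {cost.weight_memory_bits}",
        ]
        return "\n".join(lines)
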