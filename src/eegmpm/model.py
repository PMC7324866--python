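"""Model/Results interface over the classification pipeline.

:class:`EEGClassifier` is constructed from data (labeled segments, or a
precomputed feature frame) plus configuration; ``fit()`` returns an
:class:`EEGClassifierResults` carrying the fitted pipeline, the pairwise
separability (alpha) table, prediction/evaluation methods, a text
``summary()`` and ROC plotting.

Example
-------
>>> from eegmpm import SynthConfig, generate_dataset, split_train_test
>>> from eegmpm.model import EEGClassifier
>>> data = generate_dataset(SynthConfig(n_per_class=20, seed=7))
>>> train, test = split_train_test(data, 0.5, seed=7)
>>> res = EEGClassifier(train, n_neurons=12, seed=7).fit()
>>> acc = res.evaluate(test)["accuracy"]
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .features import EntropyParams
from .metrics import per_class_report, roc_curve
from .pipeline import (
    PipelineConfig,
    TrainedPipeline,
    fit_pipeline,
    fit_pipeline_features,
)
from .synth import EEGSegment


class EEGClassifier:
    """Epileptic-EEG classifier model: features -> RBF map -> MPM exclusion tree.

    Parameters
    ----------
    data : sequence of EEGSegment, or None
        Labeled training segments.  Use :meth:`from_feature_frame` to start
        from an already-extracted feature table instead.
    entropy : EntropyParams, optional
        ApEn/SampEn/MPE parameters (defaults: m=2, r=0.2, mpe m=3, tau=1,
        scales 1..5).
    wavelet, levels : str, int
        Wavelet family and decomposition depth for the wave-coefficient
        features (default db4, 4 levels).
    n_neurons : int
        RBF hidden-layer size K (k-means centers).
    child_rule : {"winner_restricted", "global_max"}
        Child-selection rule when growing the exclusion tree.
    seed : int
        Fixes k-means initialization; a fit is a pure function of
        (data, config).
    """

    def __init__(
        self,
        data: Sequence[EEGSegment] | None,
        *,
        entropy: EntropyParams | None = None,
        wavelet: str = "db4",
        levels: int = 4,
        n_neurons: int = 50,
        child_rule: str = "winner_restricted",
        seed: int = 0,
        normalize: bool = True,
    ) -> None:
        self.config = PipelineConfig(
            entropy=entropy or EntropyParams(),
            wavelet=wavelet,
            levels=levels,
            n_neurons=n_neurons,
            child_rule=child_rule,
            seed=seed,
            normalize=normalize,
        )
        self._segments = list(data) if data is not None else None
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None
        self._names: tuple[str, ...] | None = None

    @classmethod
    def from_feature_frame(
        cls, frame: pd.DataFrame, label_col: str = "label", **kwargs
    ) -> "EEGClassifier":
        """Build the model from a feature table (one row per segment).

        All non-label, non-``source_id`` columns are treated as features, in
        column order.
        """
        if label_col not in frame.columns:
            raise ConfigurationError(f"frame has no {label_col!r} column")
        names = tuple(c for c in frame.columns if c not in (label_col, "source_id"))
        model = cls(None, **kwargs)
        model._X = frame[list(names)].to_numpy(dtype=float)
        model._y = frame[label_col].to_numpy(dtype=int)
        model._names = names
        return model

    def fit(self) -> "EEGClassifierResults":
        if self._X is not None:
            pipeline = fit_pipeline_features(self._X, self._y, self.config, self._names)
        elif self._segments is not None:
            pipeline = fit_pipeline(self._segments, self.config)
        else:
            raise ConfigurationError("model has no data")
        return EEGClassifierResults(self, pipeline)


class EEGClassifierResults:
    """Fitted classifier: alpha table, tree, prediction and evaluation."""

    def __init__(self, model: EEGClassifier | None, pipeline: TrainedPipeline) -> None:
        self.model = model
        self.pipeline = pipeline

    # -- fitted quantities -------------------------------------------------

    @property
    def classes(self) -> tuple[int, ...]:
        return self.pipeline.bank.classes

    @property
    def alpha_table(self) -> pd.DataFrame:
        """Pairwise separability indices, sorted by alpha descending."""
        return (
            self.pipeline.bank.alpha_table()
            .sort_values("alpha", ascending=False, kind="stable")
            .reset_index(drop=True)
        )

    @property
    def root_pair(self) -> tuple[int, int]:
        return self.pipeline.tree.root.pair

    # -- prediction --------------------------------------------------------

    def predict(self, data) -> np.ndarray:
        """Classify segments (list of EEGSegment) or a feature matrix/frame."""
        if isinstance(data, pd.DataFrame):
            X = data[list(self.pipeline.feature_names)].to_numpy(dtype=float)
            return self.pipeline.predict_features(X)
        if len(data) and isinstance(data[0], EEGSegment):
            return self.pipeline.predict(data)
        return self.pipeline.predict_features(np.asarray(data, dtype=float))

    def evaluate(self, data, y_true=None) -> dict:
        """Predict and score: returns accuracy, the per-class SEN/SPE report,
        and per-class one-vs-rest ROC curves (AUC included)."""
        if y_true is None:
            y_true = np.array([s.label for s in data])
        else:
            y_true = np.asarray(y_true)
        y_pred = self.predict(data)
        report = per_class_report(y_true, y_pred, list(self.classes))
        if len(data) and isinstance(data[0], EEGSegment):
            X = self.pipeline.segments_to_features(data)
        elif isinstance(data, pd.DataFrame):
            X = data[list(self.pipeline.feature_names)].to_numpy(dtype=float)
        else:
            X = np.asarray(data, dtype=float)
        scores = self.pipeline.class_scores(X)
        rocs = {}
        for c in self.classes:
            y_bin = (y_true == c).astype(int)
            if 0 < y_bin.sum() < y_bin.size:
                rocs[c] = roc_curve(scores[c].to_numpy(), y_bin)
        return {
            "accuracy": float(np.mean(y_true == y_pred)),
            "report": report,
            "roc": rocs,
            "y_pred": y_pred,
        }

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary: configuration, alpha table, tree root."""
        cfg = self.pipeline.config
        lines = [
            "EEG MPM exclusion-tree classifier",
            "=" * 49,
            f"classes:            {list(self.classes)}",
            f"features:           {len(self.pipeline.feature_names)} "
            f"({cfg.wavelet}, {cfg.levels} levels; m={cfg.entropy.m}, "
            f"r={cfg.entropy.r}; MPE m={cfg.entropy.mpe_m}, "
            f"scales={list(cfg.entropy.scales)})",
            f"RBF neurons (K):    {self.pipeline.rbf_map.n_neurons}",
            f"child rule:         {self.pipeline.tree.child_rule}",
            f"seed:               {cfg.seed}",
            "",
            "Pairwise separability (alpha), best first:",
            "-" * 49,
        ]
        for _, row in self.alpha_table.iterrows():
            lines.append(
                f"  alpha({int(row.class_i)}:{int(row.class_j)}) = {row.alpha:.4f}"
            )
        i, j = self.root_pair
        lines.append("-" * 49)
        lines.append(f"tree root pair:     ({i}, {j})  [global max alpha]")
        lines.append(
            f"decisions per classification: {len(self.classes) - 1}"
        )
        return "\n".join(lines)

    def plot_roc(self, evaluation: dict, ax=None):
        """Plot the per-class ROC curves from an :meth:`evaluate` result."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c, curve in evaluation["roc"].items():
            ax.plot(curve.fpr, curve.tpr, label=f"class {c} (AUC {curve.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        return ax

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self.pipeline.save(path)

    @classmethod
    def load(cls, path: str | Path) -> "EEGClassifierResults":
        return cls(None, TrainedPipeline.load(path))
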