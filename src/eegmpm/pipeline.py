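"""End-to-end pipeline: normalize -> features -> RBF map -> MPM exclusion tree.

The trained pipeline bundles everything needed to classify a raw segment:
the entropy/wavelet configuration, the train-set feature standardization
(so features reach the RBF layer on comparable scales), the fitted RBF map,
the pairwise MPM bank with its alpha table, and the exclusion tree
topology.  The whole object serializes to a single JSON document and a fit
is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InsufficientDataError
from .features import EntropyParams, feature_names, feature_table
from .mpm import decision_margin
from .oaotree import (
    OAOTree,
    PairwiseBank,
    build_tree,
    classify,
    train_pairwise,
    tree_from_dict,
    tree_to_dict,
)
from .rbfmap import RBFMap, fit_rbf_map, rbf_transform
from .synth import EEGSegment, normalize_segment


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a fit depends on besides the data."""

    entropy: EntropyParams = field(default_factory=EntropyParams)
    wavelet: str = "db4"
    levels: int = 4
    n_neurons: int = 50
    child_rule: str = "winner_restricted"
    seed: int = 0
    normalize: bool = True

    def to_dict(self) -> dict:
        return {
            "entropy": {
                "m": self.entropy.m,
                "r": self.entropy.r,
                "mpe_m": self.entropy.mpe_m,
                "tau": self.entropy.tau,
                "scales": list(self.entropy.scales),
            },
            "wavelet": self.wavelet,
            "levels": self.levels,
            "n_neurons": self.n_neurons,
            "child_rule": self.child_rule,
            "seed": self.seed,
            "normalize": self.normalize,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        e = d["entropy"]
        return cls(
            entropy=EntropyParams(
                m=int(e["m"]), r=float(e["r"]), mpe_m=int(e["mpe_m"]),
                tau=int(e["tau"]), scales=tuple(int(s) for s in e["scales"]),
            ),
            wavelet=str(d["wavelet"]),
            levels=int(d["levels"]),
            n_neurons=int(d["n_neurons"]),
            child_rule=str(d["child_rule"]),
            seed=int(d["seed"]),
            normalize=bool(d["normalize"]),
        )


@dataclass(frozen=True)
class TrainedPipeline:
    """Serializable result of :func:`fit_pipeline`."""

    config: PipelineConfig
    feature_names: tuple[str, ...]
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    rbf_map: RBFMap
    bank: PairwiseBank
    tree: OAOTree

    # -- feature-space plumbing -------------------------------------------

    def segments_to_features(self, segments: Sequence[EEGSegment]) -> np.ndarray:
        segs = [normalize_segment(s) if self.config.normalize else s for s in segments]
        df = feature_table(segs, self.config.entropy, self.config.wavelet,
                           self.config.levels)
        return df[list(self.feature_names)].to_numpy(dtype=float)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.feat_mean) / self.feat_sd

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Standardized features -> RBF hidden-layer space."""
        return rbf_transform(self.rbf_map, self.standardize(X))

    # -- prediction --------------------------------------------------------

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        Z = self.transform(X)
        return np.array([classify(self.tree, z) for z in Z])

    def predict(self, segments: Sequence[EEGSegment]) -> np.ndarray:
        return self.predict_features(self.segments_to_features(segments))

    def class_scores(self, X: np.ndarray) -> pd.DataFrame:
        """One-vs-rest score per class: the *worst* pairwise margin in that
        class's favour over the M-1 pairs involving it.  Used for per-class
        ROC curves; larger means stronger evidence for the class."""
        Z = self.transform(X)
        cols = {}
        for c in self.bank.classes:
            margins = []
            for (i, j), model in self.bank.models.items():
                if c not in (i, j):
                    continue
                m = decision_margin(model, Z)
                margins.append(m if model.class_pos == c else -m)
            cols[c] = np.min(np.column_stack(margins), axis=1)
        return pd.DataFrame(cols)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format": "eegmpm-pipeline/1",
            "config": self.config.to_dict(),
            "feature_names": list(self.feature_names),
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "rbf_map": self.rbf_map.to_dict(),
            "bank": self.bank.to_dict(),
            "tree": tree_to_dict(self.tree),
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "TrainedPipeline":
        doc = json.loads(text)
        bank = PairwiseBank.from_dict(doc["bank"])
        return cls(
            config=PipelineConfig.from_dict(doc["config"]),
            feature_names=tuple(doc["feature_names"]),
            feat_mean=np.array(doc["feat_mean"], dtype=float),
            feat_sd=np.array(doc["feat_sd"], dtype=float),
            rbf_map=RBFMap.from_dict(doc["rbf_map"]),
            bank=bank,
            tree=tree_from_dict(doc["tree"], bank),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedPipeline":
        return cls.from_json(Path(path).read_text())


def fit_pipeline_features(
    X: np.ndarray,
    y: np.ndarray,
    config: PipelineConfig,
    names: tuple[str, ...] | None = None,
) -> TrainedPipeline:
    """Fit the RBF map + MPM bank + tree from precomputed feature vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int)
    if X.shape[0] != y.size:
        raise ConfigurationError("X and y length mismatch")
    if X.shape[0] < 2:
        raise InsufficientDataError("need at least 2 training vectors")
    names = names or feature_names(config.entropy, config.levels)
    feat_mean = X.mean(axis=0)
    feat_sd = X.std(axis=0)
    feat_sd = np.where(feat_sd > 0, feat_sd, 1.0)
    Xs = (X - feat_mean) / feat_sd
    n_neurons = config.n_neurons
    rbf = fit_rbf_map(Xs, n_neurons, config.seed, tuple(names))
    Z = rbf_transform(rbf, Xs)
    bank = train_pairwise(Z, y)
    tree = build_tree(bank, config.child_rule)
    return TrainedPipeline(
        config=config,
        feature_names=tuple(names),
        feat_mean=feat_mean,
        feat_sd=feat_sd,
        rbf_map=rbf,
        bank=bank,
        tree=tree,
    )


def fit_pipeline(
    segments: Sequence[EEGSegment], config: PipelineConfig | None = None
) -> TrainedPipeline:
    """Fit the full pipeline from labeled raw segments.

    Deterministic given ``config.seed``.  Every class needs at least two
    segments.
    """
    config = config or PipelineConfig()
    if any(s.label is None for s in segments):
        raise ConfigurationError("every training segment needs a label")
    segs = [normalize_segment(s) if config.normalize else s for s in segments]
    df = feature_table(segs, config.entropy, config.wavelet, config.levels)
    names = feature_names(config.entropy, config.levels)
    X = df[list(names)].to_numpy(dtype=float)
    y = df["label"].to_numpy(dtype=int)
    return fit_pipeline_features(X, y, config, names)
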