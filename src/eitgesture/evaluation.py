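"""Experiment harness: drive-pattern x classifier grids, confusion
matrices and 2-D feature-map export on the synthetic benchmarks.

Each grid cell generates a seeded dataset for one (pattern, condition),
splits it by session, fits the requested classifier and measures test
accuracy; replicates run over a list of seeds so users can apply their
own statistics to the per-seed accuracies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import forward_model as fm
from .baselines import BASELINE_NAMES, BaselineSpec, fit_baseline, predict_baseline
from .cgsvm_model import CGSVMConfig, TrainedCGSVM, predict as cg_predict, train as cg_train
from .cgsvm_model import _forward_features
from .synthetic_gestures import (
    DatasetSplit,
    NoiseParams,
    default_design,
    generate_dataset,
    split_dataset,
)

__all__ = [
    "accuracy",
    "confusion_matrix",
    "ExperimentConfig",
    "EvaluationReport",
    "fit_and_score",
    "run_pattern_comparison",
    "export_feature_map",
]


def accuracy(pred: Sequence[int], truth: Sequence[int]) -> float:
    """Fraction of exact label matches."""
    p, t = np.asarray(pred), np.asarray(truth)
    if p.shape != t.shape or len(p) == 0:
        raise ValueError("pred and truth must be equal-length and non-empty")
    return float((p == t).mean())


def confusion_matrix(
    pred: Sequence[int], truth: Sequence[int], n_classes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Counts[i, j] = #(truth == i, pred == j), plus row percentages
    (each row sums to 100 for classes present in the truth, 0 otherwise)."""
    p, t = np.asarray(pred, dtype=int), np.asarray(truth, dtype=int)
    if p.shape != t.shape:
        raise ValueError("pred and truth must have equal length")
    if len(p) and (p.min() < 0 or t.min() < 0 or p.max() >= n_classes or t.max() >= n_classes):
        raise ValueError("label out of range")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t, p), 1)
    rows = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(rows > 0, 100.0 * counts / rows, 0.0)
    return counts, pct


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid definition for the comparison harness."""

    patterns: tuple[str, ...] = ("fixed_opposite",)
    classifiers: tuple[str, ...] = ("svm",)
    conditions: tuple[str, ...] = ("normal",)
    seeds: tuple[int, ...] = (0,)
    mesh_h: float = fm.MESH_H_COARSE
    design_overrides: dict = field(default_factory=dict)
    cgsvm_overrides: dict = field(default_factory=dict)
    noise: NoiseParams = NoiseParams()

    def __post_init__(self) -> None:
        known = BASELINE_NAMES + ("cgsvm", "cgsvm_softmax", "cgsvm_center")
        for c in self.classifiers:
            if c not in known:
                raise ValueError(f"unknown classifier {c!r}; expected one of {known}")
        from .protocols import PATTERN_NAMES

        for p in self.patterns:
            if p not in PATTERN_NAMES:
                raise ValueError(f"unknown pattern {p!r}")


@dataclass
class EvaluationReport:
    """Per-cell replicate accuracies plus run metadata."""

    cells: dict[tuple[str, str, str], list[float]]
    config: ExperimentConfig
    config_hash: str

    def mean_accuracy(self, pattern: str, classifier: str, condition: str) -> float:
        return float(np.mean(self.cells[(pattern, classifier, condition)]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pat, clf, cond), accs in self.cells.items():
            for seed, acc in zip(self.config.seeds, accs):
                rows.append(
                    {"pattern": pat, "classifier": clf, "condition": cond,
                     "seed": seed, "accuracy": acc}
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "config_hash": self.config_hash,
            "seeds": list(self.config.seeds),
            "cells": {
                "|".join(k): v for k, v in self.cells.items()
            },
        }
        return json.dumps(payload, indent=2)


def _cgsvm_config(name: str, seed: int, overrides: dict, n_classes: int) -> CGSVMConfig:
    base = dict(seed=seed, n_classes=n_classes)
    base.update(overrides)
    if name == "cgsvm_softmax":  # ablation: softmax loss only
        base.update(lambda1=0.0, lambda2=0.0)
    elif name == "cgsvm_center":  # ablation: center loss only
        base.update(lambda2=0.0)
    return CGSVMConfig(**base)


def fit_and_score(
    classifier: str, split: DatasetSplit, seed: int,
    cgsvm_overrides: dict | None = None,
) -> tuple[float, np.ndarray, object]:
    """Fit one classifier on a split; return (test accuracy, test
    predictions, fitted model)."""
    n_classes = int(split.train.y().max()) + 1
    if classifier in BASELINE_NAMES:
        fitted = fit_baseline(BaselineSpec(name=classifier, seed=seed), split)
        pred = predict_baseline(fitted, split.test.X())
        model: object = fitted
    else:
        cfg = _cgsvm_config(classifier, seed, dict(cgsvm_overrides or {}), n_classes)
        model = cg_train(split, cfg)
        pred = cg_predict(model, split.test.X())
    return accuracy(pred, split.test.y()), pred, model


def run_pattern_comparison(config: ExperimentConfig) -> EvaluationReport:
    """Run the full pattern x classifier x condition grid over the
    replicate seeds and collect test accuracies."""
    blob = json.dumps(
        {k: str(v) for k, v in asdict(config).items()}, sort_keys=True
    ).encode()
    config_hash = hashlib.sha256(blob).hexdigest()[:12]
    cells: dict[tuple[str, str, str], list[float]] = {}
    for cond in config.conditions:
        for pat in config.patterns:
            splits = []
            for seed in config.seeds:
                design = default_design(cond, seed=seed, **config.design_overrides)
                ds = generate_dataset(design, pat, noise=config.noise,
                                      mesh_h=config.mesh_h)
                splits.append(split_dataset(ds))
            for clf in config.classifiers:
                accs = [
                    fit_and_score(clf, sp, seed, config.cgsvm_overrides)[0]
                    for sp, seed in zip(splits, config.seeds)
                ]
                cells[(pat, clf, cond)] = accs
    return EvaluationReport(cells=cells, config=config, config_hash=config_hash)


def export_feature_map(
    model: TrainedCGSVM, samples: np.ndarray, labels: Sequence[int],
    method: str = "pca",
) -> pd.DataFrame:
    """Project deep features of the given samples to 2-D for plotting.

    Returns a table with columns x, y, label; the projection method is a
    deterministic PCA of the feature layer (recorded in the frame attrs).
    """
    if method != "pca":
        raise ValueError("only the 'pca' projection is provided")
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (n_samples, 40) batch")
    xs = (x - model.mu) / model.sd
    feats, _ = _forward_features(xs, model.params, model.config)
    coords = PCA(n_components=2, svd_solver="full").fit_transform(feats)
    frame = pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], "label": np.asarray(labels, dtype=int)}
    )
    frame.attrs["projection"] = "pca"
    return frame
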