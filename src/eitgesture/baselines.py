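"""Reference classifiers for the comparison experiments.

Three classical learners on the raw (standardized) 40-vectors — KNN,
RBF SVM and a decision tree — plus the plain CNN-softmax network, which
shares the CG-SVM upper branch but classifies with its softmax head.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cgsvm_model import CGSVMConfig, TrainedCGSVM, predict as _nn_predict, train as _nn_train
from .synthetic_gestures import DatasetSplit

__all__ = ["BASELINE_NAMES", "BaselineSpec", "fit_baseline", "predict_baseline"]

BASELINE_NAMES = ("knn", "svm", "dtree", "cnn_softmax")


@dataclass(frozen=True)
class BaselineSpec:
    """A named baseline with optional hyperparameter overrides.

    Defaults: KNN k=5 (Euclidean); SVM RBF with C=1; decision tree with
    Gini impurity and unlimited depth; cnn_softmax uses the CG-SVM conv
    branch with a softmax head and no center terms.
    """

    name: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ValueError(
                f"unknown baseline {self.name!r}; expected one of {BASELINE_NAMES}"
            )


@dataclass
class FittedBaseline:
    spec: BaselineSpec
    model: Any


def fit_baseline(spec: BaselineSpec, split: DatasetSplit) -> FittedBaseline:
    """Fit a baseline on the train part of a split.

    Raw-feature learners are wrapped in a train-statistics standardizer."""
    x, y = split.train.X(), split.train.y()
    if len(x) == 0:
        raise ValueError("empty training set")
    hp = spec.hyperparameters
    if spec.name == "knn":
        est = KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5))
    elif spec.name == "svm":
        est = SVC(kernel=hp.get("kernel", "rbf"), C=hp.get("C", 1.0), gamma="scale")
    elif spec.name == "dtree":
        est = DecisionTreeClassifier(
            criterion=hp.get("criterion", "gini"), random_state=spec.seed
        )
    else:  # cnn_softmax
        cfg = CGSVMConfig(
            arch="cnn_softmax", lambda1=0.0, lambda2=0.0, seed=spec.seed,
            n_classes=int(np.max(y)) + 1,
            **{k: v for k, v in hp.items() if k in (
                "epochs", "batch_size", "learning_rate", "dropout_rate",
                "aux_hidden",
            )},
        )
        return FittedBaseline(spec=spec, model=_nn_train(split, cfg))
    pipe = make_pipeline(StandardScaler(), est)
    pipe.fit(x, y)
    return FittedBaseline(spec=spec, model=pipe)


def predict_baseline(fitted: FittedBaseline, samples: np.ndarray) -> np.ndarray:
    """Labels for a (B, 40) batch; an empty batch gives an empty array."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or (x.size and x.shape[1] != 40):
        raise ValueError("expected a (n_samples, 40) array")
    if len(x) == 0:
        return np.array([], dtype=int)
    if isinstance(fitted.model, TrainedCGSVM):
        return _nn_predict(fitted.model, x)
    return np.asarray(fitted.model.predict(x), dtype=int)
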