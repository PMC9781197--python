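"""Target/non-target detection and symbol selection.

A binary detector is trained on labeled epochs (target flash vs
non-target flash) and produces a continuous "targetness" score per
epoch.  For a selection, the per-epoch scores are averaged over the
first ``n_repetitions_used`` flashes of each symbol and the symbol with
the highest mean score wins (ties break to the lowest symbol index).

The primary detector is a random forest — its score is the fraction of
trees voting target.  SVM, LDA and kNN comparators plug into the same
path.  Class weighting defaults to balanced because each selection
yields 15 target vs 165 non-target epochs.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import EpochSet, PreprocConfig, bandpass, extract_epochs
from .simulate import EEGRecording

__all__ = [
    "DetectorConfig",
    "DetectorModel",
    "SelectionResult",
    "train_detector",
    "score_epochs",
    "select_symbol",
    "run_trial",
]

METHODS = ("random_forest", "svm", "lda", "knn")


@dataclass(frozen=True)
class DetectorConfig:
    method: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    class_weighting: str = "balanced"  # none | balanced
    seed: int = 42

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")


@dataclass
class DetectorModel:
    """A fitted detector plus the metadata needed to score new epochs."""

    config: DetectorConfig
    estimator: object
    n_features: int

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"version": 1, "model": self}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "DetectorModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != 1:
            raise ValueError("unrecognized model file version")
        return payload["model"]


@dataclass
class SelectionResult:
    """Outcome of one symbol selection."""

    symbol_scores: np.ndarray
    selected_symbol: int
    true_symbol: int | None
    n_repetitions_used: int

    @property
    def correct(self) -> bool | None:
        if self.true_symbol is None:
            return None
        return self.selected_symbol == self.true_symbol


def _build_estimator(config: DetectorConfig):
    hp = dict(config.hyperparameters)
    cw = "balanced" if config.class_weighting == "balanced" else None
    if config.method == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_trees", 100),
            class_weight=cw,
            random_state=config.seed,
            n_jobs=1,
            **hp,
        )
    if config.method == "svm":
        return make_pipeline(
            StandardScaler(),
            SVC(
                kernel=hp.pop("kernel", "linear"),
                C=hp.pop("C", 1.0),
                class_weight=cw,
                random_state=config.seed,
                **hp,
            ),
        )
    if config.method == "lda":
        return LinearDiscriminantAnalysis(
            solver=hp.pop("solver", "lsqr"), shrinkage=hp.pop("shrinkage", "auto"), **hp
        )
    # knn: no class weights; scaling matters for distances
    return make_pipeline(
        StandardScaler(), KNeighborsClassifier(n_neighbors=hp.pop("k", 5), **hp)
    )


def train_detector(train_epochs: EpochSet, config: DetectorConfig) -> DetectorModel:
    """Fit a target/non-target detector on labeled epochs.

    Deterministic given ``config.seed``.  Raises if the training set
    contains a single class.
    """
    y = train_epochs.labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both target and non-target epochs")
    est = _build_estimator(config)
    est.fit(train_epochs.features, y)
    return DetectorModel(config=config, estimator=est, n_features=train_epochs.features.shape[1])


def score_epochs(model: DetectorModel, epochs: EpochSet) -> np.ndarray:
    """Continuous targetness score per epoch; higher means more target-like.

    Probability of the target class where the estimator provides one
    (random forest: fraction of trees voting target; kNN: neighbor
    fraction), otherwise the signed decision function (SVM, LDA).
    """
    if epochs.n_epochs == 0:
        return np.empty(0)
    if epochs.features.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {epochs.features.shape[1]} != training dimension {model.n_features}"
        )
    est = model.estimator
    if model.config.method in ("random_forest", "knn"):
        scores = est.predict_proba(epochs.features)[:, 1]
    else:
        scores = est.decision_function(epochs.features)
    return np.asarray(scores, dtype=float)


def select_symbol(
    scores: np.ndarray,
    epochs: EpochSet,
    n_repetitions_used: int | None = None,
    true_symbol: int | None = None,
) -> SelectionResult:
    """Aggregate per-epoch scores into a symbol choice.

    ``symbol_scores[s]`` is the mean score over the first
    ``n_repetitions_used`` flashes of symbol ``s`` (flash order within a
    symbol follows block order).  Every symbol must be covered by at
    least ``n_repetitions_used`` flashes.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != epochs.n_epochs:
        raise ValueError("one score per epoch required")
    symbols = np.unique(epochs.symbol_indices)
    n_symbols = int(symbols.max()) + 1
    if not np.array_equal(symbols, np.arange(n_symbols)):
        raise ValueError("epochs must cover every symbol index 0..max")
    available = np.min(np.bincount(epochs.symbol_indices))
    if n_repetitions_used is None:
        n_repetitions_used = int(available)
    if not 1 <= n_repetitions_used <= available:
        raise ValueError(
            f"n_repetitions_used must be in 1..{available}, got {n_repetitions_used}"
        )
    use = epochs.block_indices < n_repetitions_used
    symbol_scores = np.array(
        [scores[use & (epochs.symbol_indices == s)].mean() for s in range(n_symbols)]
    )
    if not np.all(np.isfinite(symbol_scores)):
        raise ValueError("non-finite symbol scores")
    selected = int(np.argmax(symbol_scores))  # argmax takes the lowest index on ties
    return SelectionResult(
        symbol_scores=symbol_scores,
        selected_symbol=selected,
        true_symbol=true_symbol,
        n_repetitions_used=n_repetitions_used,
    )


def run_trial(
    recording: EEGRecording,
    preproc: PreprocConfig,
    model: DetectorModel,
    n_repetitions_used: int | None = None,
) -> SelectionResult:
    """Full decode of one selection: filter, epoch, score, aggregate."""
    filtered = bandpass(recording, preproc)
    epochs = extract_epochs(filtered, preproc)
    scores = score_epochs(model, epochs)
    return select_symbol(
        scores,
        epochs,
        n_repetitions_used=n_repetitions_used,
        true_symbol=recording.meta.get("target_symbol"),
    )
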