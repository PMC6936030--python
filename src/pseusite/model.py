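"""Random-forest training, hyper-parameter grid search and prediction.

The classifier is a 200-tree random forest whose two tuned
hyper-parameters are the maximum tree depth (searched over 2..6) and
the fraction of features considered at each split (20%..80% in 5%
steps).  Every (depth, fraction) combination is scored by stratified
5-fold cross-validation on identical fold splits, so combinations are
compared on paired folds; the best combination maximizes mean fold
accuracy (MCC selection available), with ties broken toward the
shallower tree and then the smaller feature fraction.  The winning
configuration is refit on the full development set and the refit
forest's impurity-based feature importances are profiled — the three
chemical-property features at the central position are constant (the
center is always U) and therefore receive exactly zero importance.

Prediction scores are tree-vote fractions: the share of trees calling
a fragment positive, thresholded at 0.5 by default.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .encoders import FeatureMatrix, PsekncParams, encode_dataset
from .metrics import ConfusionCounts, EvalResult
from .sequence_io import (EdgePolicy, FragmentDataset, RnaSequence,
                          UCenteredFragment, extract_u_windows)

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: max_features grid: 20% to 80% of the feature count in 5% steps.
DEFAULT_FRACTIONS = tuple(round(0.20 + 0.05 * i, 2) for i in range(13))
DEFAULT_DEPTHS = (2, 3, 4, 5, 6)


class TrainingError(ValueError):
    """Raised when a dataset cannot support training."""


class PredictionError(ValueError):
    """Raised for fragments incompatible with a trained model."""


class ModelLoadError(ValueError):
    """Raised when a model file cannot be loaded."""


@dataclass(frozen=True)
class ForestConfig:
    """Configuration of a single random forest."""

    n_trees: int = 200
    max_depth: int = 6
    max_features_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0.0 < self.max_features_fraction <= 1.0:
            raise ValueError("max_features_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class GridSpec:
    """Hyper-parameter grid and cross-validation layout."""

    depth_values: tuple[int, ...] = DEFAULT_DEPTHS
    fraction_values: tuple[float, ...] = DEFAULT_FRACTIONS
    folds: int = 5
    seed: int = 0
    n_trees: int = 200
    criterion: str = "accuracy"  # or "mcc"
    pooled: bool = False  # pool out-of-fold predictions instead of averaging folds

    def __post_init__(self) -> None:
        if not self.depth_values or not self.fraction_values:
            raise ValueError("grids must be non-empty")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.criterion not in ("accuracy", "mcc"):
            raise ValueError("criterion must be 'accuracy' or 'mcc'")


@dataclass
class CvResult:
    """Outcome of a grid search under cross-validation.

    ``mean_accuracy`` is the depth × fraction table of mean fold
    accuracies (the heatmap); ``fold_metrics`` holds SN/SP/ACC/MCC per
    combination per fold; ``fold_assignments`` maps each sample to its
    held-out fold, shared by all combinations.
    """

    mean_accuracy: pd.DataFrame
    fold_metrics: pd.DataFrame
    best_depth: int
    best_fraction: float
    best_score: float
    fold_assignments: np.ndarray
    grid: GridSpec

    def heatmap_tsv(self, path) -> None:
        """Write the accuracy table: rows = depth, columns = fraction."""
        self.mean_accuracy.to_csv(path, sep="\t", index_label="max_depth")


@dataclass
class TrainedClassifier:
    """A fitted forest bundled with its encoding and provenance."""

    estimator: RandomForestClassifier
    config: ForestConfig
    encoder_id: str
    encoder_params: dict
    feature_names: list[str]
    window_length: int
    species_tag: str = "custom"

    @property
    def importances(self) -> np.ndarray:
        return self.estimator.feature_importances_


def _features_per_split(fraction: float, n_features: int) -> int:
    return max(1, round(fraction * n_features))


def _encode(dataset: FragmentDataset, encoder_id: str,
            k_max: int, pseknc_params: Optional[PsekncParams]) -> FeatureMatrix:
    fm = encode_dataset(dataset, encoder_id=encoder_id, k_max=k_max,
                        pseknc_params=pseknc_params)
    if fm.labels is None:
        raise TrainingError("dataset must be fully labeled for training")
    if len(set(fm.labels.tolist())) < 2:
        raise TrainingError("training requires both positive and negative fragments")
    return fm


def _forest(n_trees: int, depth: int, max_features: int, seed: int
            ) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, max_depth=depth, max_features=max_features,
        random_state=seed, n_jobs=1,
    )


def grid_search_cv(
    dataset: FragmentDataset,
    encoder_id: str = "NCP",
    grid: Optional[GridSpec] = None,
    k_max: int = 5,
    pseknc_params: Optional[PsekncParams] = None,
) -> CvResult:
    """Exhaustively score every (depth, fraction) combination.

    All combinations are evaluated on the same stratified fold splits
    (fixed by ``grid.seed``), making the comparison paired.  The
    encoders are pure functions of the fragment, so encoding the whole
    dataset up front cannot leak label information across folds.
    """
    grid = grid or GridSpec()
    fm = _encode(dataset, encoder_id, k_max, pseknc_params)
    X, y = fm.values, fm.labels
    n_features = X.shape[1]

    skf = StratifiedKFold(n_splits=grid.folds, shuffle=True, random_state=grid.seed)
    splits = list(skf.split(X, y))
    fold_assignments = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(splits):
        fold_assignments[test_idx] = fold

    rows = []
    for depth, fraction in itertools.product(grid.depth_values, grid.fraction_values):
        mf = _features_per_split(fraction, n_features)
        oof_true: list[np.ndarray] = []
        oof_pred: list[np.ndarray] = []
        for fold, (train_idx, test_idx) in enumerate(splits):
            clf = _forest(grid.n_trees, depth, mf, grid.seed)
            clf.fit(X[train_idx], y[train_idx])
            pred = clf.predict(X[test_idx])
            oof_true.append(y[test_idx])
            oof_pred.append(pred)
            res = EvalResult.from_labels(y[test_idx], pred)
            rows.append({"max_depth": depth, "max_features_fraction": fraction,
                         "fold": fold, "SN": res.sn, "SP": res.sp,
                         "ACC": res.acc, "MCC": res.mcc})
        if grid.pooled:
            pooled = EvalResult.from_labels(np.concatenate(oof_true),
                                            np.concatenate(oof_pred))
            for row in rows[-grid.folds:]:
                row["pooled_ACC"] = pooled.acc
                row["pooled_MCC"] = pooled.mcc

    fold_metrics = pd.DataFrame(rows)
    mean_table = (fold_metrics
                  .groupby(["max_depth", "max_features_fraction"])["ACC"]
                  .mean()
                  .unstack())

    metric = "ACC" if grid.criterion == "accuracy" else "MCC"
    if grid.pooled:
        scores = (fold_metrics
                  .groupby(["max_depth", "max_features_fraction"])[f"pooled_{metric}"]
                  .first())
    else:
        scores = (fold_metrics
                  .groupby(["max_depth", "max_features_fraction"])[metric]
                  .mean())
    # Maximize score; ties prefer the simpler model (smaller depth, then fraction).
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    (best_depth, best_fraction), best_score = ranked[0]

    logger.info("grid search: %d combinations x %d folds, seed=%d; best "
                "(max_depth=%d, max_features=%.2f) %s=%.4f",
                len(grid.depth_values) * len(grid.fraction_values),
                grid.folds, grid.seed, best_depth, best_fraction,
                metric, best_score)
    return CvResult(mean_accuracy=mean_table, fold_metrics=fold_metrics,
                    best_depth=int(best_depth), best_fraction=float(best_fraction),
                    best_score=float(best_score),
                    fold_assignments=fold_assignments, grid=grid)


def train_final(
    dataset: FragmentDataset,
    encoder_id: str = "NCP",
    config: Optional[ForestConfig] = None,
    k_max: int = 5,
    pseknc_params: Optional[PsekncParams] = None,
) -> TrainedClassifier:
    """Refit a forest on the full labeled dataset."""
    config = config or ForestConfig()
    fm = _encode(dataset, encoder_id, k_max, pseknc_params)
    mf = _features_per_split(config.max_features_fraction, fm.shape[1])
    clf = _forest(config.n_trees, config.max_depth, mf, config.seed)
    clf.fit(fm.values, fm.labels)
    return TrainedClassifier(
        estimator=clf, config=config, encoder_id=fm.encoder_id,
        encoder_params=fm.params, feature_names=fm.feature_names,
        window_length=dataset.window_length, species_tag=dataset.species_tag,
    )


def _encode_fragments(model: TrainedClassifier,
                      fragments: Sequence[UCenteredFragment]) -> np.ndarray:
    for f in fragments:
        if len(f) != model.window_length:
            raise PredictionError(
                f"fragment of length {len(f)} submitted to a model trained on "
                f"{model.window_length}-nt windows"
            )
    ds = FragmentDataset(fragments=list(fragments))
    pseknc = None
    if model.encoder_id == "PseKNC":
        pseknc = PsekncParams(k=model.encoder_params.get("k", 2),
                              lam=model.encoder_params.get("lambda", 2),
                              w=model.encoder_params.get("w", 0.5))
    fm = encode_dataset(ds, encoder_id=model.encoder_id,
                        k_max=model.encoder_params.get("k_max", 5),
                        pseknc_params=pseknc)
    return fm.values


def predict(
    model: TrainedClassifier,
    fragments: Sequence[UCenteredFragment],
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Score fragments; returns (scores, calls).

    The score is the fraction of trees voting positive; the call is
    ``score >= threshold``.  Deterministic for a fitted model.
    """
    if not fragments:
        return np.empty(0), np.empty(0, dtype=bool)
    X = _encode_fragments(model, fragments)
    votes = np.stack([tree.predict(X) for tree in model.estimator.estimators_])
    scores = (votes == 1).mean(axis=0)
    return scores, scores >= threshold


def evaluate(model: TrainedClassifier, test: FragmentDataset,
             threshold: float = 0.5) -> EvalResult:
    """Confusion-matrix metrics of the model on a labeled test set."""
    labels = test.labels()
    if any(l is None for l in labels):
        raise TrainingError("test dataset must be fully labeled")
    _, calls = predict(model, list(test), threshold=threshold)
    return EvalResult.from_labels(labels, calls.astype(int))


def scan_sequence(
    model: TrainedClassifier,
    seq: RnaSequence,
    edge_policy: EdgePolicy = "skip",
    threshold: float = 0.5,
) -> list[dict]:
    """Score every uridine in a whole RNA sequence.

    Returns one record per scored U with its 1-based position, score
    and call; with the default ``skip`` policy, uridines too close to
    the sequence ends are not scored.
    """
    windows = extract_u_windows(seq, model.window_length, edge_policy)
    scores, calls = predict(model, windows, threshold=threshold)
    return [
        {"sequence_id": seq.id, "position": w.origin[1],
         "score": float(s), "call": bool(c)}
        for w, s, c in zip(windows, scores, calls)
    ]


def save_model(model: TrainedClassifier, path) -> None:
    """Persist a model as a versioned single-file bundle."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "estimator": model.estimator,
        "config": model.config,
        "encoder_id": model.encoder_id,
        "encoder_params": model.encoder_params,
        "feature_names": model.feature_names,
        "window_length": model.window_length,
        "species_tag": model.species_tag,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(payload, path)


def load_model(path) -> TrainedClassifier:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted or not a joblib file
        raise ModelLoadError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelLoadError(f"{path} is not a model bundle")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelLoadError(
            f"model format version {payload['format_version']} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return TrainedClassifier(
        estimator=payload["estimator"], config=payload["config"],
        encoder_id=payload["encoder_id"], encoder_params=payload["encoder_params"],
        feature_names=payload["feature_names"],
        window_length=payload["window_length"],
        species_tag=payload["species_tag"],
    )
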