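"""SMOTE rebalancing and the random-forest + multi-layer-perceptron ensemble.

The training data for driver/passenger classification is heavily imbalanced
(roughly 0.12 positives per negative), so the minority class is oversampled
with SMOTE before fitting.  Two learners are then combined: a random forest
fit on raw features (tree splits are scale-invariant) and an MLP fit on
z-standardized features, trained by full-batch gradient descent with
momentum (classic backprop), ReLU hidden layers and a sigmoid output,
with validation-based early stopping to keep its probabilities calibrated.  The ensemble score is the unweighted mean of the two
class-1 probabilities, and a mutation is called a driver when its score is
strictly above 0.5.

Default hyperparameters: forest depth 4, 130 trees, feature fraction 0.4;
MLP hidden layers (20, 15), learning rate 0.1, momentum 0.8.  Cross-
validation is stratified 10-fold with SMOTE re-run inside each training
fold, so no synthetic point ever spans a fold boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # minority:majority after resampling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ValueError("target_ratio must be in (0, 1]")


@dataclass
class EnsembleConfig:
    rf_max_depth: int = 4
    rf_n_trees: int = 130
    rf_feature_fraction: float = 0.4
    mlp_hidden: tuple[int, ...] = (20, 15)
    mlp_lr: float = 0.1
    mlp_momentum: float = 0.8
    mlp_hidden_activation: str = "relu"
    mlp_output_activation: str = "sigmoid"
    combine: str = "mean"
    threshold: float = 0.5
    seed: int = 0
    mlp_epochs: int = 200
    mlp_batch: int | None = None  # None = full-batch gradient descent

    def __post_init__(self) -> None:
        self.mlp_hidden = tuple(self.mlp_hidden)
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if not 0.0 < self.rf_feature_fraction <= 1.0:
            raise ValueError("rf_feature_fraction must be in (0, 1]")
        if any(h < 1 for h in self.mlp_hidden):
            raise ValueError("hidden layer sizes must be >= 1")
        if self.combine != "mean":
            raise ValueError("only mean combination is supported")


@dataclass
class LabeledDataset:
    X: np.ndarray
    y: np.ndarray  # 0/1, 1 = driver
    schema_version: str = "v1"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("row counts of X and y differ")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")


@dataclass
class TrainedModel:
    rf: RandomForestClassifier
    mlp: MLPClassifier
    means: np.ndarray
    sds: np.ndarray
    config: EnsembleConfig
    schema_version: str = "v1"


def smote_oversample(ds: LabeledDataset, cfg: SmoteConfig | None = None) -> LabeledDataset:
    """Oversample the minority class by k-NN interpolation.

    Output rows: all majority rows first (bit-identical to the input), then
    the original minority rows, then synthetic rows x + u*(x_nn - x) with u
    uniform in [0, 1], until the minority count reaches
    floor(target_ratio * majority count).  Seeded and reproducible.
    """
    cfg = cfg or SmoteConfig()
    y = ds.y
    n1, n0 = int(y.sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ModelError("both classes must be present")
    minority_label = 1 if n1 <= n0 else 0
    X_min = ds.X[y == minority_label]
    X_maj = ds.X[y != minority_label]
    n_min, n_maj = len(X_min), len(X_maj)
    if n_min < 2:
        raise ModelError("minority class must have >= 2 members for SMOTE")

    target = int(np.floor(cfg.target_ratio * n_maj))
    n_synth = max(0, target - n_min)
    k = cfg.k_neighbors
    if k >= n_min:
        k = n_min - 1
        logger.warning("k_neighbors clipped to %d (minority size %d)", k, n_min)

    if n_synth == 0:
        X_out = np.vstack([X_maj, X_min])
    else:
        rng = np.random.default_rng(cfg.seed)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        # column 0 is the point itself
        neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]
        base_idx = rng.integers(0, n_min, size=n_synth)
        nn_choice = rng.integers(0, k, size=n_synth)
        u = rng.uniform(0.0, 1.0, size=n_synth)
        x = X_min[base_idx]
        x_nn = X_min[neigh[base_idx, nn_choice]]
        synth = x + u[:, None] * (x_nn - x)
        X_out = np.vstack([X_maj, X_min, synth])

    n_min_total = len(X_out) - n_maj
    y_out = np.concatenate(
        [
            np.full(n_maj, 1 - minority_label, dtype=int),
            np.full(n_min_total, minority_label, dtype=int),
        ]
    )
    return LabeledDataset(X_out, y_out, ds.schema_version)


def _fit_rf(X: np.ndarray, y: np.ndarray, cfg: EnsembleConfig) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=cfg.rf_n_trees,
        max_depth=cfg.rf_max_depth,
        max_features=cfg.rf_feature_fraction,
        random_state=cfg.seed,
        n_jobs=1,
    )
    return rf.fit(X, y)


def _fit_mlp(Xz: np.ndarray, y: np.ndarray, cfg: EnsembleConfig) -> MLPClassifier:
    if cfg.mlp_hidden_activation != "relu" or cfg.mlp_output_activation != "sigmoid":
        raise ModelError("only relu hidden / sigmoid output activations are supported")
    batch = len(Xz) if cfg.mlp_batch is None else min(cfg.mlp_batch, len(Xz))
    mlp = MLPClassifier(
        hidden_layer_sizes=cfg.mlp_hidden,
        activation="relu",
        solver="sgd",
        learning_rate_init=cfg.mlp_lr,
        momentum=cfg.mlp_momentum,
        batch_size=batch,
        max_iter=cfg.mlp_epochs,
        early_stopping=True,
        validation_fraction=0.15,
        n_iter_no_change=20,
        random_state=cfg.seed + 1,
        alpha=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # full-batch exceeds the post-validation-split fold size; sklearn clips
        warnings.simplefilter("ignore", UserWarning)
        mlp.fit(Xz, y)
    return mlp


def train(
    ds: LabeledDataset,
    ecfg: EnsembleConfig | None = None,
    scfg: SmoteConfig | None = None,
) -> TrainedModel:
    """SMOTE-rebalance, standardize, and fit the RF + MLP pair.

    Standardization parameters are estimated on the (post-SMOTE) training
    rows only; the forest sees raw features, the perceptron standardized
    ones.  A fixed seed gives a bit-identical rerun.
    """
    from .features import standardize  # local import to avoid cycle

    ecfg = ecfg or EnsembleConfig()
    scfg = scfg or SmoteConfig(seed=ecfg.seed)
    if not np.all(np.isfinite(ds.X)):
        raise ModelError("non-finite features in training data")
    if len(np.unique(ds.y)) < 2:
        raise ModelError("training data must contain both classes")

    res = smote_oversample(ds, scfg)
    means, sds = standardize(res.X)
    rf = _fit_rf(res.X, res.y, ecfg)
    mlp = _fit_mlp((res.X - means) / sds, res.y, ecfg)
    return TrainedModel(rf, mlp, means, sds, ecfg, ds.schema_version)


def score_components(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class-1 probabilities of the two branches, in input row order."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.means.shape[0]:
        raise ModelError(
            f"feature dimension {X.shape[1]} does not match model ({model.means.shape[0]})"
        )
    rf_p = model.rf.predict_proba(X)[:, list(model.rf.classes_).index(1)]
    mlp_p = model.mlp.predict_proba((X - model.means) / model.sds)
    mlp_p = mlp_p[:, list(model.mlp.classes_).index(1)]
    return rf_p, mlp_p


def score(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """The driver score: arithmetic mean of the RF and MLP probabilities."""
    rf_p, mlp_p = score_components(model, X)
    return (rf_p + mlp_p) / 2.0


def classify(s: float | np.ndarray, threshold: float = 0.5):
    """Driver call: strictly above the threshold; a tie at 0.5 is negative."""
    s = np.asarray(s, dtype=float)
    if np.any((s < 0.0) | (s > 1.0)):
        raise ModelError("score outside [0, 1]")
    out = s > threshold
    return bool(out) if out.ndim == 0 else out


def _canonical_order(ds: LabeledDataset) -> np.ndarray:
    """Row permutation making CV folds invariant to input row order."""
    keys = np.vstack([ds.X.T, ds.y]).round(12)
    return np.lexsort(keys)


def cross_val_scores(
    ds: LabeledDataset,
    ecfg: EnsembleConfig | None = None,
    scfg: SmoteConfig | None = None,
    folds: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled out-of-fold ensemble scores under stratified k-fold CV.

    SMOTE and standardization are re-fit inside every training fold, so no
    synthetic point's parents span a fold boundary.  Returns (scores, labels)
    aligned with each other (canonical row order, not input order).
    """
    ecfg = ecfg or EnsembleConfig()
    scfg = scfg or SmoteConfig(seed=ecfg.seed)
    if len(ds.y) < folds:
        raise ModelError(f"fewer rows ({len(ds.y)}) than folds ({folds})")
    order = _canonical_order(ds)
    X, y = ds.X[order], ds.y[order]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=ecfg.seed)
    scores = np.empty(len(y))
    for tr, te in skf.split(X, y):
        sub = LabeledDataset(X[tr], y[tr], ds.schema_version)
        model = train(sub, ecfg, scfg)
        scores[te] = score(model, X[te])
    return scores, y


def tune(
    ds: LabeledDataset,
    grid: dict[str, list] | None = None,
    folds: int = 10,
    seed: int = 0,
    scfg: SmoteConfig | None = None,
) -> EnsembleConfig:
    """Grid search over ensemble hyperparameters by mean CV AUC.

    The default grid spans forest depth 2–10, 10–300 trees and feature
    fraction 0.3–0.5.  Ties break toward the first point in sorted grid
    order, making the result deterministic.
    """
    from .evaluation import roc_auc  # local import to avoid cycle

    grid = grid or {
        "rf_max_depth": [2, 4, 6, 8, 10],
        "rf_n_trees": [10, 70, 130, 200, 300],
        "rf_feature_fraction": [0.3, 0.4, 0.5],
    }
    keys = sorted(grid)
    best_cfg, best_auc = None, -np.inf
    for values in product(*(grid[k] for k in keys)):
        cfg = replace(EnsembleConfig(seed=seed), **dict(zip(keys, values)))
        s, y = cross_val_scores(ds, cfg, scfg, folds)
        auc = roc_auc(s, y).auc
        logger.info("grid point %s -> CV AUC %.4f", dict(zip(keys, values)), auc)
        if auc > best_auc:
            best_cfg, best_auc = cfg, auc
    assert best_cfg is not None
    return best_cfg


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize the model bundle (config, scaler, both learner states)."""
    joblib.dump(
        {
            "format": "allodriver-model",
            "format_version": 1,
            "schema_version": model.schema_version,
            "config": model.config,
            "means": model.means,
            "sds": model.sds,
            "rf": model.rf,
            "mlp": model.mlp,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    try:
        bundle = joblib.load(path)
        if not isinstance(bundle, dict) or bundle.get("format") != "allodriver-model":
            raise ModelError(f"{path} is not a model bundle")
    except ModelError:
        raise
    except Exception as e:  # unpickling junk raises a zoo of error types
        raise ModelError(f"cannot load model from {path}: {e}") from e
    return TrainedModel(
        rf=bundle["rf"],
        mlp=bundle["mlp"],
        means=bundle["means"],
        sds=bundle["sds"],
        config=bundle["config"],
        schema_version=bundle["schema_version"],
    )
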