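"""Stacked hepatotoxicity classifier: base learners + deep meta-network.

The model audited by the time-split framework is a two-level stack in the
DeepDILI style.  Five conventional algorithm families — k-nearest
neighbours, logistic regression, support-vector machine, random forest and
gradient-boosted trees (XGBoost) — are fitted on an internal training split
and scored by Matthews correlation on an internal validation split.
Candidates clearing a validation-MCC floor are retained; their positive-
class probabilities over any roster form the *model-level representation*,
a (compounds x learners) probability matrix.  A feed-forward meta-network
trained on that representation produces the final DILI-potential score.

Preprocessing is deliberately minimal: zero-variance descriptors are
dropped and the rest standardized with training statistics only.  All
randomness fans out deterministically from a single master seed, so an
identical (data, config, seed) triple reproduces the model and its
predictions exactly.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .metrics import confusion_counts, scalar_metrics
from .roster import Roster

__all__ = [
    "MetaConfig",
    "EnsembleConfig",
    "Preprocessor",
    "TrainedBaseLearner",
    "ModelLevelRepresentation",
    "MetaNetwork",
    "DeepDILIModel",
    "ALL_FAMILIES",
    "DEFAULT_GRIDS",
    "FAST_GRIDS",
    "child_seed",
    "fit_preprocessor",
    "fit_base_learners",
    "select_base_learners",
    "build_mlr",
    "fit_meta_network",
    "fit_deepdili",
    "save_model",
    "load_model",
]

ALL_FAMILIES = (
    "knn",
    "logistic_regression",
    "svm",
    "random_forest",
    "xgboost",
)

#: small per-family grids; the original stack's grids are not recoverable,
#: so these stay desk-scale and overridable through EnsembleConfig.grids
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "knn": {"n_neighbors": [3, 5, 9]},
    "logistic_regression": {"C": [0.1, 1.0, 10.0]},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [200], "max_depth": [None, 8]},
    "xgboost": {"n_estimators": [200], "max_depth": [3, 5]},
}

#: one point per family — for seed sweeps and other repeated-run settings
FAST_GRIDS: dict[str, dict[str, list]] = {
    "knn": {"n_neighbors": [5]},
    "logistic_regression": {"C": [1.0]},
    "svm": {"C": [1.0]},
    "random_forest": {"n_estimators": [60]},
    "xgboost": {"n_estimators": [60], "max_depth": [3]},
}


def child_seed(master: int, *tags) -> int:
    """Derive a deterministic child seed (< 2**31) from a master seed and tags."""
    key = zlib.crc32("/".join(str(t) for t in tags).encode())
    return int(np.random.SeedSequence([int(master), key]).generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class MetaConfig:
    """Feed-forward meta-network settings.

    The network is trained by mini-batch gradient descent (Adam); early
    stopping keeps the epoch with the best validation MCC.
    """

    hidden_layer_sizes: tuple[int, ...] = (16, 8)
    activation: str = "relu"
    max_epochs: int = 100
    patience: int = 15
    learning_rate: float = 1e-2
    batch_size: int = 32
    l2_alpha: float = 1e-4  # weight decay regularizing the small meta-net

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.hidden_layer_sizes):
            raise ValueError("hidden layer sizes must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass(frozen=True)
class EnsembleConfig:
    """Everything needed to train the stacked classifier reproducibly."""

    algorithm_families: tuple[str, ...] = ALL_FAMILIES
    grids: dict[str, dict[str, list]] = field(default_factory=lambda: dict(DEFAULT_GRIDS))
    base_selection_threshold: float = 0.0
    validation_fraction: float = 0.2
    meta: MetaConfig = field(default_factory=MetaConfig)
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.algorithm_families:
            raise ValueError("at least one algorithm family must be enabled")
        unknown = set(self.algorithm_families) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown families {sorted(unknown)}; choose from {ALL_FAMILIES}")
        for fam in self.algorithm_families:
            if not self.grids.get(fam):
                raise ValueError(f"empty hyperparameter grid for family {fam!r}")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must lie in (0, 1)")

    def with_seed(self, seed: int) -> "EnsembleConfig":
        return replace(self, seed=int(seed))


def fast_config(seed: int = 0, **overrides) -> EnsembleConfig:
    """A reduced-grid configuration for repeated-run experiments."""
    defaults = dict(grids=dict(FAST_GRIDS), meta=MetaConfig(hidden_layer_sizes=(8,), max_epochs=40, patience=10))
    defaults.update(overrides)
    return EnsembleConfig(seed=seed, **defaults)


__all__.append("fast_config")


# ---------------------------------------------------------------------------
# preprocessing

@dataclass(frozen=True)
class Preprocessor:
    """Zero-variance filter + standardization, frozen to training statistics."""

    input_names: tuple[str, ...]
    kept_indices: np.ndarray
    mean: np.ndarray
    std: np.ndarray

    @property
    def kept_names(self) -> tuple[str, ...]:
        return tuple(self.input_names[i] for i in self.kept_indices)

    def transform(self, roster: Roster) -> np.ndarray:
        if tuple(roster.descriptor_names) != self.input_names:
            raise ValueError(
                "descriptor namespace mismatch: preprocessor was fitted on "
                f"{len(self.input_names)} columns, roster has "
                f"{len(roster.descriptor_names)}"
            )
        X = roster.descriptors[:, self.kept_indices]
        return (X - self.mean) / self.std


def fit_preprocessor(train: Roster) -> Preprocessor:
    """Fit descriptor hygiene on the training roster only.

    Drops descriptors with zero variance on the training set and records
    per-feature mean/sd for standardization.  Applying the fitted
    preprocessor elsewhere always uses these training statistics.
    """
    if len(train) == 0:
        raise ValueError("training roster is empty")
    X = train.descriptors
    std = X.std(axis=0)
    kept = np.flatnonzero(std > 1e-12)
    if kept.size == 0:
        raise ValueError("all descriptors have zero variance on the training set")
    return Preprocessor(
        input_names=tuple(train.descriptor_names),
        kept_indices=kept,
        mean=X[:, kept].mean(axis=0),
        std=std[kept],
    )


# ---------------------------------------------------------------------------
# base learners

@dataclass
class TrainedBaseLearner:
    family: str
    params: dict
    estimator: object
    validation_mcc: float
    fallback: bool = False

    @property
    def name(self) -> str:
        inner = ",".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return f"{self.family}({inner})"


def _make_estimator(family: str, params: dict, seed: int):
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "logistic_regression":
        return LogisticRegression(max_iter=2000, **params)
    if family == "svm":
        # sigmoid (Platt) calibration supplies the probabilities the stack consumes
        return CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed, **params), ensemble=False
        )
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "xgboost":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss",
            tree_method="hist", verbosity=0, **params,
        )
    raise ValueError(f"unknown family {family!r}")


def _check_two_classes(labels: np.ndarray, what: str) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError(f"{what} contains a single class; cannot train/score")


def fit_base_learners(
    train: Roster,
    validation: Roster,
    config: EnsembleConfig,
    preprocessor: Preprocessor | None = None,
) -> list[TrainedBaseLearner]:
    """Fit one candidate per (family x grid point) and score it on validation.

    Each candidate is fitted on the training roster and scored by the MCC
    of its 0.5-thresholded positive-class probabilities on the validation
    roster.  Deterministic given ``config.seed``.
    """
    overlap = set(train.drug_ids) & set(validation.drug_ids)
    if overlap:
        raise ValueError(f"train/validation share drug ids: {sorted(overlap)[:5]}")
    _check_two_classes(train.labels, "training set")
    _check_two_classes(validation.labels, "validation set")

    pre = preprocessor or fit_preprocessor(train)
    Xt, Xv = pre.transform(train), pre.transform(validation)
    candidates: list[TrainedBaseLearner] = []
    for family in config.algorithm_families:
        grid = config.grids[family]
        keys = sorted(grid)
        for idx, values in enumerate(itertools.product(*(grid[k] for k in keys))):
            params = dict(zip(keys, values))
            seed = child_seed(config.seed, "base", family, idx)
            est = _make_estimator(family, params, seed)
            est.fit(Xt, train.labels)
            proba = est.predict_proba(Xv)[:, 1]
            mcc = scalar_metrics(
                confusion_counts(validation.labels, (proba >= 0.5).astype(int))
            )["mcc"]
            candidates.append(
                TrainedBaseLearner(
                    family=family,
                    params=params,
                    estimator=est,
                    validation_mcc=float(mcc) if np.isfinite(mcc) else float("nan"),
                )
            )
    return candidates


def select_base_learners(
    candidates: list[TrainedBaseLearner], threshold: float
) -> list[TrainedBaseLearner]:
    """Keep candidates with validation MCC strictly above the floor.

    If no candidate clears the floor, the single best candidate is returned
    with its ``fallback`` flag set, so the stack never goes empty-handed.
    NaN validation MCCs never pass the threshold.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    kept = [c for c in candidates if np.isfinite(c.validation_mcc) and c.validation_mcc > threshold]
    if kept:
        return kept
    scores = [c.validation_mcc if np.isfinite(c.validation_mcc) else -np.inf for c in candidates]
    best = candidates[int(np.argmax(scores))]
    best.fallback = True
    return [best]


@dataclass(frozen=True)
class ModelLevelRepresentation:
    """Positive-class probability matrix (compounds x selected learners)."""

    matrix: np.ndarray
    columns: tuple[str, ...]


def build_mlr(
    learners: list[TrainedBaseLearner],
    roster: Roster,
    preprocessor: Preprocessor,
) -> ModelLevelRepresentation:
    """Stack each learner's positive-class probabilities into feature columns."""
    columns = tuple(lrn.name for lrn in learners)
    if len(roster) == 0:
        return ModelLevelRepresentation(
            matrix=np.empty((0, len(learners))), columns=columns
        )
    X = preprocessor.transform(roster)
    cols = [np.clip(lrn.estimator.predict_proba(X)[:, 1], 0.0, 1.0) for lrn in learners]
    return ModelLevelRepresentation(matrix=np.column_stack(cols), columns=columns)


# ---------------------------------------------------------------------------
# meta-network

class MetaNetwork:
    """Feed-forward net over the model-level representation.

    A thin driver around :class:`sklearn.neural_network.MLPClassifier`:
    training proceeds epoch by epoch through ``partial_fit`` on shuffled
    mini-batches so that early stopping can select the epoch maximizing
    validation MCC (rather than accuracy) and restore those weights.
    """

    def __init__(self, config: MetaConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        self.best_epoch_: int | None = None
        self.best_val_mcc_: float = -np.inf
        self._clf: MLPClassifier | None = None

    def fit(self, X, y, X_val, y_val) -> "MetaNetwork":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        X_val = np.asarray(X_val, dtype=float)
        y_val = np.asarray(y_val, dtype=int)
        if X.shape[1] != X_val.shape[1]:
            raise ValueError(
                f"representation width mismatch: train {X.shape[1]}, "
                f"validation {X_val.shape[1]}"
            )
        _check_two_classes(y, "meta training labels")
        _check_two_classes(y_val, "meta validation labels")

        cfg = self.config
        clf = MLPClassifier(
            hidden_layer_sizes=tuple(cfg.hidden_layer_sizes),
            activation=cfg.activation,
            solver="adam",
            alpha=cfg.l2_alpha,
            learning_rate_init=cfg.learning_rate,
            random_state=self.seed,
        )
        rng = np.random.default_rng(child_seed(self.seed, "meta-shuffle"))
        classes = np.array([0, 1])
        best_weights = None
        best_mcc, best_epoch, stale = -np.inf, -1, 0
        n = X.shape[0]
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                clf.partial_fit(X[batch], y[batch], classes=classes)
            pred = (clf.predict_proba(X_val)[:, 1] >= 0.5).astype(int)
            mcc = scalar_metrics(confusion_counts(y_val, pred))["mcc"]
            mcc = float(mcc) if np.isfinite(mcc) else -np.inf
            if mcc > best_mcc:
                best_mcc, best_epoch, stale = mcc, epoch, 0
                best_weights = (
                    [w.copy() for w in clf.coefs_],
                    [b.copy() for b in clf.intercepts_],
                )
            elif best_weights is not None:
                # patience only counts once a finite validation MCC exists;
                # an undertrained net stuck on the majority class must not
                # exhaust it before learning starts
                stale += 1
                if stale >= cfg.patience:
                    break
        if best_weights is not None:
            clf.coefs_, clf.intercepts_ = best_weights
        self._clf = clf
        self.best_epoch_ = best_epoch
        self.best_val_mcc_ = best_mcc if np.isfinite(best_mcc) else float("nan")
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("meta-network is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty(0)
        return np.clip(self._clf.predict_proba(X)[:, 1], 0.0, 1.0)


def fit_meta_network(
    mlr_train: ModelLevelRepresentation | np.ndarray,
    labels_train,
    mlr_valid: ModelLevelRepresentation | np.ndarray,
    labels_valid,
    meta: MetaConfig,
    seed: int,
) -> MetaNetwork:
    """Train the meta-network on model-level representations."""
    Xt = mlr_train.matrix if isinstance(mlr_train, ModelLevelRepresentation) else mlr_train
    Xv = mlr_valid.matrix if isinstance(mlr_valid, ModelLevelRepresentation) else mlr_valid
    return MetaNetwork(meta, seed).fit(Xt, labels_train, Xv, labels_valid)


# ---------------------------------------------------------------------------
# the full model

@dataclass
class DeepDILIModel:
    """A fitted stack: preprocessing state, selected learners, meta-network."""

    preprocessor: Preprocessor
    learners: list[TrainedBaseLearner]
    meta: MetaNetwork
    decision_threshold: float
    config: EnsembleConfig
    internal_validation_mcc: float = float("nan")
    fallback_used: bool = False

    def predict(self, roster: Roster) -> tuple[np.ndarray, np.ndarray]:
        """Scores in [0, 1] and thresholded binary calls for a roster."""
        mlr = build_mlr(self.learners, roster, self.preprocessor)
        scores = self.meta.predict_proba(mlr.matrix)
        return scores, (scores >= self.decision_threshold).astype(int)


def fit_deepdili(dev_pool: Roster, config: EnsembleConfig) -> DeepDILIModel:
    """Train the full stacked classifier on a development pool.

    The pool is split (stratified, seeded) into an internal training and an
    internal validation part; descriptor hygiene, base-learner fitting and
    selection all see the training part only, while the validation part
    scores candidates and steers the meta-network's early stopping.
    """
    if len(dev_pool) < 20:
        raise ValueError("development pool too small (< 20 records)")
    _check_two_classes(dev_pool.labels, "development pool")

    idx = np.arange(len(dev_pool))
    train_idx, valid_idx = train_test_split(
        idx,
        test_size=config.validation_fraction,
        stratify=dev_pool.labels,
        random_state=child_seed(config.seed, "dev-split"),
    )
    train, valid = dev_pool.subset(np.sort(train_idx)), dev_pool.subset(np.sort(valid_idx))

    pre = fit_preprocessor(train)
    candidates = fit_base_learners(train, valid, config, preprocessor=pre)
    selected = select_base_learners(candidates, config.base_selection_threshold)
    mlr_train = build_mlr(selected, train, pre)
    mlr_valid = build_mlr(selected, valid, pre)
    meta = fit_meta_network(
        mlr_train, train.labels, mlr_valid, valid.labels,
        config.meta, child_seed(config.seed, "meta"),
    )
    return DeepDILIModel(
        preprocessor=pre,
        learners=selected,
        meta=meta,
        decision_threshold=config.decision_threshold,
        config=config,
        internal_validation_mcc=meta.best_val_mcc_,
        fallback_used=any(l.fallback for l in selected),
    )


def save_model(model: DeepDILIModel, path) -> None:
    """Serialize a fitted model; reloading reproduces predictions exactly."""
    joblib.dump(model, path)


def load_model(path) -> DeepDILIModel:
    return joblib.load(path)
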