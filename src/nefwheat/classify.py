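"""Serial SVM → XGBoost fusion classifier and the comparison baselines.

The fused model runs in two stages. A kernel SVM (RBF by default, tuned by
an internal cross-validated grid over C and gamma on standardised features)
first learns a maximum-margin boundary. Its outputs are then *appended* to
the original band features as an augmented representation:

* the one-vs-rest decision-function value for each class, and
* per class, the max and the mean kernel similarity of the sample to that
  class's support vectors (2 features per class).

A gradient-boosted-tree classifier (XGBoost), tuned by its own seeded
cross-validated grid on a freshly shuffled copy of the training rows, makes
the final prediction from the augmented matrix. The augmented layout is
fixed at training time: ``bands + n_classes + 2 × n_classes`` columns.

``train_baseline`` provides the four single-model baselines (SVM, random
forest, XGBoost, AdaBoost) with small documented grids, all seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics.pairwise import pairwise_kernels
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import LabelEncoder, StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "SvmConfig",
    "XgbConfig",
    "SvmStageModel",
    "FusedClassifier",
    "train_svm_stage",
    "augment_features",
    "train_fused",
    "train_baseline",
    "BASELINE_NAMES",
]

BASELINE_NAMES = ("svm", "rf", "xgboost", "adaboost")


@dataclass
class SvmConfig:
    """SVM-stage settings: kernel plus the C/gamma tuning grid.

    ``gamma_scale_multipliers`` multiply the scale heuristic
    1 / (p · Var(X)) computed on the standardised training features.
    """

    kernel: str = "rbf"
    c_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    gamma_scale_multipliers: tuple = (0.1, 1.0, 10.0)
    cv_folds: int = 5
    seed: int = 0


@dataclass
class XgbConfig:
    """Boosted-stage tuning grid; small by design for ~120-sample problems."""

    max_depth_grid: tuple = (2, 3)
    learning_rate_grid: tuple = (0.1, 0.3)
    n_estimators_grid: tuple = (100, 300)
    cv_folds: int = 3
    crossfit_folds: int = 5
    seed: int = 0


@dataclass
class SvmStageModel:
    """Fitted first stage: scaler + tuned SVC + the info needed to augment."""

    scaler: StandardScaler
    svc: SVC
    classes_: np.ndarray
    kernel: str
    gamma: float
    n_features: int

    def decision_block(self, Xs: np.ndarray) -> np.ndarray:
        """One-vs-rest decision values, one column per class (fixed layout)."""
        d = self.svc.decision_function(Xs)
        if d.ndim == 1:  # binary: single margin, expand to per-class scores
            d = np.column_stack([-d, d])
        return d

    def support_block(self, Xs: np.ndarray) -> np.ndarray:
        """Per class: max and mean kernel similarity to its support vectors."""
        sv = self.svc.support_vectors_
        sv_labels = self.classes_[
            np.repeat(np.arange(len(self.classes_)), self.svc.n_support_)
        ]
        K = pairwise_kernels(Xs, sv, metric=self.kernel, gamma=self.gamma)
        cols = []
        for cls in self.classes_:
            Kc = K[:, sv_labels == cls]
            cols += [Kc.max(axis=1), Kc.mean(axis=1)]
        return np.column_stack(cols)


def _cv(folds: int, seed: int) -> StratifiedKFold:
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)


def train_svm_stage(X, y, cfg: SvmConfig | None = None) -> SvmStageModel:
    """Standardise, grid-tune C/gamma by stratified CV, fit the SVC."""
    cfg = cfg or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("SVM stage needs at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    var = Xs.var()
    scale = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    gamma_grid = [m * scale for m in cfg.gamma_scale_multipliers]
    folds = min(cfg.cv_folds, int(counts.min()))
    if folds >= 2:
        search = GridSearchCV(
            SVC(kernel=cfg.kernel, decision_function_shape="ovr"),
            {"C": list(cfg.c_grid), "gamma": gamma_grid},
            cv=_cv(folds, cfg.seed),
            n_jobs=1,
        ).fit(Xs, y)
        svc = search.best_estimator_
        gamma = float(search.best_params_["gamma"])
    else:  # too few per class to tune: fit mid-grid defaults
        gamma = scale
        svc = SVC(
            kernel=cfg.kernel, C=1.0, gamma=gamma, decision_function_shape="ovr"
        ).fit(Xs, y)
    return SvmStageModel(
        scaler=scaler,
        svc=svc,
        classes_=svc.classes_,
        kernel=cfg.kernel,
        gamma=gamma,
        n_features=X.shape[1],
    )


def augment_features(model: SvmStageModel, X) -> np.ndarray:
    """Append decision values and support-similarity summaries to X.

    Output width = bands + n_classes (decision block) + 2 × n_classes
    (support block). Deterministic given the fitted stage.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else '?'} does not match "
            f"the {model.n_features} bands the SVM stage was trained on"
        )
    Xs = model.scaler.transform(X)
    return np.hstack([X, model.decision_block(Xs), model.support_block(Xs)])


class FusedClassifier:
    """Serial SVM → XGBoost classifier with seeded internal tuning.

    Use :meth:`fit` / :meth:`predict`; ``train_fused`` is the functional
    spelling. Predicts only classes seen in training.
    """

    def __init__(
        self,
        svm_cfg: SvmConfig | None = None,
        xgb_cfg: XgbConfig | None = None,
        seed: int = 0,
    ):
        self.svm_cfg = svm_cfg or SvmConfig(seed=seed)
        self.xgb_cfg = xgb_cfg or XgbConfig(seed=seed)
        self.seed = seed
        self.svm_stage_: SvmStageModel | None = None
        self.xgb_: XGBClassifier | None = None
        self.encoder_: LabelEncoder | None = None

    def _training_augmentation(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Augmented training matrix with out-of-fold SVM outputs.

        Decision values and support similarities for a training row come
        from an SVM fitted without that row (the "repartitioning" between
        the two stages): in-sample SVM outputs are systematically cleaner
        than what the boosted stage will see at prediction time (a support
        vector's self-similarity is exactly the kernel bound), and training
        on them teaches the trees artefacts. Prediction-time augmentation
        uses the full-data SVM stage.
        """
        _, counts = np.unique(y, return_counts=True)
        folds = min(self.xgb_cfg.crossfit_folds, int(counts.min()))
        if folds < 2:
            return augment_features(self.svm_stage_, X)
        A = np.empty((len(y), X.shape[1] + 3 * len(self.svm_stage_.classes_)))
        cv = _cv(folds, self.seed)
        for train, held in cv.split(X, y):
            stage = train_svm_stage(X[train], y[train], self.svm_cfg)
            A[held] = augment_features(stage, X[held])
        return A

    def fit(self, X, y) -> "FusedClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.svm_stage_ = train_svm_stage(X, y, self.svm_cfg)
        A = self._training_augmentation(X, y)
        self.encoder_ = LabelEncoder().fit(y)
        codes = self.encoder_.transform(y)
        # repartition: fresh seeded shuffle before the boosted stage's own CV
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(len(y))
        A_sh, c_sh = A[perm], codes[perm]
        cfg = self.xgb_cfg
        base = XGBClassifier(
            random_state=cfg.seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
            eval_metric="logloss",
        )
        counts = np.bincount(c_sh)
        folds = min(cfg.cv_folds, int(counts.min()))
        grid = {
            "max_depth": list(cfg.max_depth_grid),
            "learning_rate": list(cfg.learning_rate_grid),
            "n_estimators": list(cfg.n_estimators_grid),
        }
        if folds >= 2:
            search = GridSearchCV(base, grid, cv=_cv(folds, cfg.seed), n_jobs=1)
            search.fit(A_sh, c_sh)
            self.xgb_ = search.best_estimator_
        else:
            base.set_params(
                max_depth=cfg.max_depth_grid[0],
                learning_rate=cfg.learning_rate_grid[0],
                n_estimators=cfg.n_estimators_grid[0],
            )
            self.xgb_ = base.fit(A_sh, c_sh)
        return self

    def _check_fitted(self) -> None:
        if self.xgb_ is None:
            raise RuntimeError("FusedClassifier is not fitted; call fit() first")

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        A = augment_features(self.svm_stage_, np.asarray(X, dtype=float))
        return self.encoder_.inverse_transform(self.xgb_.predict(A))

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        A = augment_features(self.svm_stage_, np.asarray(X, dtype=float))
        return self.xgb_.predict_proba(A)


def train_fused(
    X, y, svm_cfg: SvmConfig | None = None, xgb_cfg: XgbConfig | None = None, seed: int = 0
) -> FusedClassifier:
    return FusedClassifier(svm_cfg, xgb_cfg, seed).fit(X, y)


class _ScaledModel:
    """Scaler + inner estimator, so test rows reuse training-fold scaling."""

    def __init__(self, inner, scale: bool, encode: bool = False):
        self.inner = inner
        self.scale = scale
        self.encode = encode
        self.scaler_ = None
        self.encoder_ = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if self.scale:
            self.scaler_ = StandardScaler().fit(X)
            X = self.scaler_.transform(X)
        if self.encode:
            self.encoder_ = LabelEncoder().fit(y)
            y = self.encoder_.transform(y)
        self.inner.fit(X, y)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.scale:
            X = self.scaler_.transform(X)
        pred = self.inner.predict(X)
        if self.encode:
            pred = self.encoder_.inverse_transform(pred)
        return pred


def train_baseline(name: str, X, y, seed: int = 0, cv_folds: int = 3):
    """Fit one of the comparison baselines with its documented small grid."""
    model = make_baseline(name, seed, cv_folds)
    return model.fit(np.asarray(X, dtype=float), np.asarray(y))


def make_baseline(name: str, seed: int = 0, cv_folds: int = 3):
    """Unfitted baseline estimator (for cross-validation harnesses)."""
    cv = _cv(cv_folds, seed)
    if name == "svm":
        grid = GridSearchCV(
            SVC(kernel="rbf"),
            {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1]},
            cv=cv,
            n_jobs=1,
        )
        return _ScaledModel(grid, scale=True)
    if name == "rf":
        grid = GridSearchCV(
            RandomForestClassifier(random_state=seed, n_jobs=1),
            {"n_estimators": [100, 300], "max_depth": [None, 5]},
            cv=cv,
            n_jobs=1,
        )
        return _ScaledModel(grid, scale=False)
    if name == "xgboost":
        grid = GridSearchCV(
            XGBClassifier(
                random_state=seed,
                n_jobs=1,
                tree_method="hist",
                verbosity=0,
                eval_metric="logloss",
            ),
            {"max_depth": [2, 3], "learning_rate": [0.1, 0.3], "n_estimators": [100, 300]},
            cv=cv,
            n_jobs=1,
        )
        return _ScaledModel(grid, scale=False, encode=True)
    if name == "adaboost":
        grid = GridSearchCV(
            AdaBoostClassifier(random_state=seed),
            {"n_estimators": [50, 200], "learning_rate": [0.5, 1.0]},
            cv=cv,
            n_jobs=1,
        )
        return _ScaledModel(grid, scale=False)
    raise ValueError(f"unknown baseline: {name!r} (choose from {BASELINE_NAMES})")
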