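"""Ten-fold cross-validation harness, overall accuracy and Cohen's Kappa.

With confusion counts x_ij (rows = actual, columns = predicted), N total
samples and marginals x_i+ / x_+i:

    OA    = 100 · Σ_i x_ii / N                                    (percent)
    Kappa = (N · Σ_i x_ii − Σ_i x_i+ · x_+i) / (N² − Σ_i x_i+ · x_+i)

Folds are stratified by class label nested within a treatment group
(nitrogen level), so each fold mirrors the class mix of every treatment.
The headline numbers are the mean over fold-wise OA/Kappa; the pooled
confusion matrix and its metrics are reported alongside.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import BASELINE_NAMES, FusedClassifier, make_baseline
from .containers import BandSubset, ConfusionMatrix, SpectraMatrix

__all__ = [
    "overall_accuracy",
    "kappa",
    "stratified_folds",
    "cross_validate",
    "compare_band_inputs",
    "compare_models",
    "EvalReport",
    "MODEL_NAMES",
]

MODEL_NAMES = ("svm_xgboost",) + BASELINE_NAMES


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percent of samples on the confusion-matrix diagonal."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's chance-corrected agreement coefficient."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    observed = float(np.trace(cm.counts))
    expected = float(cm.row_marginals @ cm.col_marginals)
    denom = n * n - expected
    if denom == 0:
        return float("nan")  # degenerate: all mass in a single class
    return (n * observed - expected) / denom


def stratified_folds(labels, groups=None, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold assignment stratified by class nested within treatment group.

    Within each (group, class) cell, shuffled samples are dealt greedily to
    the currently least-filled folds, so per-fold class counts within a cell
    never deviate by more than one sample. Cells with fewer than ``k``
    members are simply spread over distinct folds.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} samples")
    groups = np.zeros(n, dtype=int) if groups is None else np.asarray(groups)
    rng = np.random.default_rng(seed)
    assignment = np.full(n, -1, dtype=int)
    fill = np.zeros(k, dtype=int)
    cells = sorted(
        set(zip(groups.tolist(), labels.tolist())), key=lambda c: (str(c[0]), str(c[1]))
    )
    for g, cls in cells:
        idx = np.flatnonzero((groups == g) & (labels == cls))
        idx = rng.permutation(idx)
        for j, sample in enumerate(idx):
            if j % k == 0:
                # restart a pass over folds, least-filled first (ties random)
                order = np.lexsort((rng.permutation(k), fill))
            fold = order[j % k]
            assignment[sample] = fold
            fill[fold] += 1
    return assignment


def fold_hash(assignment: np.ndarray) -> str:
    return hashlib.sha1(np.asarray(assignment, dtype=np.int64).tobytes()).hexdigest()[:12]


@dataclass
class EvalReport:
    """Cross-validation results: per-fold matrices/metrics plus pooled ones."""

    fold_matrices: list
    fold_oa: np.ndarray
    fold_kappa: np.ndarray
    pooled: ConfusionMatrix
    folds: np.ndarray
    seed: int
    skipped_folds: list = field(default_factory=list)

    @property
    def mean_oa(self) -> float:
        return float(np.mean(self.fold_oa))

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(self.fold_kappa))

    @property
    def pooled_oa(self) -> float:
        return overall_accuracy(self.pooled)

    @property
    def pooled_kappa(self) -> float:
        return kappa(self.pooled)

    @property
    def fold_hash(self) -> str:
        return fold_hash(self.folds)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"fold": i, "OA": oa, "Kappa": kp, "n": m.total}
            for i, (oa, kp, m) in enumerate(
                zip(self.fold_oa, self.fold_kappa, self.fold_matrices)
            )
        ]
        rows.append(
            {"fold": "mean", "OA": self.mean_oa, "Kappa": self.mean_kappa,
             "n": self.pooled.total}
        )
        rows.append(
            {"fold": "pooled", "OA": self.pooled_oa, "Kappa": self.pooled_kappa,
             "n": self.pooled.total}
        )
        return pd.DataFrame(rows)


def cross_validate(
    model_factory,
    X,
    y,
    groups=None,
    k: int = 10,
    seed: int = 0,
    folds: np.ndarray | None = None,
) -> EvalReport:
    """k-fold cross-validation of an unfitted-model factory.

    ``model_factory()`` must return a fresh estimator with fit/predict.
    All preprocessing lives inside the estimator, so it is fitted on
    training folds only. Folds whose training part holds a single class are
    skipped with a warning and recorded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds is None:
        folds = stratified_folds(y, groups, k=k, seed=seed)
    folds = np.asarray(folds)
    classes = sorted(set(y.tolist()))
    matrices, oas, kappas, skipped = [], [], [], []
    for f in sorted(set(folds.tolist())):
        test = folds == f
        train = ~test
        if len(set(y[train].tolist())) < 2:
            warnings.warn(f"fold {f}: training part has one class; skipped", stacklevel=2)
            skipped.append(int(f))
            continue
        model = model_factory()
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        cm = ConfusionMatrix.from_labels(y[test], pred, classes)
        matrices.append(cm)
        oas.append(overall_accuracy(cm))
        kappas.append(kappa(cm))
    if not matrices:
        raise ValueError("every fold was skipped")
    pooled = matrices[0]
    for m in matrices[1:]:
        pooled = pooled + m
    return EvalReport(
        matrices, np.array(oas), np.array(kappas), pooled, folds, seed, skipped
    )


def _factory(name: str, n_features: int, seed: int, fused_kwargs=None):
    if name == "svm_xgboost":
        kwargs = fused_kwargs or {}
        return lambda: FusedClassifier(seed=seed, **kwargs)
    return lambda: make_baseline(name, seed=seed)


def compare_models(
    X,
    y,
    groups=None,
    names=MODEL_NAMES,
    k: int = 10,
    seed: int = 0,
    fused_kwargs: dict | None = None,
) -> pd.DataFrame:
    """OA/Kappa per model under identical fold assignments."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = stratified_folds(y, groups, k=k, seed=seed)
    rows = []
    for name in names:
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model: {name!r} (choose from {MODEL_NAMES})")
        report = cross_validate(
            _factory(name, X.shape[1], seed, fused_kwargs), X, y, folds=folds, seed=seed
        )
        rows.append(
            {
                "model": name,
                "OA": report.mean_oa,
                "Kappa": report.mean_kappa,
                "OA_pooled": report.pooled_oa,
                "Kappa_pooled": report.pooled_kappa,
                "fold_hash": report.fold_hash,
            }
        )
    return pd.DataFrame(rows)


def compare_band_inputs(
    spectra: SpectraMatrix,
    y,
    subsets: dict,
    groups=None,
    model: str = "svm_xgboost",
    k: int = 10,
    seed: int = 0,
    fused_kwargs: dict | None = None,
) -> pd.DataFrame:
    """OA/Kappa per band-input subset under identical fold assignments.

    ``subsets`` maps a row name to a :class:`BandSubset` or an index array;
    the full-band input is always included as the first row.
    """
    y = np.asarray(y)
    folds = stratified_folds(y, groups, k=k, seed=seed)
    named = {"full": np.arange(spectra.n_bands)}
    for name, sub in subsets.items():
        idx = sub.indices if isinstance(sub, BandSubset) else np.asarray(sub, dtype=int)
        if idx.size == 0:
            raise ValueError(f"band subset {name!r} is empty")
        if idx.min() < 0 or idx.max() >= spectra.n_bands:
            raise ValueError(f"band subset {name!r} indexes outside the spectra")
        named[name] = idx
    rows = []
    for name, idx in named.items():
        X = spectra.reflectance[:, idx]
        report = cross_validate(
            _factory(model, X.shape[1], seed, fused_kwargs), X, y, folds=folds, seed=seed
        )
        rows.append(
            {
                "input": name,
                "n_bands": len(idx),
                "OA": report.mean_oa,
                "Kappa": report.mean_kappa,
                "OA_pooled": report.pooled_oa,
                "Kappa_pooled": report.pooled_kappa,
                "fold_hash": report.fold_hash,
            }
        )
    return pd.DataFrame(rows)
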