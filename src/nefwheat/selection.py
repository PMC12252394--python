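"""Characteristic-band selection: Lasso screening + CARS refinement.

Hyperspectral canopy reflectance is high-dimensional (hundreds of bands)
with strong adjacent-band collinearity. The selection strategy here runs two
stages in series:

1. **Lasso screening** — an L1-penalised linear regression of the encoded
   class target on the (standardised) bands, with the regularisation weight
   chosen by cross-validation; bands with non-zero coefficients survive.
2. **CARS refinement** (competitive adaptive reweighted sampling) — ``N``
   Monte-Carlo runs; each run subsamples the rows, fits a PLS regression on
   the currently retained bands, weights each band by its normalised
   absolute PLS coefficient, applies an exponentially decreasing forced
   reduction keeping the top ``ceil(r_i · p)`` bands (``r_i = a·e^(−k·i)``
   pinned at ``r_1 = 1`` and ``r_N = 2/p``), and optionally resamples bands
   with probability proportional to weight (adaptive reweighted sampling).
   The run whose retained set minimises cross-validated RMSE wins.

The composition (stage ``lasso_cars``) feeds the Lasso survivors into CARS,
so the final subset is always a subset of the Lasso subset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .containers import BandSubset, CarsTrace, SpectraMatrix

__all__ = [
    "LassoConfig",
    "CarsConfig",
    "encode_target",
    "lasso_screen",
    "cars_refine",
    "lasso_cars",
    "pls_fit",
    "cars_ratio_schedule",
]


@dataclass
class LassoConfig:
    """Cross-validated Lasso screening settings."""

    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, 0, 30)
    )
    cv_folds: int = 5
    target_encoding: str = "binary_01"  # or "pm1"
    max_iter: int = 50_000
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha_grid = np.sort(np.asarray(self.alpha_grid, dtype=float))
        if self.alpha_grid.size == 0:
            raise ValueError("alpha grid must be non-empty")
        if np.any(self.alpha_grid <= 0):
            raise ValueError("alphas must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.target_encoding not in ("binary_01", "pm1"):
            raise ValueError(f"unknown target encoding: {self.target_encoding!r}")


@dataclass
class CarsConfig:
    """CARS Monte-Carlo refinement settings.

    ``ars_draws=None`` draws as many bands as the input subset size per run;
    ``use_ars=False`` disables the adaptive reweighted sampling step so only
    the deterministic forced reduction shrinks the set.
    """

    n_runs: int = 50
    sample_fraction: float = 0.8
    pls_components: int = 5
    ars_draws: int | None = None
    rmsecv_folds: int = 5
    use_ars: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.pls_components < 1:
            raise ValueError("pls_components must be >= 1")


def encode_target(labels, mode: str = "binary_01") -> np.ndarray:
    """Encode class labels as a regression target.

    Two classes map to {0, 1} (``binary_01``) or {−1, +1} (``pm1``) in
    sorted label order; more classes map to 0..k−1 ordinal codes.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    codes = np.array([classes.index(l) for l in labels], dtype=float)
    if mode == "pm1" and len(classes) == 2:
        codes = 2.0 * codes - 1.0
    return codes


def _zscore(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mean) / sd


def pls_fit(X: np.ndarray, y: np.ndarray, A: int) -> tuple[np.ndarray, float]:
    """PLS1 regression coefficients (original scale) and intercept.

    ``A`` is the number of latent components, at most ``min(n − 1, p)``.
    A constant target yields zero coefficients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if A > min(n - 1, p):
        raise ValueError(f"A={A} exceeds min(n-1, p)={min(n - 1, p)}")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("X has no variance after centering")
    if y.std() == 0:
        return np.zeros(p), float(y.mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=A, scale=False)
        pls.fit(X, y)
    coef = pls.coef_.ravel()
    intercept = float(y.mean() - X.mean(axis=0) @ coef)
    return coef, intercept


def lasso_screen(
    spectra: SpectraMatrix, labels, cfg: LassoConfig | None = None
) -> BandSubset:
    """Select bands whose Lasso coefficients survive at the CV-optimal alpha.

    If every coefficient is zero at the optimum, falls back to the smallest
    alpha in the grid that yields a non-empty set (with a warning); if no
    alpha yields one (e.g. a constant target), returns an empty subset with
    a warning.
    """
    cfg = cfg or LassoConfig()
    y = encode_target(labels, cfg.target_encoding)
    X = _zscore(spectra.reflectance)
    cv = KFold(cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # coordinate-descent convergence chatter
        model = LassoCV(
            alphas=cfg.alpha_grid, cv=cv, max_iter=cfg.max_iter, tol=cfg.tol
        ).fit(X, y)
    nonzero = np.flatnonzero(model.coef_ != 0)
    if nonzero.size == 0:
        for alpha in cfg.alpha_grid:  # ascending
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lasso = Lasso(alpha=alpha, max_iter=cfg.max_iter, tol=cfg.tol).fit(X, y)
            nonzero = np.flatnonzero(lasso.coef_ != 0)
            if nonzero.size:
                warnings.warn(
                    f"empty selection at CV-optimal alpha {model.alpha_:.4g}; "
                    f"falling back to alpha {alpha:.4g}",
                    stacklevel=2,
                )
                break
        else:
            warnings.warn("no alpha yields a non-empty selection", stacklevel=2)
    return BandSubset(nonzero, spectra.wavelengths[nonzero], stage="lasso")


def cars_ratio_schedule(p: int, n_runs: int) -> np.ndarray:
    """Forced-reduction ratios r_i = a·e^(−k·i), with r_1 = 1, r_N = 2/p."""
    if p < 2:
        raise ValueError("schedule needs p >= 2")
    k = math.log(p / 2.0) / (n_runs - 1)
    return np.exp(-k * np.arange(n_runs, dtype=float))


def _rmsecv(X: np.ndarray, y: np.ndarray, A: int, folds: int, seed: int) -> float:
    cv = KFold(min(folds, len(y)), shuffle=True, random_state=seed)
    sq = []
    for tr, te in cv.split(X):
        a = min(A, len(tr) - 1, X.shape[1])
        coef, intercept = pls_fit(X[tr], y[tr], a)
        pred = X[te] @ coef + intercept
        sq.append(np.sum((pred - y[te]) ** 2))
    return float(np.sqrt(np.sum(sq) / len(y)))


def cars_refine(
    spectra: SpectraMatrix, labels, cfg: CarsConfig | None = None
) -> BandSubset:
    """CARS refinement of the bands in ``spectra`` (already restricted).

    Returns the retained set of the Monte-Carlo run minimising RMSECV,
    together with the full per-run trace. Indices in the result refer to
    ``spectra``'s band axis.
    """
    cfg = cfg or CarsConfig()
    y = encode_target(labels)
    X = _zscore(spectra.reflectance)
    n, p = X.shape
    if p < 2:
        raise ValueError("CARS needs an input subset of >= 2 bands")
    rng = np.random.default_rng(cfg.seed)
    ratios = cars_ratio_schedule(p, cfg.n_runs)
    draws = cfg.ars_draws or p

    retained = np.arange(p)
    retained_sets, rmsecv = [], []
    n_sub = max(2, math.ceil(cfg.sample_fraction * n))
    for i in range(cfg.n_runs):
        sub = rng.choice(n, size=n_sub, replace=False) if n_sub < n else np.arange(n)
        a_eff = max(1, min(cfg.pls_components, len(retained), n_sub - 1))
        if a_eff < cfg.pls_components and i == 0:
            warnings.warn(
                f"PLS components clipped to {a_eff} (retained set / subsample size)",
                stacklevel=2,
            )
        coef, _ = pls_fit(X[np.ix_(sub, retained)], y[sub], a_eff)
        w = np.abs(coef)
        w = w / w.sum() if w.sum() > 0 else np.full(len(retained), 1.0 / len(retained))

        # forced reduction: top ceil(r_i * p) by weight, ties by wavelength
        keep = min(math.ceil(ratios[i] * p), len(retained))
        order = np.lexsort((retained, -w))  # weight desc, then band index asc
        kept = retained[np.sort(order[:keep])]
        w_kept = w[np.sort(order[:keep])]

        # adaptive reweighted sampling: union of weighted draws
        if cfg.use_ars and len(kept) > 1 and w_kept.sum() > 0:
            probs = w_kept / w_kept.sum()
            drawn = rng.choice(len(kept), size=draws, replace=True, p=probs)
            kept = kept[np.unique(drawn)]
        if len(kept) < 1:
            warnings.warn(f"run {i + 1}: retained set collapsed; skipped", stacklevel=2)
            retained_sets.append(retained.copy())
            rmsecv.append(np.nan)
            continue
        retained = kept
        a_cv = max(1, min(cfg.pls_components, len(retained)))
        rmsecv.append(
            _rmsecv(X[:, retained], y, a_cv, cfg.rmsecv_folds, cfg.seed + i)
        )
        retained_sets.append(retained.copy())

    rmsecv = np.asarray(rmsecv)
    chosen = int(np.nanargmin(rmsecv))
    trace = CarsTrace(retained_sets, ratios, rmsecv, chosen)
    idx = retained_sets[chosen]
    return BandSubset(idx, spectra.wavelengths[idx], stage="cars", trace=trace)


def lasso_cars(
    spectra: SpectraMatrix,
    labels,
    lasso_cfg: LassoConfig | None = None,
    cars_cfg: CarsConfig | None = None,
) -> BandSubset:
    """Lasso screening followed by CARS refinement.

    Returned indices refer to the full band axis of ``spectra`` and are
    always a subset of the Lasso survivors. A singleton Lasso result passes
    through unchanged (CARS needs at least two bands).
    """
    screened = lasso_screen(spectra, labels, lasso_cfg)
    if len(screened) == 0:
        raise ValueError("Lasso screening selected no bands")
    if len(screened) == 1:
        return BandSubset(
            screened.indices, screened.wavelengths, stage="lasso_cars"
        )
    refined = cars_refine(spectra.select_bands(screened.indices), labels, cars_cfg)
    # map back from the restricted band axis to the full one
    full_idx = screened.indices[refined.indices]
    return BandSubset(
        full_idx, spectra.wavelengths[full_idx], stage="lasso_cars", trace=refined.trace
    )
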