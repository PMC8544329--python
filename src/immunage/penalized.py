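"""Elastic-net tuning and bootstrap stability selection for age prediction.

Follows the glmnet parameterisation: the penalty is

    lambda * [ alpha * |beta|_1 + (1 - alpha)/2 * |beta|_2^2 ]

with ``alpha`` the L1/L2 mixing weight scanned over a grid and ``lambda``
the overall strength chosen on a geometric path.  Model selection uses
repeat-averaged k-fold cross-validated RMSE: the mixing ``alpha*`` minimises
the minimum averaged RMSE, ``lambda_min`` minimises the averaged RMSE at
``alpha*``, and ``lambda_1se`` is the largest lambda whose averaged RMSE is
within one standard error of that minimum.  Stability selection refits the
penalized model on bootstrap resamples of participants and retains markers
whose coefficient is nonzero in strictly more than ``retain_threshold``
resamples.

Features are standardized internally with training-fold statistics only;
coefficients are reported per standardized unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import enet_path

logger = logging.getLogger(__name__)

__all__ = ["PenalizedSpec", "CVSelection", "StabilityResult",
           "select_alpha_lambda", "stability_select", "lambda_path",
           "penalized_path"]

_DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


@dataclass(frozen=True)
class PenalizedSpec:
    """Tuning protocol: alpha grid, CV repeats, bootstrap and retention rules.

    Defaults follow the full-scale protocol (10-fold CV repeated 500 times,
    500 bootstrap resamples, retain at > 250, 70/30 tuning split); analyses
    on desk-scale data typically lower ``n_cv_repeats``/``n_bootstrap``.
    """

    alpha_grid: tuple[float, ...] = _DEFAULT_ALPHA_GRID
    n_cv_repeats: int = 500
    n_folds: int = 10
    lambda_rule: str = "1se"            # {"min", "1se"}
    n_bootstrap: int = 500
    retain_threshold: int = 250
    train_fraction: float = 0.7
    seed: int = 0
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-2
    nadeau_bengio: bool = False         # variance-corrected SE for the 1se rule
    bootstrap_lambda: str = "fixed"     # {"fixed", "reselect"}
    #: cap on the final OLS panel; None = n_train // 5 (ensures estimability
    #: when stability selection keeps a dense candidate set)
    max_final_params: int | None = None

    def validate(self) -> None:
        g = np.asarray(self.alpha_grid, float)
        if g.min() < 0 or g.max() > 1 or not np.all(np.diff(g) > 0):
            raise ValueError("alpha_grid must be ascending within [0, 1]")
        if self.retain_threshold >= self.n_bootstrap:
            raise ValueError("retain_threshold must be < n_bootstrap")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError(f"unknown lambda_rule {self.lambda_rule!r}")
        if self.bootstrap_lambda not in ("reselect", "fixed"):
            raise ValueError(f"unknown bootstrap_lambda {self.bootstrap_lambda!r}")


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def lambda_path(X: np.ndarray, y: np.ndarray, alpha: float,
                n_lambdas: int = 50, lambda_min_ratio: float = 1e-2) -> np.ndarray:
    """Descending geometric lambda path; lambda_max just zeroes all coefficients.

    For alpha near 0 the L1 entry point diverges, so the mixing is floored at
    1e-3 when computing lambda_max (the glmnet convention).
    """
    Z, _, _ = _standardize(X)
    yc = y - y.mean()
    lam_max = np.max(np.abs(Z.T @ yc)) / (len(y) * max(alpha, 1e-3))
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, num=n_lambdas)


def _fit_path(Z: np.ndarray, yc: np.ndarray, alpha: float,
              lambdas: np.ndarray, tol: float = 1e-4,
              max_iter: int = 5000) -> np.ndarray:
    """Coefficients (p x n_lambdas) on standardized data along a fixed path."""
    _, coefs, _ = enet_path(Z, yc, l1_ratio=alpha, alphas=lambdas,
                            max_iter=max_iter, tol=tol)
    return coefs


def penalized_path(X, y, alpha: float, lambdas: np.ndarray | None = None,
                   n_lambdas: int = 50, lambda_min_ratio: float = 1e-2,
                   tol: float = 1e-4, max_iter: int = 5000):
    """Elastic-net coefficient path on internally standardized features.

    Returns ``(lambdas, coefs)`` with ``coefs`` of shape (p, len(lambdas))
    in standardized units.  As lambda -> 0 on a full-rank design the
    endpoint converges to the OLS solution (tighten ``tol`` to resolve it).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambdas is None:
        lambdas = lambda_path(X, y, alpha, n_lambdas, lambda_min_ratio)
    Z, _, _ = _standardize(X)
    coefs = _fit_path(Z, y - y.mean(), alpha, np.asarray(lambdas, float),
                      tol=tol, max_iter=max_iter)
    return np.asarray(lambdas, float), coefs


@dataclass
class CVSelection:
    """Outcome of the repeated-CV alpha/lambda scan."""

    alpha: float
    lambda_min: float
    lambda_1se: float
    cv_curve: pd.DataFrame        # alpha, lambda, mean_rmse, se_rmse
    alpha_summary: pd.DataFrame   # alpha, min_mean_rmse
    n_cv_repeats: int
    n_folds: int

    def lambda_for(self, rule: str) -> float:
        return self.lambda_1se if rule == "1se" else self.lambda_min


def _cv_rmse_matrix(X: np.ndarray, y: np.ndarray, alpha: float,
                    lambdas: np.ndarray, n_folds: int, n_repeats: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-(repeat x fold) validation RMSE along the lambda path."""
    n = len(y)
    out = np.empty((n_repeats * n_folds, len(lambdas)))
    row = 0
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        for val_idx in folds:
            tr_idx = np.setdiff1d(perm, val_idx, assume_unique=True)
            Ztr, mu, sd = _standardize(X[tr_idx])
            ytr = y[tr_idx]
            coefs = _fit_path(Ztr, ytr - ytr.mean(), alpha, lambdas)
            Zval = (X[val_idx] - mu) / sd
            pred = Zval @ coefs + ytr.mean()
            resid = pred - y[val_idx][:, None]
            out[row] = np.sqrt((resid ** 2).mean(axis=0))
            row += 1
    return out


def select_alpha_lambda(features, age, spec: PenalizedSpec,
                        rng: np.random.Generator | None = None) -> CVSelection:
    """Scan the alpha grid with repeated k-fold CV and apply the 1se rule.

    alpha* is the smallest alpha attaining the minimal averaged RMSE;
    lambda_1se is the largest path lambda whose averaged RMSE at alpha* is
    <= min RMSE + one standard error of that mean.
    """
    spec.validate()
    X = np.asarray(features, dtype=float)
    y = np.asarray(age, dtype=float)
    n = len(y)
    if spec.n_folds > n:
        raise ValueError(f"n_folds={spec.n_folds} exceeds n={n}")
    if n < 2 * spec.n_folds:
        raise ValueError(f"need n >= 2*n_folds; got n={n}")
    if np.std(y) == 0:
        raise ValueError("response (age) is constant")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    curves = []
    best = None  # (min_rmse, alpha, lambdas, mean_rmse, se_rmse)
    alpha_rows = []
    for alpha in spec.alpha_grid:
        lambdas = lambda_path(X, y, alpha, spec.n_lambdas, spec.lambda_min_ratio)
        # one child stream per alpha so the scan order cannot leak between alphas
        sub = np.random.default_rng(rng.integers(2 ** 31))
        mat = _cv_rmse_matrix(X, y, alpha, lambdas, spec.n_folds,
                              spec.n_cv_repeats, sub)
        mean_rmse = mat.mean(axis=0)
        # 1se band: per-repeat SE across folds (sd/sqrt(k) as in cv.glmnet),
        # averaged over repeats -- repeating stabilizes the band rather than
        # shrinking it with the repeat count
        per_repeat = mat.reshape(spec.n_cv_repeats, spec.n_folds, -1)
        se = (per_repeat.std(axis=1, ddof=1) / np.sqrt(spec.n_folds)).mean(axis=0)
        if spec.nadeau_bengio:
            # Nadeau-Bengio variance correction for overlapping training folds
            rho_corr = 1.0 / spec.n_folds + (1.0 / spec.n_folds) / (
                1.0 - 1.0 / spec.n_folds)
            se = (per_repeat.std(axis=1, ddof=1) * np.sqrt(rho_corr)).mean(axis=0)
        curves.append(pd.DataFrame({"alpha": alpha, "lambda": lambdas,
                                    "mean_rmse": mean_rmse, "se_rmse": se}))
        mmin = mean_rmse.min()
        alpha_rows.append({"alpha": alpha, "min_mean_rmse": mmin})
        if best is None or mmin < best[0]:
            best = (mmin, alpha, lambdas, mean_rmse, se)

    assert best is not None
    mmin, alpha_star, lambdas, mean_rmse, se = best
    i_min = int(np.argmin(mean_rmse))
    lam_min = float(lambdas[i_min])
    within = mean_rmse <= mmin + se[i_min]
    lam_1se = float(lambdas[within].max())
    return CVSelection(alpha=float(alpha_star), lambda_min=lam_min,
                       lambda_1se=lam_1se, cv_curve=pd.concat(curves,
                                                              ignore_index=True),
                       alpha_summary=pd.DataFrame(alpha_rows),
                       n_cv_repeats=spec.n_cv_repeats, n_folds=spec.n_folds)


@dataclass
class StabilityResult:
    """Bootstrap nonzero-coefficient counts and the retained marker set."""

    counts: pd.Series             # parameter -> bootstrap nonzero count
    retained: list[str]
    n_bootstrap: int
    retain_threshold: int
    alpha: float
    lambda_rule: str
    n_redrawn: int = 0

    def to_dict(self) -> dict:
        return {"counts": self.counts.to_dict(), "retained": self.retained,
                "n_bootstrap": self.n_bootstrap,
                "retain_threshold": self.retain_threshold,
                "alpha": self.alpha, "lambda_rule": self.lambda_rule,
                "n_redrawn": self.n_redrawn}


def _select_lambda_single_cv(X: np.ndarray, y: np.ndarray, alpha: float,
                             lambdas: np.ndarray, n_folds: int, rule: str,
                             rng: np.random.Generator) -> float:
    mat = _cv_rmse_matrix(X, y, alpha, lambdas, n_folds, 1, rng)
    mean_rmse = mat.mean(axis=0)
    i_min = int(np.argmin(mean_rmse))
    if rule == "min":
        return float(lambdas[i_min])
    se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    within = mean_rmse <= mean_rmse[i_min] + se[i_min]
    return float(lambdas[within].max())


def stability_select(features, age, spec: PenalizedSpec, alpha: float,
                     lambda_fixed: float | None = None,
                     rng: np.random.Generator | None = None) -> StabilityResult:
    """Bootstrap the penalized fit and count nonzero-coefficient occurrences.

    Participants are resampled with replacement (same n) ``n_bootstrap``
    times; the elastic net is refit on each resample at the fixed mixing
    ``alpha``.  By default lambda is held at ``lambda_fixed`` -- the value
    the full-data CV chose -- so the bootstrap assesses that one model;
    ``spec.bootstrap_lambda == 'reselect'`` instead re-runs a single k-fold
    CV inside every resample.
    Markers retained are those with strictly more than ``retain_threshold``
    nonzero occurrences.  Degenerate resamples (constant age) are redrawn.
    """
    spec.validate()
    names = list(features.columns) if hasattr(features, "columns") else [
        f"x{j}" for j in range(np.asarray(features).shape[1])]
    X = np.asarray(features, dtype=float)
    y = np.asarray(age, dtype=float)
    n = len(y)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.bootstrap_lambda == "fixed" and lambda_fixed is None:
        raise ValueError("bootstrap_lambda='fixed' requires lambda_fixed")

    counts = np.zeros(len(names), dtype=int)
    n_redrawn = 0
    for _ in range(spec.n_bootstrap):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.std(y[idx]) > 0:
                break
            n_redrawn += 1
            logger.warning("degenerate bootstrap resample (constant age); redrawn")
        Xb, yb = X[idx], y[idx]
        lambdas = lambda_path(Xb, yb, alpha, spec.n_lambdas, spec.lambda_min_ratio)
        if spec.bootstrap_lambda == "reselect":
            lam = _select_lambda_single_cv(Xb, yb, alpha, lambdas, spec.n_folds,
                                           spec.lambda_rule, rng)
        else:
            lam = float(lambda_fixed)  # type: ignore[arg-type]
        Zb, _, _ = _standardize(Xb)
        path = np.sort(np.append(lambdas[lambdas > lam], lam))[::-1]
        coefs = _fit_path(Zb, yb - yb.mean(), alpha, path)
        counts += coefs[:, -1] != 0.0
    series = pd.Series(counts, index=names, name="count")
    retained = [m for m in names if series[m] > spec.retain_threshold]
    return StabilityResult(counts=series, retained=retained,
                           n_bootstrap=spec.n_bootstrap,
                           retain_threshold=spec.retain_threshold,
                           alpha=alpha, lambda_rule=spec.lambda_rule,
                           n_redrawn=n_redrawn)
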