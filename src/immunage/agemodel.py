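"""Immunological age prediction: stability-selected markers, OLS final fit.

``ImmuneAgeModel`` wraps the whole model-building protocol for one group:

1. scan the elastic-net mixing grid with repeated k-fold CV and pick
   (alpha*, lambda) by the configured rule (``penalized.select_alpha_lambda``);
2. bootstrap stability selection at alpha*: keep markers with a nonzero
   coefficient in strictly more than ``retain_threshold`` resamples;
3. refit the retained markers by ordinary least squares -- the final model
   is plain linear regression on standardized markers.

``fit()`` runs 1-3 on all rows; ``tune()`` first holds out a 30% test split
(stratified by age decile), runs 1-3 on the training split only, and reports
held-out RMSE/R-squared plus permutation feature importance.  A fitted
``ImmuneAgeResults`` predicts for new participants using its stored training
standardization and never refits, so cross-group application (e.g. a
control-trained model applied to the HIV group) is a pure evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .penalized import (CVSelection, PenalizedSpec, StabilityResult,
                        select_alpha_lambda, stability_select)

__all__ = ["ImmuneAgeModel", "ImmuneAgeResults", "CombinedAgeModel",
           "fit_final", "combine_models"]


def _metrics(actual: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    resid = actual - predicted
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    tss = float(np.sum((actual - actual.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / tss if tss > 0 else float("nan")
    return {"r_squared": r2, "rmse": rmse}


def _dependent_subset(X: pd.DataFrame) -> list[str]:
    from scipy.linalg import qr
    Z = X.to_numpy(float)
    Z = Z - Z.mean(axis=0)
    rank = np.linalg.matrix_rank(Z)
    _, _, piv = qr(Z, pivoting=True, mode="economic")
    return sorted(X.columns[j] for j in piv[rank:])


@dataclass
class ImmuneAgeResults:
    """A fitted linear age model over stability-selected markers.

    Coefficients are in years per standardized unit of each marker; the
    stored center/scale come from the training data and are reused verbatim
    when predicting for new participants.
    """

    parameters: list[str]
    coefficients: pd.Series       # years per standardized unit
    intercept: float              # years
    center: pd.Series
    scale: pd.Series
    metrics: dict[str, float]     # training-data R^2 / RMSE
    group: str | None = None
    spec: PenalizedSpec | None = None
    cv: CVSelection | None = None
    stability: StabilityResult | None = None
    test_metrics: dict[str, float] | None = None   # held-out, when tuned
    importance: pd.Series | None = None            # permutation delta-RMSE
    fitted_values: pd.Series | None = None

    def predict(self, features: pd.DataFrame) -> pd.Series:
        """Predicted age (years); never refits, never re-standardizes."""
        missing = [p for p in self.parameters if p not in features.columns]
        if missing:
            raise KeyError(f"feature matrix lacks model parameters: {missing}")
        if not self.parameters:
            return pd.Series(self.intercept, index=features.index,
                             name="predicted_age")
        z = (features[self.parameters] - self.center) / self.scale
        pred = self.intercept + z.mul(self.coefficients, axis=1).sum(axis=1)
        return pred.rename("predicted_age")

    def summary(self) -> str:
        rows = pd.DataFrame({"coefficient": self.coefficients})
        if self.importance is not None:
            rows["perm_importance"] = self.importance
        lines = [
            f"Immunological age model ({self.group or 'unlabelled'} group): "
            f"{len(self.parameters)} parameters",
        ]
        if self.cv is not None:
            lines.append(f"alpha* = {self.cv.alpha:g}; "
                         f"lambda_min = {self.cv.lambda_min:.4g}; "
                         f"lambda_1se = {self.cv.lambda_1se:.4g}")
        if self.stability is not None:
            lines.append(f"stability: {len(self.stability.retained)} markers "
                         f"retained (> {self.stability.retain_threshold} of "
                         f"{self.stability.n_bootstrap} bootstraps)")
        lines.append(f"train R^2 = {self.metrics['r_squared']:.4f}, "
                     f"RMSE = {self.metrics['rmse']:.3f} yrs")
        if self.test_metrics is not None:
            lines.append(f"test  R^2 = {self.test_metrics['r_squared']:.4f}, "
                         f"RMSE = {self.test_metrics['rmse']:.3f} yrs")
        lines.append(f"intercept = {self.intercept:.3f} yrs")
        lines.append(rows.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "parameters": self.parameters,
            "coefficients": self.coefficients.to_dict(),
            "intercept": self.intercept,
            "center": self.center.to_dict(),
            "scale": self.scale.to_dict(),
            "metrics": self.metrics,
            "test_metrics": self.test_metrics,
            "group": self.group,
            "spec": None if self.spec is None else {
                "alpha_grid": list(self.spec.alpha_grid),
                "n_cv_repeats": self.spec.n_cv_repeats,
                "n_folds": self.spec.n_folds,
                "lambda_rule": self.spec.lambda_rule,
                "n_bootstrap": self.spec.n_bootstrap,
                "retain_threshold": self.spec.retain_threshold,
                "train_fraction": self.spec.train_fraction,
                "seed": self.spec.seed,
            },
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ImmuneAgeResults":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        p = d["parameters"]
        spec = None
        if d.get("spec"):
            s = d["spec"]
            spec = PenalizedSpec(alpha_grid=tuple(s["alpha_grid"]),
                                 n_cv_repeats=s["n_cv_repeats"],
                                 n_folds=s["n_folds"],
                                 lambda_rule=s["lambda_rule"],
                                 n_bootstrap=s["n_bootstrap"],
                                 retain_threshold=s["retain_threshold"],
                                 train_fraction=s["train_fraction"],
                                 seed=s["seed"])
        return cls(parameters=p,
                   coefficients=pd.Series(d["coefficients"]).reindex(p),
                   intercept=float(d["intercept"]),
                   center=pd.Series(d["center"]).reindex(p),
                   scale=pd.Series(d["scale"]).reindex(p),
                   metrics=d["metrics"], test_metrics=d.get("test_metrics"),
                   group=d.get("group"), spec=spec)


def fit_final(features: pd.DataFrame, age, group: str | None = None,
              allow_empty: bool = False) -> ImmuneAgeResults:
    """Ordinary least squares of age on standardized retained markers."""
    y = np.asarray(age, dtype=float)
    params = list(features.columns)
    if not params:
        if not allow_empty:
            raise ValueError("retained marker set is empty")
        mean_age = float(y.mean())
        res = ImmuneAgeResults(parameters=[], coefficients=pd.Series(dtype=float),
                               intercept=mean_age,
                               center=pd.Series(dtype=float),
                               scale=pd.Series(dtype=float),
                               metrics=_metrics(y, np.full_like(y, mean_age)),
                               group=group)
        return res
    if len(y) <= len(params) + 1:
        raise ValueError(f"need n > p + 1; got n={len(y)}, p={len(params)}")
    center = features.mean()
    scale = features.std(ddof=0)
    if (scale == 0).any():
        raise ValueError("zero-variance marker(s): "
                         f"{scale.index[scale == 0].tolist()}")
    Z = ((features - center) / scale).to_numpy(float)
    if np.linalg.matrix_rank(Z - Z.mean(axis=0)) < Z.shape[1]:
        raise ValueError("collinear retained markers; dependent subset: "
                         f"{_dependent_subset(features)}")
    ols = sm.OLS(y, sm.add_constant(Z)).fit()
    pred = np.asarray(ols.fittedvalues)
    res = ImmuneAgeResults(
        parameters=params,
        coefficients=pd.Series(ols.params[1:], index=params, name="coef"),
        intercept=float(ols.params[0]),
        center=center, scale=scale,
        metrics=_metrics(y, pred),
        group=group,
    )
    res.fitted_values = pd.Series(pred, index=features.index,
                                  name="predicted_age")
    return res


def _stratified_split(age: np.ndarray, train_fraction: float,
                      rng: np.random.Generator):
    """70/30-style split stratified by age decile (fewer bins at small n)."""
    n = len(age)
    n_bins = int(np.clip(n // 10, 2, 10))
    q = pd.qcut(pd.Series(age), q=n_bins, labels=False, duplicates="drop")
    train_idx, test_idx = [], []
    for _, members in pd.Series(np.arange(n)).groupby(q.to_numpy()):
        m = members.to_numpy()
        rng.shuffle(m)
        k = int(round(train_fraction * len(m)))
        k = min(max(k, 1), len(m) - 1) if len(m) > 1 else len(m)
        train_idx.extend(m[:k])
        test_idx.extend(m[k:])
    return np.sort(train_idx), np.sort(test_idx)


def _permutation_importance(results: ImmuneAgeResults, features: pd.DataFrame,
                            age: np.ndarray, k: int,
                            rng: np.random.Generator) -> pd.Series:
    base = _metrics(age, results.predict(features).to_numpy())["rmse"]
    out = {}
    for p in results.parameters:
        deltas = np.empty(k)
        for i in range(k):
            shuffled = features.copy()
            shuffled[p] = rng.permutation(shuffled[p].to_numpy())
            deltas[i] = _metrics(age, results.predict(shuffled).to_numpy())["rmse"] - base
        out[p] = deltas.mean()
    return pd.Series(out, name="perm_importance")


class ImmuneAgeModel:
    """Build an age-prediction model for one participant group.

    Parameters
    ----------
    features : DataFrame (participants x markers), typically pre-filtered to
        markers significant in the age-association screen.
    age : chronological ages (years), aligned to rows.
    spec : PenalizedSpec tuning protocol.
    group : label recorded as provenance (e.g. "HC").
    """

    def __init__(self, features: pd.DataFrame, age,
                 spec: PenalizedSpec | None = None, group: str | None = None):
        self.features = features
        self.age = np.asarray(age, dtype=float)
        self.spec = spec or PenalizedSpec()
        self.group = group
        if len(self.age) != len(features):
            raise ValueError("age must align with feature rows")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, age_col: str = "age",
                       drop: tuple[str, ...] = ("id", "group", "stratum"),
                       **kw) -> "ImmuneAgeModel":
        cols = [c for c in frame.columns if c != age_col and c not in drop]
        return cls(frame[cols], frame[age_col], **kw)

    # -- stages ---------------------------------------------------------
    def _select_and_stabilize(self, features, age, rng):
        cv = select_alpha_lambda(features, age, self.spec, rng)
        lam = cv.lambda_for(self.spec.lambda_rule)
        stab = stability_select(features, age, self.spec, cv.alpha,
                                lambda_fixed=lam, rng=rng)
        return cv, stab

    def _final_panel(self, features, age, cv, stab) -> list[str]:
        """Stability candidates, reduced to an OLS-estimable final panel.

        When the candidate set is dense (as happens when CV favours a
        ridge-ward mixing, where nonzero counts saturate), the model is
        tuned down to the markers with the largest penalized-fit
        coefficients at (alpha*, lambda); ties broken by bootstrap count,
        then name.
        """
        retained = list(stab.retained)
        cap = self.spec.max_final_params
        if cap is None:
            cap = max(2, len(age) // 5)
        if len(retained) <= cap:
            return retained
        lam = cv.lambda_for(self.spec.lambda_rule)
        from .penalized import penalized_path
        _, coefs = penalized_path(features[retained], age, cv.alpha,
                                  lambdas=np.array([lam]))
        rank = sorted(
            range(len(retained)),
            key=lambda j: (-abs(coefs[j, 0]),
                           -stab.counts[retained[j]], retained[j]))
        return [retained[j] for j in rank[:cap]]

    def fit(self) -> ImmuneAgeResults:
        """Run selection + stability + OLS on all rows (no held-out split)."""
        rng = np.random.default_rng(self.spec.seed)
        cv, stab = self._select_and_stabilize(self.features, self.age, rng)
        panel = self._final_panel(self.features, self.age, cv, stab)
        res = fit_final(self.features[panel], self.age, group=self.group)
        res.spec, res.cv, res.stability = self.spec, cv, stab
        return res

    def tune(self, importance_permutations: int = 20) -> ImmuneAgeResults:
        """Hold out a test split, build on train only, evaluate held-out.

        Reports test RMSE/R-squared and permutation feature importance
        (mean increase in test RMSE over ``importance_permutations``
        shuffles of each retained column).
        """
        rng = np.random.default_rng(self.spec.seed)
        tr, te = _stratified_split(self.age, self.spec.train_fraction, rng)
        if len(te) < 5:
            raise ValueError(f"test split too small (n={len(te)} < 5)")
        Xtr = self.features.iloc[tr]
        Xte = self.features.iloc[te]
        ytr, yte = self.age[tr], self.age[te]
        cv, stab = self._select_and_stabilize(Xtr, ytr, rng)
        panel = self._final_panel(Xtr, ytr, cv, stab)
        res = fit_final(Xtr[panel], ytr, group=self.group)
        res.spec, res.cv, res.stability = self.spec, cv, stab
        res.test_metrics = _metrics(yte, res.predict(Xte).to_numpy())
        res.importance = _permutation_importance(res, Xte, yte,
                                                 importance_permutations, rng)
        return res


@dataclass
class CombinedAgeModel:
    """Union-of-parameters model with group-specific coefficient sets.

    Merging a control-trained and a case-trained marker set (a's order, then
    b's novel markers) and refitting OLS per group yields one signature with
    two coefficient vectors -- the combined immunological-age signature.
    """

    parameters: list[str]
    per_group: dict[str, ImmuneAgeResults]

    @property
    def union_size(self) -> int:
        return len(self.parameters)

    def predict(self, features: pd.DataFrame, group: str) -> pd.Series:
        if group not in self.per_group:
            raise KeyError(f"no coefficient set for group {group!r}; have "
                           f"{sorted(self.per_group)}")
        return self.per_group[group].predict(features)

    def summary(self) -> str:
        coefs = pd.DataFrame({g: r.coefficients for g, r in self.per_group.items()})
        lines = [f"Combined age model: {self.union_size} parameters, "
                 f"groups {sorted(self.per_group)}"]
        for g, r in self.per_group.items():
            lines.append(f"  {g}: R^2 = {r.metrics['r_squared']:.4f}, "
                         f"RMSE = {r.metrics['rmse']:.3f} yrs")
        lines.append(coefs.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


def combine_models(model_a: ImmuneAgeResults, model_b: ImmuneAgeResults,
                   features_by_group: dict[str, pd.DataFrame],
                   ages_by_group: dict[str, np.ndarray]) -> CombinedAgeModel:
    """Union the two parameter sets and refit OLS separately per group."""
    union = list(model_a.parameters) + [p for p in model_b.parameters
                                        if p not in model_a.parameters]
    n_min = min(len(a) for a in ages_by_group.values())
    if len(union) > n_min - 2:
        raise ValueError(
            f"union of {len(union)} parameters is not estimable with the "
            f"smaller group's n={n_min}; consider a regularized refit")
    per_group = {}
    for g, feats in features_by_group.items():
        missing = [p for p in union if p not in feats.columns]
        if missing:
            raise KeyError(f"group {g!r} lacks parameters: {missing}")
        per_group[g] = fit_final(feats[union], ages_by_group[g], group=g)
    return CombinedAgeModel(parameters=union, per_group=per_group)
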