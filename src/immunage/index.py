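"""Inflammatory Index: PC1-weighted composite of age-selected plasma markers.

The index is built in two stages.  First, backward stepwise regression of age
on the candidate plasma markers (AIC by default; a drop-while-max-p variant
and a lasso variant are available) picks the markers most associated with
age.  Second, the selected markers are standardized and the loadings of the
first principal component of the standardized matrix become the weights:

    index_p = sign * sum_i w_i * (x_pi - center_i) / scale_i

with the orientation ``sign`` fixed so the index correlates non-negatively
with age on the fitting data.  Standardization constants are computed on the
pooled cohort so the index remains comparable across groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LassoCV

__all__ = ["backward_stepwise_select", "InflammatoryIndex",
           "InflammatoryIndexResults", "contrast_index_by_group", "GroupContrast"]


def _aic(age: np.ndarray, X: np.ndarray) -> float:
    """AIC of the Gaussian linear model age ~ X (plus intercept).

    n*log(RSS/n) + 2*(k+1); constant offsets cancel in comparisons.
    """
    n = len(age)
    fit = sm.OLS(age, sm.add_constant(X) if X.shape[1] else np.ones((n, 1))).fit()
    return n * np.log(fit.ssr / n) + 2 * (X.shape[1] + 1)


def _check_full_rank(plasma: pd.DataFrame) -> None:
    X = plasma.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < X.shape[1]:
        # name a dependent subset via pivoted QR
        from scipy.linalg import qr as scipy_qr
        _, _, piv = scipy_qr(Xc, pivoting=True, mode="economic")
        dep = [plasma.columns[j] for j in piv[rank:]]
        raise ValueError(f"collinear plasma markers (singular design): {sorted(dep)}")


def backward_stepwise_select(plasma: pd.DataFrame, age,
                             criterion: str = "aic",
                             p_threshold: float = 0.157) -> list[str]:
    """Backward elimination of plasma markers in the model age ~ markers.

    criterion='aic': from the full model, repeatedly drop the marker whose
    removal lowers AIC the most, until no removal lowers it.
    criterion='pvalue': drop the largest-p marker while max p > p_threshold.

    Returns surviving marker names in input column order.
    """
    age = np.asarray(age, dtype=float)
    if plasma.shape[1] < 2:
        raise ValueError("need at least 2 candidate markers")
    if plasma.isna().to_numpy().any():
        raise ValueError("plasma matrix must not contain missing values")
    if len(age) != len(plasma):
        raise ValueError("age must align with plasma rows")
    _check_full_rank(plasma)

    current = list(plasma.columns)
    if criterion == "aic":
        best = _aic(age, plasma[current].to_numpy(float))
        while len(current) > 1:
            drops = [(_aic(age, plasma[[m for m in current if m != c]].to_numpy(float)), c)
                     for c in current]
            cand_aic, cand = min(drops, key=lambda t: (t[0], t[1]))
            if cand_aic < best:
                best = cand_aic
                current.remove(cand)
            else:
                break
    elif criterion == "pvalue":
        while len(current) > 1:
            fit = sm.OLS(age, sm.add_constant(plasma[current].to_numpy(float))).fit()
            pvals = pd.Series(fit.pvalues[1:], index=current)
            worst = pvals.idxmax()
            if pvals[worst] > p_threshold:
                current.remove(worst)
            else:
                break
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    if not current:
        raise ValueError("no markers survive elimination; relax the criterion")
    return [c for c in plasma.columns if c in current]


def _lasso_select(plasma: pd.DataFrame, age, seed: int = 0) -> list[str]:
    z = (plasma - plasma.mean()) / plasma.std(ddof=0)
    fit = LassoCV(cv=10, random_state=seed).fit(z.to_numpy(float),
                                                np.asarray(age, float))
    keep = [c for c, b in zip(plasma.columns, fit.coef_) if b != 0.0]
    if not keep:
        raise ValueError("lasso eliminated every marker; relax the criterion")
    return keep


@dataclass
class GroupContrast:
    """Welch two-sample comparison of a score between two groups."""

    labels: tuple[str, str]
    means: tuple[float, float]
    difference: float          # mean(second) - mean(first)
    statistic: float
    p: float
    n: tuple[int, int]

    def to_dict(self) -> dict:
        return {"labels": list(self.labels), "means": list(self.means),
                "difference": self.difference, "statistic": self.statistic,
                "p": self.p, "n": list(self.n)}


def contrast_index_by_group(scores, groups) -> GroupContrast:
    """Welch two-sided t-test of per-participant scores between two groups."""
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required; got {labels}")
    a = scores[groups == labels[0]]
    b = scores[groups == labels[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs n >= 2")
    if np.allclose(a.mean(), b.mean()) and a.std() == 0 and b.std() == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_ind(b, a, equal_var=False)
    return GroupContrast(labels=(labels[0], labels[1]),
                         means=(float(a.mean()), float(b.mean())),
                         difference=float(b.mean() - a.mean()),
                         statistic=float(stat), p=float(p),
                         n=(len(a), len(b)))


@dataclass
class InflammatoryIndexResults:
    """Fitted index: selected markers, standardization constants, PC1 weights."""

    markers: list[str]
    center: pd.Series
    scale: pd.Series
    weights: pd.Series
    sign: int
    selection: str
    fitted_scores: pd.Series | None = None

    def score(self, plasma: pd.DataFrame) -> pd.Series:
        """Apply the stored index to (possibly new) participants.

        Uses the stored center/scale; never refits.
        """
        missing = [m for m in self.markers if m not in plasma.columns]
        if missing:
            raise KeyError(f"plasma matrix lacks index markers: {missing}")
        z = (plasma[self.markers] - self.center) / self.scale
        return self.sign * z.mul(self.weights, axis=1).sum(axis=1).rename("index")

    def contrast(self, plasma: pd.DataFrame, groups) -> GroupContrast:
        return contrast_index_by_group(self.score(plasma), groups)

    def summary(self) -> str:
        tab = pd.DataFrame({"weight": self.weights, "center": self.center,
                            "scale": self.scale}).loc[self.markers]
        lines = ["Inflammatory Index (PC1-weighted standardized plasma markers)",
                 f"selection: {self.selection}; markers: {len(self.markers)}; "
                 f"orientation sign: {self.sign:+d}",
                 tab.to_string(float_format=lambda v: f"{v: .4f}")]
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"markers": self.markers,
                   "center": self.center.to_dict(),
                   "scale": self.scale.to_dict(),
                   "weights": self.weights.to_dict(),
                   "sign": self.sign, "selection": self.selection}
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "InflammatoryIndexResults":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        m = d["markers"]
        return cls(markers=m,
                   center=pd.Series(d["center"]).loc[m],
                   scale=pd.Series(d["scale"]).loc[m],
                   weights=pd.Series(d["weights"]).loc[m],
                   sign=int(d["sign"]), selection=d.get("selection", "stepwise"))


class InflammatoryIndex:
    """Model object: select plasma markers on age, weight them by PC1.

    Parameters
    ----------
    plasma : DataFrame of candidate plasma markers (participants x markers).
    age : chronological ages in years, aligned to rows.
    selection : 'stepwise' (backward AIC, default), 'pvalue', 'lasso', or
        'none' (use all provided markers).
    """

    def __init__(self, plasma: pd.DataFrame, age, selection: str = "stepwise",
                 p_threshold: float = 0.157, seed: int = 0):
        keep = ~plasma.isna().any(axis=1)   # complete-case rows
        self.plasma = plasma.loc[keep]
        self.age = np.asarray(age, dtype=float)[np.asarray(keep)]
        self.selection = selection
        self.p_threshold = p_threshold
        self.seed = seed
        if len(self.plasma) < 3:
            raise ValueError("need at least 3 complete-case participants")

    def fit(self) -> InflammatoryIndexResults:
        if self.selection == "stepwise":
            markers = backward_stepwise_select(self.plasma, self.age, "aic")
        elif self.selection == "pvalue":
            markers = backward_stepwise_select(self.plasma, self.age, "pvalue",
                                               self.p_threshold)
        elif self.selection == "lasso":
            markers = _lasso_select(self.plasma, self.age, self.seed)
        elif self.selection == "none":
            markers = list(self.plasma.columns)
        else:
            raise ValueError(f"unknown selection {self.selection!r}")

        sel = self.plasma[markers]
        center = sel.mean()
        scale = sel.std(ddof=0)
        dead = scale.index[scale == 0].tolist()
        if dead:
            raise ValueError(f"zero-variance marker(s): {dead}")
        z = ((sel - center) / scale).to_numpy(float)
        # first principal axis of the standardized matrix (unit-norm loadings)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        w = vt[0]
        scores = z @ w
        sgn = 1
        if stats.spearmanr(scores, self.age).statistic < 0:
            sgn = -1
        res = InflammatoryIndexResults(
            markers=markers, center=center, scale=scale,
            weights=pd.Series(w, index=markers, name="weight"),
            sign=sgn, selection=self.selection)
        res.fitted_scores = pd.Series(sgn * scores, index=self.plasma.index,
                                      name="index")
        return res
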