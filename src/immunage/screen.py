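"""Rank-correlation screen of immune parameters against chronological age.

Every parameter is tested for Spearman correlation with age within a group
(two-sided t-approximation, average ranks for ties).  Significance defaults
to raw p < alpha, matching common practice in immune-phenotyping screens;
Benjamini-Hochberg adjustment is available behind a flag.  Cross-group
results are partitioned into shared / same-direction / opposite-direction /
group-exclusive significant sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["spearman_screen", "top_parameters", "classify_overlap",
           "OverlapClassification"]


def spearman_screen(features: pd.DataFrame, age, alpha: float = 0.05,
                    group: str | None = None,
                    bh_adjust: bool = False) -> pd.DataFrame:
    """Spearman rho and two-sided p for each column of ``features`` vs age.

    Returns a DataFrame with one row per parameter: parameter, group, rho, p,
    significant, direction.  Constant columns get rho = NaN and are never
    significant.  No multiplicity adjustment unless ``bh_adjust``.
    """
    age = np.asarray(age, dtype=float)
    if len(age) != len(features):
        raise ValueError("age must align with feature rows")
    if len(age) < 4:
        raise ValueError("need n >= 4 participants for the screen")
    if features.isna().to_numpy().any():
        raise ValueError("screened columns must not contain missing values")

    X = features.to_numpy(dtype=float)
    constant = X.std(axis=0) == 0
    # vectorized: Pearson on average ranks, identical to per-column spearmanr
    rx = stats.rankdata(X, axis=0)
    ry = stats.rankdata(age)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum(axis=0) * (ry ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx * ry[:, None]).sum(axis=0) / denom
    rho[constant] = np.nan

    n = len(age)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[constant] = np.nan

    p_eff = p.copy()
    if bh_adjust:
        ok = ~np.isnan(p)
        adj = np.full_like(p, np.nan)
        if ok.any():
            adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        p_eff = adj

    significant = np.where(np.isnan(p_eff), False, p_eff < alpha)
    direction = np.where(np.isnan(rho), "undefined",
                         np.where(rho >= 0, "positive", "negative"))
    return pd.DataFrame({
        "parameter": features.columns,
        "group": group,
        "rho": rho,
        "p": p,
        "significant": significant.astype(bool),
        "direction": direction,
    })


def top_parameters(records: pd.DataFrame, rho_threshold: float = 0.4) -> pd.DataFrame:
    """Significant records with |rho| strictly above the threshold.

    Sorted by |rho| descending, ties broken by parameter name.
    """
    if not 0.0 <= rho_threshold < 1.0:
        raise ValueError(f"rho_threshold must be in [0, 1); got {rho_threshold}")
    keep = records[records["significant"]
                   & (records["rho"].abs() > rho_threshold)].copy()
    keep["_mag"] = keep["rho"].abs()
    keep = keep.sort_values(["_mag", "parameter"], ascending=[False, True],
                            kind="mergesort").drop(columns="_mag")
    return keep.reset_index(drop=True)


@dataclass
class OverlapClassification:
    """Cross-group partition of significant age-associated parameters."""

    shared: set[str]
    same_direction: set[str]
    opposite_direction: set[str]
    a_only: set[str]
    b_only: set[str]
    labels: tuple[str, str] = ("A", "B")

    def counts(self) -> dict[str, int]:
        a, b = self.labels
        return {
            f"significant_{a}": len(self.a_only) + len(self.shared),
            f"significant_{b}": len(self.b_only) + len(self.shared),
            "shared": len(self.shared),
            "same_direction": len(self.same_direction),
            "opposite_direction": len(self.opposite_direction),
            f"{a}_only": len(self.a_only),
            f"{b}_only": len(self.b_only),
        }

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "shared": sorted(self.shared),
            "same_direction": sorted(self.same_direction),
            "opposite_direction": sorted(self.opposite_direction),
            "a_only": sorted(self.a_only),
            "b_only": sorted(self.b_only),
            "counts": self.counts(),
        }


def classify_overlap(records_a: pd.DataFrame,
                     records_b: pd.DataFrame) -> OverlapClassification:
    """Partition significant parameters of two group screens.

    shared = significant in both; split into same/opposite direction by the
    sign product of the two rhos.  Both screens must cover the same universe.
    """
    pa = set(records_a["parameter"])
    pb = set(records_b["parameter"])
    if pa != pb:
        asym = sorted(pa.symmetric_difference(pb))
        raise ValueError(f"parameter universes differ; asymmetric names: {asym[:20]}")

    a = records_a.set_index("parameter")
    b = records_b.set_index("parameter")
    sig_a = set(a.index[a["significant"]])
    sig_b = set(b.index[b["significant"]])
    shared = sig_a & sig_b
    same = {p for p in shared
            if np.sign(a.at[p, "rho"]) * np.sign(b.at[p, "rho"]) > 0}
    labels = (records_a["group"].iloc[0] if len(records_a) else "A",
              records_b["group"].iloc[0] if len(records_b) else "B")
    labels = tuple("AB"[i] if lab is None else str(lab)
                   for i, lab in enumerate(labels))
    return OverlapClassification(
        shared=shared,
        same_direction=same,
        opposite_direction=shared - same,
        a_only=sig_a - shared,
        b_only=sig_b - shared,
        labels=labels,  # type: ignore[arg-type]
    )
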