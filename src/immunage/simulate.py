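"""Synthetic immune-aging cohorts with planted, recoverable structure.

Generates a two-group participant table (e.g. HIV-negative controls vs
ART-treated people living with HIV) together with a wide numeric feature
matrix that mimics the statistical structure of a combined flow-cytometry /
plasma-biomarker panel:

* planted age-correlated features -- shared between groups, exclusive to one
  group, or correlated in opposite directions -- at a configurable target
  Spearman correlation with chronological age;
* a plasma block driven by a single latent inflammatory factor that rises
  with age and can be shifted additively in the case group;
* an aging-rate multiplier that inflates the latent immunological age of the
  case group inside one age stratum, so that downstream rate contrasts have
  a known truth;
* pure-noise filler features for null calibration.

Every draw is reproducible from the single config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SimulationConfig", "SyntheticCohort", "generate_cohort", "write_cohort"]

#: age-stratum boundaries in years: Young < 40 <= Middle < 60 <= Old
STRATUM_EDGES = (40.0, 60.0)
STRATA = ("Young", "Middle", "Old")


class ConfigError(ValueError):
    """A SimulationConfig field violates its invariant."""


def assign_stratum(age) -> np.ndarray:
    """Map ages (years) to Young/Middle/Old with half-open bins [40, 60)."""
    age = np.asarray(age, dtype=float)
    out = np.where(age < STRATUM_EDGES[0], "Young",
                   np.where(age < STRATUM_EDGES[1], "Middle", "Old"))
    return out.astype(object)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-structure defaults: ~209 participants, 1,357 parameters.

    Planted counts default to the shared / group-exclusive / opposite-direction
    partition implied by a 277-vs-491 significant screen with 113 overlapping
    parameters of which 78 agree in direction.
    """

    n_per_group: int = 104
    n_features: int = 1357
    n_shared_age: int = 78
    n_groupA_only: int = 164
    n_groupB_only: int = 378
    n_opposite: int = 35
    effect_rho: float = 0.3
    #: optional (lo, hi) per-feature spread of planted |rho| values; when set,
    #: planted features span the range instead of sitting at effect_rho,
    #: emulating the spectrum of weak-to-moderate age correlates seen in
    #: immune-phenotyping panels
    effect_rho_range: tuple[float, float] | None = None
    n_plasma: int = 26
    inflammatory_loading: float = 0.8
    group_index_shift: float = 0.5
    aging_rate_multiplier: float = 1.18
    rate_stratum: str = "Young"
    noise_sd: float = 1.0
    age_range: tuple[float, float] = (19.0, 77.0)
    group_labels: tuple[str, str] = ("HC", "HIV")
    #: optional per-group (Young, Middle, Old) counts; overrides n_per_group
    stratum_counts: tuple[int, int, int] | None = None
    seed: int = 0
    #: SD of the inflammatory factor's age-independent component
    factor_noise_sd: float = field(default=1.5, repr=False)

    def validate(self) -> None:
        planted = (self.n_shared_age + self.n_groupA_only
                   + self.n_groupB_only + self.n_opposite)
        if planted + self.n_plasma > self.n_features:
            raise ConfigError(
                "n_shared_age + n_groupA_only + n_groupB_only + n_opposite "
                f"+ n_plasma = {planted + self.n_plasma} exceeds n_features="
                f"{self.n_features}")
        if not 0.0 < self.effect_rho <= 1.0:
            raise ConfigError(f"effect_rho must be in (0, 1]; got {self.effect_rho}")
        if self.effect_rho_range is not None:
            lo, hi = self.effect_rho_range
            if not 0.0 < lo <= hi <= 1.0:
                raise ConfigError("effect_rho_range must satisfy 0 < lo <= hi "
                                  f"<= 1; got {self.effect_rho_range}")
        if self.aging_rate_multiplier <= 0:
            raise ConfigError("aging_rate_multiplier must be > 0; got "
                              f"{self.aging_rate_multiplier}")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigError(f"age_range min must be < max; got {self.age_range}")
        if self.age_range[0] <= 0:
            raise ConfigError("age_range must be positive (ages in years); got "
                              f"{self.age_range}")
        if self.n_per_group < 3 and self.stratum_counts is None:
            raise ConfigError(f"n_per_group must be >= 3; got {self.n_per_group}")
        if self.rate_stratum not in STRATA:
            raise ConfigError(f"rate_stratum must be one of {STRATA}; got "
                              f"{self.rate_stratum!r}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0; got {self.noise_sd}")
        if len(set(self.group_labels)) != 2:
            raise ConfigError("group_labels must be two distinct labels; got "
                              f"{self.group_labels}")


@dataclass
class SyntheticCohort:
    """A generated cohort: participant table, features, and planted truth."""

    cohort: pd.DataFrame          # id, age, group, stratum
    features: pd.DataFrame        # participants x parameters, indexed by id
    truth: dict[str, dict]        # planted feature -> {direction, specificity, effect_rho}
    latent_age: pd.Series         # per-participant latent immunological age
    classes: pd.Series            # parameter -> {flow, plasma, serology}
    plasma_loadings: pd.Series    # plasma marker -> planted factor loading
    config: SimulationConfig

    @property
    def plasma(self) -> pd.DataFrame:
        return self.features.loc[:, self.classes[self.classes == "plasma"].index]

    def group_mask(self, label: str) -> np.ndarray:
        return (self.cohort["group"] == label).to_numpy()


@lru_cache(maxsize=64)
def _calibrate_noise_sd(rho: float, age_range: tuple[float, float],
                        n_ref: int = 20000) -> float:
    """Noise SD giving Spearman(age, age + noise) ~= rho for uniform ages.

    The target is rank-based, so the mapping from noise scale to correlation
    is found by bisection on a large fixed reference sample rather than a
    parametric formula.
    """
    if rho >= 1.0:
        return 0.0
    rng = np.random.default_rng(20211011)  # fixed: calibration is a pure lookup
    ages = rng.uniform(*age_range, size=n_ref)
    noise = rng.standard_normal(n_ref)

    def rho_at(s: float) -> float:
        return stats.spearmanr(ages, ages + s * noise).statistic

    lo, hi = 0.0, np.ptp(ages)
    while rho_at(hi) > rho:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if rho_at(mid) > rho:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _planted_column(latent: np.ndarray, direction: int, noise_sd: float,
                    rng: np.random.Generator) -> np.ndarray:
    return direction * latent + noise_sd * rng.standard_normal(latent.size)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort under ``config``; bit-identical for identical configs."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_age, ss_plant, ss_plasma, ss_noise = root.spawn(4)
    rng_age = np.random.default_rng(ss_age)
    rng_plant = np.random.default_rng(ss_plant)
    rng_plasma = np.random.default_rng(ss_plasma)
    rng_noise = np.random.default_rng(ss_noise)

    label_a, label_b = config.group_labels
    lo, hi = config.age_range
    ages_per_group = []
    if config.stratum_counts is None:
        for _ in range(2):
            ages_per_group.append(rng_age.uniform(lo, hi, size=config.n_per_group))
    else:
        edges = [lo, min(STRATUM_EDGES[0], hi), min(STRATUM_EDGES[1], hi), hi]
        for _ in range(2):
            parts = [rng_age.uniform(edges[k], edges[k + 1], size=c)
                     for k, c in enumerate(config.stratum_counts)]
            ages_per_group.append(np.concatenate(parts))

    age = np.concatenate(ages_per_group)
    n = age.size
    group = np.array([label_a] * ages_per_group[0].size
                     + [label_b] * ages_per_group[1].size, dtype=object)
    ids = np.array([f"P{i + 1:04d}" for i in range(n)])
    stratum = assign_stratum(age)

    # latent immunological age: case-group participants inside the flagged
    # stratum age faster by the configured multiplier
    flagged = (group == label_b) & (stratum == config.rate_stratum)
    latent = np.where(flagged, age * config.aging_rate_multiplier, age)

    is_a = group == label_a
    is_b = ~is_a
    sig_mu = float(np.mean(latent))

    def rho_profile(count: int) -> np.ndarray:
        """Per-feature |rho| targets; a descending spread when configured."""
        if config.effect_rho_range is None:
            return np.full(count, config.effect_rho)
        lo, hi = config.effect_rho_range
        # snap to a coarse grid so noise calibration is cached per level
        return np.round(np.linspace(hi, lo, num=count) / 0.025) * 0.025

    cols: dict[str, np.ndarray] = {}
    classes: dict[str, str] = {}
    truth: dict[str, dict] = {}

    # ---- plasma block: one inflammatory common factor ----
    z_age = (age - np.mean(age)) / (np.std(age) or 1.0)
    factor = z_age + config.factor_noise_sd * rng_plasma.standard_normal(n)
    factor = factor + np.where(is_b, config.group_index_shift, 0.0)
    loadings = np.linspace(config.inflammatory_loading,
                           0.5 * config.inflammatory_loading,
                           num=config.n_plasma)
    plasma_names = [f"plasma_{j + 1:02d}" for j in range(config.n_plasma)]
    for name, lam in zip(plasma_names, loadings):
        resid = config.noise_sd * np.sqrt(max(0.0, 1.0 - min(lam, 1.0) ** 2))
        cols[name] = lam * factor + resid * rng_plasma.standard_normal(n)
        classes[name] = "plasma"

    # ---- planted age-correlated flow parameters ----
    def plant(count: int, tag: str, prefix: str) -> None:
        rhos = rho_profile(count)
        for j in range(count):
            name = f"{prefix}_{j + 1:03d}"
            direction = 1 if j % 2 == 0 else -1
            cal_sd = _calibrate_noise_sd(float(rhos[j]), config.age_range)
            col = np.empty(n)
            if tag == "shared":
                col[:] = _planted_column(latent, direction, cal_sd, rng_plant)
            elif tag == "opposite":
                col[is_a] = _planted_column(latent[is_a], direction, cal_sd, rng_plant)
                col[is_b] = _planted_column(latent[is_b], -direction, cal_sd, rng_plant)
            else:
                on = is_a if tag == "A" else is_b
                # silent-group noise is mean/variance matched to the signal
                sig_sd = float(np.sqrt(np.var(latent) + cal_sd ** 2))
                col[on] = _planted_column(latent[on], direction, cal_sd, rng_plant)
                col[~on] = sig_mu * direction + sig_sd * rng_plant.standard_normal(int(np.sum(~on)))
            cols[name] = col
            classes[name] = "flow"
            truth[name] = {"direction": direction, "specificity": tag,
                           "effect_rho": float(rhos[j])}

    plant(config.n_shared_age, "shared", "flow_shared")
    plant(config.n_groupA_only, "A", "flow_aonly")
    plant(config.n_groupB_only, "B", "flow_bonly")
    plant(config.n_opposite, "opposite", "flow_opp")

    # ---- filler noise parameters (one tagged serology, e.g. an IgG titer) ----
    filler_sd = float(np.sqrt(
        np.var(latent)
        + _calibrate_noise_sd(config.effect_rho, config.age_range) ** 2))
    n_filler = config.n_features - len(cols)
    for j in range(n_filler):
        if j == 0:
            name, cls = "serology_igg_titer", "serology"
        else:
            name, cls = f"flow_noise_{j:04d}", "flow"
        cols[name] = sig_mu + filler_sd * rng_noise.standard_normal(n)
        classes[name] = cls

    features = pd.DataFrame(cols, index=pd.Index(ids, name="id"))
    cohort = pd.DataFrame({"id": ids, "age": age, "group": group,
                           "stratum": stratum})
    return SyntheticCohort(
        cohort=cohort,
        features=features,
        truth=truth,
        latent_age=pd.Series(latent, index=features.index, name="latent_age"),
        classes=pd.Series(classes, name="class"),
        plasma_loadings=pd.Series(loadings, index=plasma_names, name="loading"),
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, str]:
    """Write one TSV (id, age, group, features...) plus the truth ledger JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = cohort.cohort.set_index("id")[["age", "group"]].join(cohort.features)
    tsv = outdir / "cohort.tsv"
    table.to_csv(tsv, sep="\t", float_format="%.10g")
    truth_path = outdir / "truth.json"
    payload = {
        "planted": cohort.truth,
        "plasma_loadings": cohort.plasma_loadings.round(10).to_dict(),
        "classes": cohort.classes.to_dict(),
        "latent_age": {k: round(v, 10) for k, v in cohort.latent_age.items()},
    }
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return {"cohort": str(tsv), "truth": str(truth_path)}
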