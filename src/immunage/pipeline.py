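"""End-to-end pipeline: simulate/load -> index -> screen -> models -> rates.

``run_pipeline`` executes the full analysis in the order the stages build on
each other: the inflammatory index on the plasma block, the per-group
age-association screen with cross-group overlap classification, per-group
penalized age models with bootstrap stability selection and 70/30 tuning,
cross-group application, the combined union-signature model, and per-stratum
aging-rate contrasts.  All artifacts are plain TSV/JSON under the output
directory and a manifest records counts, metrics and artifact paths.

The manifest is byte-reproducible for a fixed config and seed; wall-clock
timings go to the run log only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agemodel import ImmuneAgeModel, combine_models
from .index import InflammatoryIndex
from .penalized import PenalizedSpec
from .rates import compute_rates, contrast_strata
from .screen import classify_overlap, spearman_screen, top_parameters
from .simulate import SimulationConfig, SyntheticCohort, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_cohort_table"]


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source, thresholds, seed."""

    input_path: str | None = None
    simulate: SimulationConfig | None = None
    screen_alpha: float = 0.05
    rho_top: float = 0.4
    spec: PenalizedSpec = field(default_factory=PenalizedSpec)
    reference_group: str = "HC"
    out_dir: str = "immunage_run"
    seed: int = 0
    plasma_prefix: str = "plasma"
    index_selection: str = "stepwise"
    tune_models: bool = True

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path / simulate must be set")

    @classmethod
    def fast(cls, **kw) -> "RunConfig":
        """Desk-scale profile: 20 CV repeats, 100 bootstraps, retain > 50."""
        spec = kw.pop("spec", None) or PenalizedSpec(
            n_cv_repeats=20, n_bootstrap=100, retain_threshold=50)
        return cls(spec=spec, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        spec = raw.pop("spec", None)
        cfg = cls(**raw)
        if sim is not None:
            if "age_range" in sim:
                sim["age_range"] = tuple(sim["age_range"])
            if "group_labels" in sim:
                sim["group_labels"] = tuple(sim["group_labels"])
            if "stratum_counts" in sim and sim["stratum_counts"] is not None:
                sim["stratum_counts"] = tuple(sim["stratum_counts"])
            cfg.simulate = SimulationConfig(**sim)
        if spec is not None:
            if "alpha_grid" in spec:
                spec["alpha_grid"] = tuple(spec["alpha_grid"])
            cfg.spec = PenalizedSpec(**spec)
        return cfg


def load_cohort_table(path: str | Path):
    """Read a cohort TSV (id, age, group, features...) into table + matrix."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("id", "age", "group"):
        if col not in frame.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    meta = frame[["id", "age", "group"]].copy()
    from .simulate import assign_stratum
    meta["stratum"] = assign_stratum(meta["age"])
    features = frame.drop(columns=["id", "age", "group"]).set_axis(
        frame["id"], axis=0)
    return meta, features


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            logger.error("stage %s: failed after %.2fs: %s", self.name, dt, exc)
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.2fs", self.name, dt)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and return the manifest dictionary."""
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {"config_seed": config.seed, "artifacts": {}, "counts": {},
                      "metrics": {}}
    try:
        # ---- input ----------------------------------------------------
        with _Stage("input"):
            if config.simulate is not None:
                sim = dataclasses.replace(config.simulate, seed=config.seed)
                cohort_obj: SyntheticCohort = generate_cohort(sim)
                meta, features = cohort_obj.cohort, cohort_obj.features
                paths = write_cohort(cohort_obj, outdir)
                manifest["artifacts"].update(paths)
            else:
                meta, features = load_cohort_table(config.input_path)
                manifest["artifacts"]["cohort"] = str(config.input_path)
        labels = sorted(pd.unique(meta["group"]).tolist())
        if config.reference_group not in labels:
            raise ValueError(f"reference group {config.reference_group!r} not "
                             f"among labels {labels}")
        ref = config.reference_group
        case = next(g for g in labels if g != ref)

        # ---- inflammatory index ---------------------------------------
        with _Stage("index"):
            plasma_cols = [c for c in features.columns
                           if c.startswith(config.plasma_prefix)]
            if len(plasma_cols) >= 2:
                idx_model = InflammatoryIndex(features[plasma_cols],
                                              meta["age"],
                                              selection=config.index_selection,
                                              seed=config.seed)
                idx_res = idx_model.fit()
                scores = idx_res.score(features)
                contrast = idx_res.contrast(features, meta["group"].to_numpy())
                idx_res.to_json(outdir / "inflammatory_index.json")
                scores.rename("index").to_frame().to_csv(
                    outdir / "index_scores.tsv", sep="\t",
                    float_format="%.10g")
                manifest["artifacts"]["inflammatory_index"] = str(
                    outdir / "inflammatory_index.json")
                manifest["artifacts"]["index_scores"] = str(
                    outdir / "index_scores.tsv")
                manifest["counts"]["index_markers"] = len(idx_res.markers)
                manifest["metrics"]["index_contrast"] = contrast.to_dict()
            else:
                manifest["counts"]["index_markers"] = 0

        # ---- age-association screen ----------------------------------
        with _Stage("screen"):
            screens = {}
            for g in (ref, case):
                mask = (meta["group"] == g).to_numpy()
                rec = spearman_screen(features.iloc[np.where(mask)[0]],
                                      meta.loc[mask, "age"],
                                      alpha=config.screen_alpha, group=g)
                screens[g] = rec
                rec.to_csv(outdir / f"screen_{g}.tsv", sep="\t", index=False,
                           float_format="%.10g")
                manifest["artifacts"][f"screen_{g}"] = str(outdir / f"screen_{g}.tsv")
                manifest["counts"][f"significant_{g}"] = int(rec["significant"].sum())
                top = top_parameters(rec, config.rho_top)
                top.to_csv(outdir / f"top_{g}.tsv", sep="\t", index=False,
                           float_format="%.10g")
                manifest["counts"][f"top_{g}"] = len(top)
            overlap = classify_overlap(screens[ref], screens[case])
            (outdir / "overlap.json").write_text(
                json.dumps(overlap.to_dict(), indent=1, sort_keys=True))
            manifest["artifacts"]["overlap"] = str(outdir / "overlap.json")
            manifest["counts"].update({
                "shared": len(overlap.shared),
                "same_direction": len(overlap.same_direction),
                "opposite_direction": len(overlap.opposite_direction),
                f"{ref}_only": len(overlap.a_only),
                f"{case}_only": len(overlap.b_only),
            })

        # ---- per-group age models -------------------------------------
        models = {}
        with _Stage("age_models"):
            for g in (ref, case):
                mask = (meta["group"] == g).to_numpy()
                rec = screens[g]
                sig = rec.loc[rec["significant"], "parameter"].tolist()
                if not sig:
                    raise ValueError(f"no significant parameters for group {g}")
                feats_g = features.loc[features.index[mask], sig]
                model = ImmuneAgeModel(feats_g, meta.loc[mask, "age"],
                                       spec=dataclasses.replace(
                                           config.spec, seed=config.seed),
                                       group=g)
                res = model.tune() if config.tune_models else model.fit()
                models[g] = (res, feats_g, meta.loc[mask, "age"].to_numpy())
                res.to_json(outdir / f"age_model_{g}.json")
                manifest["artifacts"][f"age_model_{g}"] = str(
                    outdir / f"age_model_{g}.json")
                manifest["counts"][f"retained_{g}"] = len(res.parameters)
                manifest["metrics"][f"model_{g}"] = {
                    "train": res.metrics, "test": res.test_metrics,
                    "alpha": res.cv.alpha if res.cv else None,
                    "lambda_1se": res.cv.lambda_1se if res.cv else None,
                }

        # ---- cross-group application ----------------------------------
        with _Stage("cross_apply"):
            res_ref = models[ref][0]
            mask_case = (meta["group"] == case).to_numpy()
            feats_case_all = features.loc[features.index[mask_case]]
            pred = res_ref.predict(feats_case_all)
            from .agemodel import _metrics
            manifest["metrics"]["cross_applied"] = _metrics(
                meta.loc[mask_case, "age"].to_numpy(), pred.to_numpy())

        # ---- combined model -------------------------------------------
        with _Stage("combine"):
            feats_by_group = {}
            ages_by_group = {}
            for g in (ref, case):
                mask = (meta["group"] == g).to_numpy()
                feats_by_group[g] = features.loc[features.index[mask]]
                ages_by_group[g] = meta.loc[mask, "age"].to_numpy()
            combined = combine_models(models[ref][0], models[case][0],
                                      feats_by_group, ages_by_group)
            manifest["counts"]["union_size"] = combined.union_size
            for g, r in combined.per_group.items():
                manifest["metrics"][f"combined_{g}"] = r.metrics
                r.to_json(outdir / f"combined_model_{g}.json")
                manifest["artifacts"][f"combined_model_{g}"] = str(
                    outdir / f"combined_model_{g}.json")

        # ---- aging rates ----------------------------------------------
        with _Stage("rates"):
            preds = pd.concat([combined.predict(feats_by_group[g], g)
                               for g in (ref, case)])
            preds = preds.loc[meta["id"]]
            records = compute_rates(preds.to_numpy(), meta)
            records.to_csv(outdir / "rates.tsv", sep="\t", index=False,
                           float_format="%.10g")
            manifest["artifacts"]["rates"] = str(outdir / "rates.tsv")
            contrasts = contrast_strata(records, ref)
            manifest["metrics"]["stratum_contrasts"] = [c.to_dict()
                                                        for c in contrasts]
            (outdir / "contrasts.json").write_text(json.dumps(
                _jsonable([c.to_dict() for c in contrasts]), indent=1))

        # artifact paths are stored relative to the output directory so a
        # rerun with the same config is byte-identical wherever it lands
        on_disk = dict(manifest)
        on_disk["artifacts"] = {
            k: (str(Path(v).relative_to(outdir)) if str(v).startswith(str(outdir))
                else str(v))
            for k, v in manifest["artifacts"].items()}
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(_jsonable(on_disk), indent=1,
                                            sort_keys=True))
        manifest["artifacts"]["manifest"] = str(manifest_path)
        return manifest
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
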