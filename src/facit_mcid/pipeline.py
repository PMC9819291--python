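"""End-to-end orchestration with reproducible seeds and a run manifest.

``run_pipeline`` executes the full analysis on either a supplied cohort
CSV or a freshly generated synthetic cohort: change computation, anchor
classification, per-direction ROC/MCID estimation, anchor
reconciliation, patient classification, random-forest screening of the
baseline and one-year-change predictor pools, the collinearity rule,
the four logistic predictor models, and post hoc power estimates for
the group comparisons.  Every intermediate table is written to the
output directory and listed, with a content hash, in ``manifest.json``;
identical configuration + seed yields byte-identical outputs.

Stage seeds fan out from the single global seed through a
``numpy.random.SeedSequence`` keyed by a fixed per-stage index, so any
stage can be rerun in isolation with the same stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import mcid_estimation as mcid
from . import synthetic_cohort as synth
from .logistic_model import (BASELINE_PREDICTORS, CHANGE_PREDICTORS,
                             change_columns, run_predictor_analyses,
                             to_table_frame)
from .power_simulation import PowerSpec, resampler, wmw_power
from .rf_screening import ForestSpec, screen_predictors

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_config",
           "stage_seed"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


_STAGE_INDEX = {"simulate": 0, "mcid": 1, "screen_baseline": 2,
                "screen_change": 3, "logistic": 4, "power": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = _STAGE_INDEX[stage]
    state = np.random.SeedSequence([global_seed & 0x7FFFFFFF, idx])
    return int(state.generate_state(1)[0] % 2147483647)


@dataclass
class RunConfig:
    out_dir: Path
    cohort_path: Path | None = None
    synthetic: synth.CohortSpec | None = None
    anchors: tuple[mcid.AnchorSpec, ...] = mcid.DEFAULT_ANCHORS
    mcid_policy: str = "primary"
    forest: ForestSpec = field(default_factory=ForestSpec)
    baseline_predictors: tuple[str, ...] = BASELINE_PREDICTORS
    change_predictors: tuple[str, ...] = CHANGE_PREDICTORS
    power_reps: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if (self.cohort_path is None) == (self.synthetic is None):
            raise ConfigError(
                "exactly one of cohort_path / synthetic must be supplied")
        if not self.anchors:
            raise ConfigError("anchors: at least one anchor is required")


def _anchor_from_dict(cfg: dict[str, Any]) -> mcid.AnchorSpec:
    for key in ("name", "higher_is_better", "mcid_worsen", "mcid_improve"):
        if key not in cfg:
            raise ConfigError(f"anchor config missing field {key!r}")
    return mcid.AnchorSpec(cfg["name"], bool(cfg["higher_is_better"]),
                           float(cfg["mcid_worsen"]), float(cfg["mcid_improve"]),
                           primary=bool(cfg.get("primary", False)))


def load_config(path: str | Path, out_dir: str | Path | None = None,
                seed: int | None = None) -> RunConfig:
    """Read a TOML run configuration.

    Top-level keys: ``cohort_path`` or a ``[synthetic]`` table (CohortSpec
    fields), ``[[anchors]]`` tables, ``[forest]`` (ForestSpec fields),
    ``mcid_policy``, ``power_reps``, ``seed``, ``out_dir``.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    synthetic = None
    if "synthetic" in raw:
        fields = {f.name for f in dataclasses.fields(synth.CohortSpec)}
        unknown = set(raw["synthetic"]) - fields
        if unknown:
            raise ConfigError(f"unknown synthetic-spec fields: {sorted(unknown)}")
        synthetic = synth.CohortSpec(**raw["synthetic"])
    anchors = tuple(_anchor_from_dict(a) for a in raw.get("anchors", []))
    config = RunConfig(
        out_dir=Path(out_dir if out_dir is not None else raw.get("out_dir", "results")),
        cohort_path=Path(raw["cohort_path"]) if "cohort_path" in raw else None,
        synthetic=synthetic,
        anchors=anchors or mcid.DEFAULT_ANCHORS,
        mcid_policy=raw.get("mcid_policy", "primary"),
        forest=ForestSpec(**raw.get("forest", {})),
        power_reps=int(raw.get("power_reps", 2000)),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
    )
    config.validate()
    return config


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_digest(config: RunConfig) -> str:
    def default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return str(obj)
    fields = dataclasses.asdict(config)
    fields.pop("out_dir", None)        # the digest describes the analysis,
    payload = json.dumps(fields, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "config_sha256": _config_digest(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_INDEX},
    }

    stage = "load-cohort"
    try:
        # --- cohort ------------------------------------------------------
        if config.synthetic is not None:
            stage = "simulate"
            spec = dataclasses.replace(config.synthetic,
                                       seed=stage_seed(config.seed, "simulate"))
            cohort = synth.generate_cohort(spec)
            synth.write_cohort(cohort, out / "cohort.csv")
            artifacts["cohort"] = out / "cohort.csv"
            truth = synth.truth_table(cohort)
            _write_csv(truth, out / "truth_table.csv")
            artifacts["truth_table"] = out / "truth_table.csv"
            manifest["realized_anchor_correlation"] = \
                cohort.attrs["realized_anchor_correlation"]
            manifest["clipping_fraction"] = cohort.attrs["clipping_fraction"]
            cohort = cohort.drop(columns=["latent_true_change"])
        else:
            cohort = synth.read_cohort(config.cohort_path)

        # --- MCID estimation --------------------------------------------
        stage = "mcid"
        analysis = mcid.estimate_mcid(cohort, anchors=config.anchors,
                                      policy=config.mcid_policy)
        _write_csv(analysis.change_scores, out / "change_scores.csv")
        _write_csv(analysis.results_frame(), out / "mcid_results.csv")
        _write_csv(analysis.roc_frame(), out / "roc_coordinates.csv")
        _write_csv(analysis.labels, out / "labels.csv")
        (out / "mcid_pair.json").write_text(json.dumps({
            "mcid_worsen": analysis.pair.mcid_worsen,
            "mcid_improve": analysis.pair.mcid_improve,
            "counts": analysis.counts,
        }, indent=2) + "\n")
        for name in ("change_scores", "mcid_results", "roc_coordinates",
                     "labels"):
            artifacts[name] = out / f"{name}.csv"
        artifacts["mcid_pair"] = out / "mcid_pair.json"
        manifest["mcid_pair"] = {"worsen": analysis.pair.mcid_worsen,
                                 "improve": analysis.pair.mcid_improve}
        manifest["group_counts"] = analysis.counts

        # --- random-forest screening ------------------------------------
        stage = "screen"
        delta = analysis.change_scores["delta_target"].to_numpy()
        base_design = pd.DataFrame(
            {v: cohort[v] if v in cohort.columns else cohort[f"{v}_base"]
             for v in config.baseline_predictors})
        change_design = change_columns(cohort, list(config.change_predictors))
        screened: dict[str, list[str]] = {}
        for tag, design in (("baseline", base_design), ("change", change_design)):
            fspec = dataclasses.replace(
                config.forest, seed=stage_seed(config.seed, f"screen_{tag}"))
            table = screen_predictors(design, delta, fspec)
            _write_csv(table.to_frame().reset_index(),
                       out / f"importance_{tag}.csv")
            artifacts[f"importance_{tag}"] = out / f"importance_{tag}.csv"
            raw_names = [c.removeprefix("d_") for c in table.selected]
            screened[tag] = raw_names
        manifest["screened"] = screened

        # --- logistic predictor models -----------------------------------
        stage = "logistic"
        fits = run_predictor_analyses(
            cohort, analysis.labels,
            screened={"baseline": screened["baseline"] or
                      list(config.baseline_predictors),
                      "change": screened["change"] or
                      list(config.change_predictors)})
        _write_csv(to_table_frame(fits), out / "logistic_models.csv")
        artifacts["logistic_models"] = out / "logistic_models.csv"

        # --- post hoc power ----------------------------------------------
        stage = "power"
        power_out: dict[str, Any] = {}
        merged = analysis.change_scores.merge(analysis.labels, on="patient_id")
        pseed = stage_seed(config.seed, "power")
        for k, anchor in enumerate(config.anchors):
            deltas = merged[f"delta_{anchor.name}"]
            for j, direction in enumerate(mcid.DIRECTIONS):
                in_group = merged["label"] == direction
                a = deltas[in_group].dropna().to_numpy()
                b = deltas[~in_group].dropna().to_numpy()
                if a.size < 2 or b.size < 2:
                    power_out[f"{direction}_{anchor.name}"] = None
                    continue
                est = wmw_power(PowerSpec(resampler(a), resampler(b),
                                          n_a=a.size, n_b=b.size,
                                          n_reps=config.power_reps,
                                          seed=(pseed + 7 * k + j) % 2147483647))
                power_out[f"{direction}_{anchor.name}"] = {
                    "power": est.power, "mc_se": est.mc_se,
                    "n_a": est.n_a, "n_b": est.n_b}
        (out / "power.json").write_text(json.dumps(power_out, indent=2) + "\n")
        artifacts["power"] = out / "power.json"
        manifest["power"] = power_out
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        manifest["artifacts"] = {k: v.name for k, v in artifacts.items()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise

    manifest["artifacts"] = {
        name: {"path": path.name, "sha256": _sha256(path)}
        for name, path in artifacts.items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
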