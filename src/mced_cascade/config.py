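"""Pipeline configuration: YAML schema, validation, and defaults.

The config is a nested mapping with four sections — ``cohort`` (synthetic
cohort spec), ``model`` (cutoffs, grid step, percentile convention),
``scenarios`` (the screening strategies to project, with their costs), and
top-level ``seed`` / ``output_dir`` / ``verbosity``.  Validation is strict:
unknown keys are rejected and missing required fields are reported by name,
before any stage runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .cohort import CohortSpec, PTMParams, MarkerParams, MARKERS, STAGES
from .projection import ScenarioSpec

__all__ = ["ConfigError", "PipelineConfig", "ScenarioConfig", "ModelConfig",
           "load_config", "default_config_dict", "config_from_dict"]


class ConfigError(ValueError):
    """Raised on schema violations, naming the offending field."""


@dataclass(frozen=True)
class ModelConfig:
    grid_step: float = 0.05
    poc_cutoff: float = 0.5
    crs_cutoff: float = 2.0
    crs_target_specificity: float = 0.98


@dataclass(frozen=True)
class ScenarioConfig:
    """A projection scenario plus its cost rule.

    ``cost_type`` is ``one_step`` (pay ``per_test`` for everyone) or
    ``two_step`` (pay ``step1_per_test`` for everyone plus
    ``step2_per_test`` for the first-step positives of the scenario named
    by ``step1_positives_from``).
    """

    scenario: ScenarioSpec
    cost_type: str
    per_test: float | None = None
    step1_per_test: float | None = None
    step2_per_test: float | None = None
    step1_positives_from: str | None = None


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortSpec
    model: ModelConfig
    scenarios: tuple[ScenarioConfig, ...]
    seed: int = 0
    output_dir: str = "out"
    verbosity: str = "info"


def default_config_dict() -> dict:
    """The bundled default configuration (reference cohort + four strategies)."""
    return {
        "seed": 20240601,
        "output_dir": "out",
        "verbosity": "info",
        "cohort": {"n_cancer": 617, "n_noncancer": 580},
        "model": {"grid_step": 0.05, "poc_cutoff": 0.5, "crs_cutoff": 2.0,
                  "crs_target_specificity": 0.98},
        "scenarios": [
            {"label": "OncoSeek", "population": 5_000_000, "incidence": 0.019,
             "sensitivity_case_control": 0.499, "specificity": 0.910,
             "adjustment": "proportional",
             "sens_retrospective_ref": 0.515, "sens_prospective_ref": 0.289,
             "cost": {"type": "one_step", "per_test": 80}},
            {"label": "SeekInCare", "population": 5_000_000, "incidence": 0.019,
             "sensitivity_case_control": 0.600, "specificity": 0.983,
             "adjustment": "proportional",
             "sens_retrospective_ref": 0.515, "sens_prospective_ref": 0.289,
             "cost": {"type": "one_step", "per_test": 750}},
            {"label": "Two-step MCED", "population": 5_000_000, "incidence": 0.019,
             "sensitivity_case_control": 0.399, "specificity": 0.993,
             "adjustment": "proportional",
             "sens_retrospective_ref": 0.515, "sens_prospective_ref": 0.289,
             "cost": {"type": "two_step", "step1_per_test": 80,
                      "step2_per_test": 670, "step1_positives_from": "OncoSeek"}},
            {"label": "Galleri", "population": 5_000_000, "incidence": 0.019,
             "sensitivity_case_control": 0.515, "specificity": 0.991,
             "adjustment": "proportional",
             "sens_retrospective_ref": 0.515, "sens_prospective_ref": 0.289,
             "cost": {"type": "one_step", "per_test": 949}},
        ],
    }


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"missing required field {key!r} in {where}")
    return mapping[key]


def _check_keys(mapping: Mapping, allowed: set[str], where: str) -> None:
    if not isinstance(mapping, Mapping):
        raise ConfigError(f"{where} must be a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown field(s) {sorted(unknown)} in {where}")


def _parse_marker_params(name: str, d: Mapping, base: MarkerParams) -> MarkerParams:
    allowed = {"log10_median", "log10_sd", "elevation_shift", "elevation_shift_sd"}
    _check_keys(d, allowed, f"cohort.ptm.markers.{name}")
    kwargs = {k: float(d.get(k, getattr(base, k))) for k in allowed}
    return MarkerParams(**kwargs)


def _parse_ptm(d: Mapping) -> PTMParams:
    allowed = {"markers", "elevation_prob_by_stage", "noncancer_elevation_prob",
               "noncancer_shift_scale", "burden_corr", "cancer_continuous_shift"}
    _check_keys(d, allowed, "cohort.ptm")
    base = PTMParams()
    markers = dict(base.markers)
    for name, md in d.get("markers", {}).items():
        if name not in MARKERS:
            raise ConfigError(f"unknown marker {name!r} in cohort.ptm.markers")
        markers[name] = _parse_marker_params(name, md, markers[name])
    probs = dict(base.elevation_prob_by_stage)
    for st, p in d.get("elevation_prob_by_stage", {}).items():
        if st not in STAGES:
            raise ConfigError(f"unknown stage {st!r} in cohort.ptm.elevation_prob_by_stage")
        probs[st] = float(p)
    return PTMParams(
        markers=markers, elevation_prob_by_stage=probs,
        noncancer_elevation_prob=float(
            d.get("noncancer_elevation_prob", base.noncancer_elevation_prob)),
        noncancer_shift_scale=float(
            d.get("noncancer_shift_scale", base.noncancer_shift_scale)),
        burden_corr=float(d.get("burden_corr", base.burden_corr)),
        cancer_continuous_shift=float(
            d.get("cancer_continuous_shift", base.cancer_continuous_shift)),
    )


def _parse_cohort(d: Mapping, seed: int) -> CohortSpec:
    allowed = {"n_cancer", "n_noncancer", "stage_probs", "feature_auc_targets",
               "feature_corr", "ptm", "age_mean_cancer", "age_sd_cancer",
               "age_mean_noncancer", "age_sd_noncancer",
               "male_frac_cancer", "male_frac_noncancer"}
    _check_keys(d, allowed, "cohort")
    base = CohortSpec()
    kwargs: dict[str, Any] = {"seed": seed}
    for k in ("n_cancer", "n_noncancer"):
        kwargs[k] = int(d.get(k, getattr(base, k)))
    for k in ("feature_corr", "age_mean_cancer", "age_sd_cancer",
              "age_mean_noncancer", "age_sd_noncancer",
              "male_frac_cancer", "male_frac_noncancer"):
        kwargs[k] = float(d.get(k, getattr(base, k)))
    if "stage_probs" in d:
        kwargs["stage_probs"] = {str(k): float(v) for k, v in d["stage_probs"].items()}
    if "feature_auc_targets" in d:
        kwargs["feature_auc_targets"] = {
            str(k): float(v) for k, v in d["feature_auc_targets"].items()}
    if "ptm" in d:
        kwargs["ptm_params"] = _parse_ptm(d["ptm"])
    spec = CohortSpec(**kwargs)
    try:
        spec.validate()
    except ValueError as exc:
        raise ConfigError(f"cohort: {exc}") from exc
    return spec


def _parse_scenario(d: Mapping, idx: int) -> ScenarioConfig:
    where = f"scenarios[{idx}]"
    allowed = {"label", "population", "incidence", "sensitivity_case_control",
               "specificity", "adjustment", "sens_retrospective_ref",
               "sens_prospective_ref", "cost"}
    _check_keys(d, allowed, where)
    label = str(_require(d, "label", where))
    try:
        spec = ScenarioSpec(
            label=label,
            population=int(_require(d, "population", where)),
            incidence=float(_require(d, "incidence", where)),
            sensitivity_case_control=float(
                _require(d, "sensitivity_case_control", where)),
            specificity=float(_require(d, "specificity", where)),
            adjustment=str(d.get("adjustment", "proportional")),
            sens_retrospective_ref=float(d.get("sens_retrospective_ref", 0.515)),
            sens_prospective_ref=float(d.get("sens_prospective_ref", 0.289)),
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc

    cost = _require(d, "cost", where)
    ctype = str(_require(cost, "type", f"{where}.cost"))
    if ctype == "one_step":
        _check_keys(cost, {"type", "per_test"}, f"{where}.cost")
        return ScenarioConfig(scenario=spec, cost_type=ctype,
                              per_test=float(_require(cost, "per_test", f"{where}.cost")))
    if ctype == "two_step":
        _check_keys(cost, {"type", "step1_per_test", "step2_per_test",
                           "step1_positives_from"}, f"{where}.cost")
        return ScenarioConfig(
            scenario=spec, cost_type=ctype,
            step1_per_test=float(_require(cost, "step1_per_test", f"{where}.cost")),
            step2_per_test=float(_require(cost, "step2_per_test", f"{where}.cost")),
            step1_positives_from=str(
                _require(cost, "step1_positives_from", f"{where}.cost")),
        )
    raise ConfigError(f"{where}.cost.type must be 'one_step' or 'two_step', got {ctype!r}")


def config_from_dict(d: Mapping) -> PipelineConfig:
    """Validate a raw mapping into a :class:`PipelineConfig` (strict schema)."""
    allowed = {"seed", "output_dir", "verbosity", "cohort", "model", "scenarios"}
    _check_keys(d, allowed, "config")
    seed = int(d.get("seed", 0))
    model_d = d.get("model", {})
    _check_keys(model_d, {"grid_step", "poc_cutoff", "crs_cutoff",
                          "crs_target_specificity"}, "model")
    model = ModelConfig(
        grid_step=float(model_d.get("grid_step", 0.05)),
        poc_cutoff=float(model_d.get("poc_cutoff", 0.5)),
        crs_cutoff=float(model_d.get("crs_cutoff", 2.0)),
        crs_target_specificity=float(model_d.get("crs_target_specificity", 0.98)),
    )
    cohort = _parse_cohort(d.get("cohort", {}), seed)
    raw_scen = d.get("scenarios", [])
    if not isinstance(raw_scen, (list, tuple)):
        raise ConfigError("scenarios must be a list")
    scenarios = tuple(_parse_scenario(s, i) for i, s in enumerate(raw_scen))
    labels = [s.scenario.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ConfigError("scenario labels must be unique")
    for s in scenarios:
        if s.cost_type == "two_step" and s.step1_positives_from not in labels:
            raise ConfigError(
                f"scenario {s.scenario.label!r}: step1_positives_from "
                f"{s.step1_positives_from!r} is not a configured scenario label")
    return PipelineConfig(
        cohort=cohort, model=model, scenarios=scenarios, seed=seed,
        output_dir=str(d.get("output_dir", "out")),
        verbosity=str(d.get("verbosity", "info")),
    )


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return config_from_dict(raw)
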