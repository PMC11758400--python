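"""End-to-end pipeline: cohort -> models -> cascade -> metrics -> projection.

``run_pipeline`` executes the stages in order and writes a reproducible
bundle (cohort CSV, model files, metrics JSON, projection JSON, a rendered
report table, and a run manifest).  Every output is a pure function of the
configuration and seed; re-running with the same pair reproduces the bundle
byte-for-byte (no timestamps inside the artifacts — progress banners go to
the logger only).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cascade import cascade_performance, run_cascade
from .cohort import GENOMIC_FEATURES, generate_cohort, write_cohort
from .config import PipelineConfig, ScenarioConfig
from .costs import CostResult, CostSpec, one_step_cost, two_step_cost
from .crs import fit_crs, save_crs_model, score_crs
from .metrics import delong_test, empirical_auc, sens_spec_at
from .poc import fit_poc, save_poc_model, score_poc
from .projection import ProjectionResult, project, round_half_up

__all__ = ["run_pipeline", "compute_metrics", "project_scenarios", "render_table3"]

logger = logging.getLogger("mced_cascade")

TABLE3_PERFORMANCE_ROWS = (
    "Sensitivity", "Specificity",
    "Number of true positives", "Number of false positives",
    "Number of true negatives", "Number of false negatives",
    "PPV", "Negative predictive value",
    "Positive likelihood ratio", "Negative likelihood ratio",
    "Pretest probability",
    "Posttest probability for positive test",
    "Posttest probability for negative test",
    "NNS",
)
TABLE3_COST_ROWS = ("Total", "Per patient with cancer identified",
                    "Per individual screened")


# ---------------------------------------------------------------------------
# case-control metrics
# ---------------------------------------------------------------------------

def compute_metrics(records: pd.DataFrame, poc_scores, crs_scores,
                    cascade_results: pd.DataFrame,
                    poc_cutoff: float = 0.5, crs_cutoff: float = 2.0) -> dict:
    """Case-control performance summary (JSON-serializable)."""
    y = (records["group"] == "cancer").to_numpy()
    poc = np.asarray(poc_scores, dtype=float)
    crs = np.asarray(crs_scores, dtype=float)

    feature_aucs = {
        f: empirical_auc(records.loc[y, f], records.loc[~y, f])
        for f in GENOMIC_FEATURES
    }
    dl = delong_test(crs, poc, y)
    step1 = sens_spec_at(poc, y, poc_cutoff)
    standalone = sens_spec_at(crs, y, crs_cutoff)
    casc = cascade_performance(cascade_results, records[["id", "group"]])
    return {
        "n_cancer": int(y.sum()),
        "n_noncancer": int((~y).sum()),
        "poc_auc": empirical_auc(poc[y], poc[~y]),
        "crs_auc": empirical_auc(crs[y], crs[~y]),
        "feature_aucs": feature_aucs,
        "delong": {"z": dl.z, "p": dl.p, "auc_a_crs": dl.auc_a, "auc_b_poc": dl.auc_b},
        "step1_at_cutoff": step1,
        "crs_standalone_at_cutoff": standalone,
        "cascade": casc,
    }


# ---------------------------------------------------------------------------
# projection + cost over configured scenarios
# ---------------------------------------------------------------------------

def project_scenarios(scenarios: tuple[ScenarioConfig, ...]
                      ) -> tuple[dict[str, ProjectionResult], dict[str, CostResult]]:
    """Closed-form projection and cost for every configured scenario."""
    projections = {sc.scenario.label: project(sc.scenario) for sc in scenarios}
    costs: dict[str, CostResult] = {}
    for sc in scenarios:
        label = sc.scenario.label
        pr = projections[label]
        if sc.cost_type == "one_step":
            costs[label] = one_step_cost(pr.population, sc.per_test, pr.tp)
        else:
            ref = projections[sc.step1_positives_from]
            spec = CostSpec(cost_step1_per_test=sc.step1_per_test,
                            cost_step2_per_test=sc.step2_per_test)
            costs[label] = two_step_cost(pr.population, ref.tp + ref.fp, spec, pr.tp)
    return projections, costs


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def _fmt_pct(x: float) -> str:
    return f"{round_half_up(100.0 * x, 1):.1f}%"


def _fmt_millions(total: float) -> str:
    m = round_half_up(total / 1e6, 1)
    if m == int(m):
        return f"${int(m):,} million"
    return f"${m:,.1f} million"


def _fmt_dollars(x: float | None) -> str:
    if x is None:
        return "-"
    return f"${int(round_half_up(x)):,}"


def render_table3(projections: dict[str, ProjectionResult],
                  costs: dict[str, CostResult]) -> str:
    """Plain-text report table: performance and cost rows per strategy."""
    labels = list(projections)
    cells: dict[str, list[str]] = {}
    for label in labels:
        p = projections[label]
        c = costs.get(label)
        col = [
            _fmt_pct(p.sensitivity_adjusted),
            _fmt_pct(p.specificity),
            f"{p.tp:,}", f"{p.fp:,}", f"{p.tn:,}", f"{p.fn:,}",
            _fmt_pct(p.ppv), _fmt_pct(p.npv),
            f"{round_half_up(p.lr_pos, 1):.1f}", f"{round_half_up(p.lr_neg, 1):.1f}",
            _fmt_pct(p.pretest), _fmt_pct(p.posttest_pos), _fmt_pct(p.posttest_neg),
            f"{p.nns:,}",
        ]
        if c is not None:
            col += [_fmt_millions(c.total), _fmt_dollars(c.per_case_detected),
                    _fmt_dollars(c.per_individual_screened)]
        else:
            col += ["-", "-", "-"]
        cells[label] = col

    rows = list(TABLE3_PERFORMANCE_ROWS) + list(TABLE3_COST_ROWS)
    name_w = max(len(r) for r in rows) if rows else 0
    widths = {lb: max(len(lb), max((len(v) for v in cells[lb]), default=0))
              for lb in labels}
    lines = ["  ".join(["Metric".ljust(name_w)] + [lb.rjust(widths[lb]) for lb in labels])]
    for i, row in enumerate(rows):
        lines.append("  ".join(
            [row.ljust(name_w)] + [cells[lb][i].rjust(widths[lb]) for lb in labels]))
    return "\n".join(lines) + "\n"


def _table3_frame(projections, costs) -> pd.DataFrame:
    data = {}
    for label in projections:
        p, c = projections[label], costs.get(label)
        data[label] = {
            "sensitivity_pct": round_half_up(100 * p.sensitivity_adjusted, 1),
            "specificity_pct": round_half_up(100 * p.specificity, 1),
            "tp": p.tp, "fp": p.fp, "tn": p.tn, "fn": p.fn,
            "ppv_pct": round_half_up(100 * p.ppv, 1),
            "npv_pct": round_half_up(100 * p.npv, 1),
            "lr_pos": round_half_up(p.lr_pos, 1), "lr_neg": round_half_up(p.lr_neg, 1),
            "pretest_pct": round_half_up(100 * p.pretest, 1),
            "posttest_pos_pct": round_half_up(100 * p.posttest_pos, 1),
            "posttest_neg_pct": round_half_up(100 * p.posttest_neg, 1),
            "nns": p.nns,
            "total_cost": c.total if c else None,
            "cost_per_case": (round_half_up(c.per_case_detected)
                              if c and c.per_case_detected is not None else None),
            "cost_per_screened": round_half_up(c.per_individual_screened) if c else None,
        }
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _config_digest(config: PipelineConfig) -> str:
    # dataclasses -> canonical JSON -> sha256
    def enc(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: enc(getattr(obj, k)) for k in sorted(obj.__dataclass_fields__)}
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj
    blob = json.dumps(enc(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _dump_json(payload, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Execute every stage and write the report bundle.

    Returns a dict with the in-memory results (cohort frame, models,
    metrics, projections, costs, and the list of files written).
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/6: generating cohort (n=%d)",
                config.cohort.n_cancer + config.cohort.n_noncancer)
    records = generate_cohort(config.cohort, config.seed)
    write_cohort(records, out / "cohort.csv")

    logger.info("stage 2/6: fitting POC model")
    poc_model = fit_poc(records, seed=config.seed)
    save_poc_model(poc_model, out / "poc_model.json")
    poc = score_poc(poc_model, records)

    logger.info("stage 3/6: fitting CRS (grid step %.3g)", config.model.grid_step)
    crs_model = fit_crs(records, poc, step=config.model.grid_step)
    save_crs_model(crs_model, out / "crs_model.json")
    crs = score_crs(crs_model, records, poc)

    logger.info("stage 4/6: running two-step cascade")
    cascade_results = run_cascade(poc_model, crs_model, records,
                                  poc_cutoff=config.model.poc_cutoff,
                                  crs_cutoff=config.model.crs_cutoff)
    cascade_results.to_csv(out / "cascade.csv", index=False, float_format="%.6g")

    logger.info("stage 5/6: computing case-control metrics")
    metrics = compute_metrics(records, poc, crs, cascade_results,
                              poc_cutoff=config.model.poc_cutoff,
                              crs_cutoff=config.model.crs_cutoff)
    _dump_json(metrics, out / "metrics.json")

    logger.info("stage 6/6: projecting %d screening scenario(s)",
                len(config.scenarios))
    projections, cost_results = project_scenarios(config.scenarios)
    table = _table3_frame(projections, cost_results)
    _dump_json(json.loads(table.to_json()), out / "projection.json")
    report = render_table3(projections, cost_results)
    (out / "report.txt").write_text(report, encoding="utf-8")
    table.to_csv(out / "report.csv")

    manifest = {
        "package": "mced-cascade",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_digest(config),
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    _dump_json(manifest, out / "manifest.json")

    return {
        "records": records, "poc_model": poc_model, "crs_model": crs_model,
        "poc": poc, "crs": crs, "cascade": cascade_results, "metrics": metrics,
        "projections": projections, "costs": cost_results, "report": report,
        "output_dir": out, "manifest": manifest,
    }
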