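"""Population-scale screening projection from case-control operating points.

Given a screening strategy's case-control sensitivity and specificity, a
target population and a cancer incidence (the pretest probability), this
module computes the closed-form 2x2 outcome counts, predictive values,
likelihood ratios, post-test probabilities, and the number needed to screen
(NNS) per cancer case detected.

Because case-control (retrospective) sensitivity overstates what a
prospective screen achieves, the projection supports a proportional
real-world adjustment: the case-control sensitivity is scaled by the ratio
of a reference test's prospective to retrospective sensitivity
(28.9% / 51.5% for the CCGA-vs-PATHFINDER anchor) and rounded to one
decimal place in percent before any count is formed.  Specificity is used
as given.  All counts are rounded half-up; the unrounded ratios are kept on
the result for downstream formatting.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = ["ScenarioSpec", "ProjectionResult", "adjust_sensitivity", "project",
           "compare_scenarios", "round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScenarioSpec:
    """One screening strategy's projection inputs.

    ``adjustment='proportional'`` rescales the case-control sensitivity by
    ``sens_prospective_ref / sens_retrospective_ref``; ``'none'`` uses it
    as-is (still rounded to one decimal in percent, so printed and computed
    quantities agree).
    """

    label: str
    population: int
    incidence: float
    sensitivity_case_control: float
    specificity: float
    adjustment: str = "proportional"               # "none" | "proportional"
    sens_retrospective_ref: float = 0.515
    sens_prospective_ref: float = 0.289

    def __post_init__(self):
        if self.population <= 0:
            raise ValueError("population must be positive")
        for name in ("incidence", "sensitivity_case_control", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.adjustment not in ("none", "proportional"):
            raise ValueError(f"unknown adjustment {self.adjustment!r}")


@dataclass(frozen=True)
class ProjectionResult:
    """Closed-form screening outcome for one scenario."""

    label: str
    population: int
    pretest: float
    sensitivity_adjusted: float     # after proportional adjustment + rounding
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    posttest_pos: float             # = ppv
    posttest_neg: float             # = 1 - npv
    nns: int


def adjust_sensitivity(sens_cc: float, ref_retro: float, ref_prosp: float) -> float:
    """Proportional real-world sensitivity, rounded to 0.1% precision.

    Scales the case-control sensitivity by the prospective/retrospective
    ratio of the reference test and rounds half-up to one decimal place in
    percent (the rounded value is what enters the count projection, so the
    projected counts match their printed one-decimal sensitivities exactly).
    """
    if not (0.0 < ref_retro <= 1.0 and 0.0 < ref_prosp <= 1.0):
        raise ValueError("reference sensitivities must lie in (0, 1]")
    if not 0.0 < sens_cc <= 1.0:
        raise ValueError("sens_cc must lie in (0, 1]")
    if ref_retro < ref_prosp:
        raise ValueError("retrospective reference must be >= prospective reference")
    pct = 100.0 * sens_cc * (ref_prosp / ref_retro)
    return round_half_up(pct, 1) / 100.0


def project(spec: ScenarioSpec) -> ProjectionResult:
    """Project one scenario onto its screening population.

    Counts: cancers = population * incidence (rounded half-up), TP =
    cancers * adjusted sensitivity (rounded half-up), FP from (1 -
    specificity) on the noncancer remainder; TN/FN by complement so the
    four cells always sum to the population exactly.
    """
    if spec.adjustment == "proportional":
        sens = adjust_sensitivity(spec.sensitivity_case_control,
                                  spec.sens_retrospective_ref,
                                  spec.sens_prospective_ref)
    else:
        sens = round_half_up(100.0 * spec.sensitivity_case_control, 1) / 100.0
    spec_ = spec.specificity

    cancers = int(round_half_up(spec.population * spec.incidence))
    noncancers = spec.population - cancers
    tp = int(round_half_up(cancers * sens))
    fn = cancers - tp
    fp = int(round_half_up(noncancers * (1.0 - spec_)))
    tn = noncancers - fp

    ppv = tp / (tp + fp) if (tp + fp) else 0.0
    npv = tn / (tn + fn) if (tn + fn) else 1.0
    lr_pos = sens / (1.0 - spec_) if spec_ < 1.0 else np.inf
    lr_neg = (1.0 - sens) / spec_ if spec_ > 0.0 else np.inf
    nns = int(round_half_up(1.0 / (spec.incidence * sens))) if spec.incidence * sens > 0 else 0

    return ProjectionResult(
        label=spec.label, population=spec.population, pretest=spec.incidence,
        sensitivity_adjusted=sens, specificity=spec_,
        tp=tp, fp=fp, tn=tn, fn=fn,
        ppv=ppv, npv=npv, lr_pos=float(lr_pos), lr_neg=float(lr_neg),
        posttest_pos=ppv, posttest_neg=1.0 - npv, nns=nns,
    )


def compare_scenarios(results: list[ProjectionResult]) -> dict:
    """Side-by-side scenario comparison.

    Returns a dict with a per-scenario table (one row per strategy, all
    :class:`ProjectionResult` fields plus the post-test positive/negative
    probability ratio) and pairwise fold changes of the false-positive
    rates (one decimal).
    """
    if len(results) < 2:
        raise ValueError("need at least 2 scenarios to compare")
    rows = []
    for r in results:
        row = {k: getattr(r, k) for k in (
            "label", "population", "pretest", "sensitivity_adjusted", "specificity",
            "tp", "fp", "tn", "fn", "ppv", "npv", "lr_pos", "lr_neg",
            "posttest_pos", "posttest_neg", "nns")}
        row["posttest_ratio"] = (r.posttest_pos / r.posttest_neg
                                 if r.posttest_neg > 0 else np.inf)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("label")

    fp_folds = {}
    for ra in results:
        for rb in results:
            if ra.label == rb.label:
                continue
            rate_a = ra.fp / (ra.fp + ra.tn)
            rate_b = rb.fp / (rb.fp + rb.tn)
            fp_folds[(ra.label, rb.label)] = round_half_up(rate_a / rate_b, 1)
    return {"table": table, "fp_rate_folds": fp_folds}
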