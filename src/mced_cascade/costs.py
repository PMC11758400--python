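"""Screening program cost model for single-test and two-step strategies.

A single-test strategy pays its per-test price for every individual
screened.  The two-step strategy pays the cheap first-line test for
everyone plus the follow-up test price only for first-step positives (the
follow-up price can be lower than the standalone price of the same assay
because the protein-marker results carry over and are not re-run).

Reported ratios: cost per cancer case identified divides the total by the
number of true positives (screen-detected cancers); cost per individual
screened divides by the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .projection import round_half_up

__all__ = ["CostSpec", "CostResult", "one_step_cost", "two_step_cost",
           "cost_fold_comparison"]


@dataclass(frozen=True)
class CostSpec:
    """Per-test prices (currency units) for the bundled strategies."""

    cost_step1_per_test: float = 80.0       # first-line protein-marker test
    cost_step2_per_test: float = 670.0      # follow-up multi-omics test (carry-over price)
    cost_standalone: dict[str, float] = field(
        default_factory=lambda: {"SeekInCare": 750.0, "Galleri": 949.0})

    def __post_init__(self):
        if self.cost_step1_per_test < 0 or self.cost_step2_per_test < 0:
            raise ValueError("per-test costs must be nonnegative")
        if any(v < 0 for v in self.cost_standalone.values()):
            raise ValueError("standalone costs must be nonnegative")


@dataclass(frozen=True)
class CostResult:
    """Total and unit costs of one screening strategy (unrounded)."""

    total: float
    per_case_detected: float | None     # None when no case was detected
    per_individual_screened: float


def _result(total: float, population: int, tp: int) -> CostResult:
    per_case = total / tp if tp > 0 else None
    return CostResult(total=float(total), per_case_detected=per_case,
                      per_individual_screened=total / population)


def one_step_cost(population: int, per_test: float, tp: int) -> CostResult:
    """Cost of screening everyone once with a single test."""
    if population <= 0:
        raise ValueError("population must be positive")
    if per_test < 0 or tp < 0:
        raise ValueError("per_test and tp must be nonnegative")
    return _result(population * per_test, population, tp)


def two_step_cost(population: int, step1_positive_count: int, costs: CostSpec,
                  tp: int) -> CostResult:
    """Cost of the cascade: everyone tested at step 1, positives at step 2."""
    if population <= 0:
        raise ValueError("population must be positive")
    if not 0 <= step1_positive_count <= population:
        raise ValueError("step1_positive_count must lie in [0, population]")
    total = population * costs.cost_step1_per_test \
        + step1_positive_count * costs.cost_step2_per_test
    return _result(total, population, tp)


def cost_fold_comparison(result_a: CostResult, result_b: CostResult) -> dict:
    """Fold change of total and per-case cost, a over b, to one decimal."""
    if result_a.total <= 0 or result_b.total <= 0:
        raise ValueError("both totals must be positive to compare")
    folds = {"total_fold": round_half_up(result_a.total / result_b.total, 1)}
    if result_a.per_case_detected is not None and result_b.per_case_detected:
        folds["per_case_fold"] = round_half_up(
            result_a.per_case_detected / result_b.per_case_detected, 1)
    else:
        folds["per_case_fold"] = None
    return folds
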