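"""Two-step cascade: protein-marker screen first, multi-omics test second.

Every subject gets the cheap POC test.  Subjects with POC >= 0.5 are
"initially positive" and proceed to the CRS test; a CRS >= 2.0 there is a
final cancer-predicted call.  Everyone else is predicted noncancer (at
step 1 if POC < 0.5, at step 2 otherwise).  Because step 2 can only turn
initial positives into negatives, the cascade's positives are always a
subset of the step-1 positives: specificity can only rise and sensitivity
can only fall relative to the first test alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .crs import CRSModel, CRS_CUTOFF, score_crs
from .poc import POCModel, POC_CUTOFF, score_poc

__all__ = ["run_cascade", "cascade_performance", "CASCADE_COLUMNS"]

CASCADE_COLUMNS = ("id", "poc", "step1_call", "crs", "final_call", "step_reached")


def run_cascade(poc_model: POCModel, crs_model: CRSModel,
                records: pd.DataFrame,
                poc_cutoff: float = POC_CUTOFF,
                crs_cutoff: float = CRS_CUTOFF) -> pd.DataFrame:
    """Apply the two-step decision flow to a cohort table.

    Returns one row per subject with columns ``CASCADE_COLUMNS``.  ``crs``
    is NaN for subjects stopped at step 1 (the second test is never run for
    them).  Scoring errors are re-raised with the offending subject id.
    """
    records = records.reset_index(drop=True)
    try:
        poc = np.asarray(score_poc(poc_model, records), dtype=float)
    except ValueError as exc:
        raise ValueError(f"POC scoring failed: {exc}") from exc
    step1_pos = poc >= poc_cutoff

    crs = np.full(len(records), np.nan)
    if step1_pos.any():
        sub = records.loc[step1_pos]
        try:
            crs[step1_pos] = score_crs(crs_model, sub, poc[step1_pos])
        except ValueError as exc:
            first_id = sub["id"].iloc[0] if len(sub) else "?"
            raise ValueError(
                f"CRS scoring failed (first step-2 subject {first_id!r}): {exc}"
            ) from exc

    final_pos = step1_pos & (crs >= crs_cutoff)
    return pd.DataFrame({
        "id": records["id"].astype(str),
        "poc": poc,
        "step1_call": np.where(step1_pos, "positive", "negative"),
        "crs": crs,
        "final_call": np.where(final_pos, "cancer_predicted", "noncancer_predicted"),
        "step_reached": np.where(step1_pos, 2, 1),
    }, columns=list(CASCADE_COLUMNS))


def cascade_performance(results: pd.DataFrame, truth_labels: pd.Series | pd.DataFrame) -> dict:
    """Cascade-level sensitivity, specificity and second-step test usage.

    ``truth_labels`` maps subject id to group ("cancer"/"noncancer"): either
    a Series indexed by id, or a frame with ``id`` and ``group`` columns
    (unstaged and missing-stage cancers are ordinary cancer rows there).
    Sensitivity/specificity are reported as None when the corresponding
    class is absent.
    """
    if isinstance(truth_labels, pd.DataFrame):
        truth = truth_labels.set_index("id")["group"]
    else:
        truth = truth_labels
    ids = results["id"]
    missing = [i for i in ids if i not in truth.index]
    if missing:
        raise ValueError(f"truth labels missing for ids: {missing[:5]}")
    y = (truth.loc[ids].to_numpy() == "cancer")
    called_cancer = (results["final_call"] == "cancer_predicted").to_numpy()

    tp = int((called_cancer & y).sum())
    fn = int((~called_cancer & y).sum())
    fp = int((called_cancer & ~y).sum())
    tn = int((~called_cancer & ~y).sum())
    return {
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "n_second_step": int((results["step_reached"] == 2).sum()),
    }
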