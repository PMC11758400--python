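"""Probability-of-cancer (POC) index from the seven-marker PTM panel.

A binomial GLM with logit link maps the log10-transformed concentrations of
AFP, CA125, CA15-3, CA19-9, CA72-4, CEA and CYFRA 21-1 to a probability of
cancer in [0, 1].  Marker values are winsorized at the 99.9th percentile of
the training pool before the log transform (clinical analyzers saturate;
capping keeps the fit stable), and the caps are stored with the model so
scoring is reproducible.  A POC at or above 0.5 is a screen-positive call.

The slope coefficients are maximum-likelihood; the intercept is then
re-anchored (an offset recalibration) so that the 0.5 cutoff sits at a
chosen training-noncancer specificity — 91% by default, the operating
point the deployed test reports for its 0.5 cutoff.  A plain case-control
MLE fit would instead put the 0.5 cutoff at the posterior-0.5 boundary of
the roughly balanced training cohort, which is not how the screening test
is operated.  Pass ``anchor_specificity=None`` for the raw MLE intercept.

If the training cohort is perfectly separable the maximum-likelihood fit
diverges; in that case a ridge-penalized logistic fit is returned instead
and the model carries ``separation_flag=True``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .cohort import MARKERS

__all__ = ["POCModel", "fit_poc", "score_poc", "classify_poc", "save_poc_model",
           "load_poc_model", "POC_CUTOFF"]

POC_CUTOFF = 0.5

#: Training-noncancer specificity at which the 0.5 cutoff is anchored.
POC_ANCHOR_SPECIFICITY = 0.91

_WINSOR_Q = 0.999
_SEPARATION_COEF = 25.0  # |coef| on log10 scale beyond which MLE has diverged


@dataclass(frozen=True)
class POCModel:
    """Fitted POC scoring model (logistic regression on log10 markers)."""

    intercept: float
    coefficients: dict[str, float]          # one per marker, log10 scale
    winsor_caps: dict[str, float]           # per-marker upper caps (raw units)
    transform: str = "log10"
    separation_flag: bool = False

    def __post_init__(self):
        if set(self.coefficients) != set(MARKERS):
            raise ValueError(f"coefficients must cover exactly the markers {MARKERS}")
        if self.transform != "log10":
            raise ValueError("only the log10 transform is supported")


def _marker_matrix(records: pd.DataFrame, caps: dict[str, float]) -> np.ndarray:
    X = np.empty((len(records), len(MARKERS)))
    for j, m in enumerate(MARKERS):
        v = np.asarray(records[m], dtype=float)
        if (v <= 0).any():
            raise ValueError(f"nonpositive concentration for marker {m!r}: "
                             "log transform undefined")
        X[:, j] = np.log10(np.minimum(v, caps[m]))
    return X


def fit_poc(records: pd.DataFrame, seed: int = 0,
            anchor_specificity: float | None = POC_ANCHOR_SPECIFICITY) -> POCModel:
    """Fit the POC logistic model on a labeled cohort.

    ``records`` needs a ``group`` column ("cancer"/"noncancer") and the
    seven marker columns.  The fit is deterministic given the input; the
    ``seed`` argument is accepted for interface uniformity across the
    pipeline stages but the IRLS fit does not use randomness.

    ``anchor_specificity`` re-anchors the intercept so that POC = 0.5
    falls at that percentile (type-7) of the training-noncancer linear
    predictor; ``None`` keeps the raw MLE intercept.
    """
    del seed
    y = np.asarray(records["group"] == "cancer", dtype=float)
    if y.all() or not y.any():
        raise ValueError("training cohort must contain both cancer and noncancer")
    pool = records[list(MARKERS)].to_numpy(dtype=float)
    caps = {m: float(np.quantile(pool[:, j], _WINSOR_Q)) for j, m in enumerate(MARKERS)}
    X = _marker_matrix(records, caps)
    Xc = sm.add_constant(X, has_constant="add")

    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit()
        params = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(params)) or np.abs(params[1:]).max() > _SEPARATION_COEF:
            separated = True
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError):
        separated = True

    if separated:
        # ridge fallback keeps coefficients finite on separable data
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)
        clf.fit(X, y)
        params = np.concatenate([[clf.intercept_[0]], clf.coef_[0]])

    if anchor_specificity is not None:
        if not 0.0 < anchor_specificity < 1.0:
            raise ValueError("anchor_specificity must lie in (0, 1)")
        lin = X @ params[1:]
        params[0] = -float(np.quantile(lin[y == 0], anchor_specificity))

    return POCModel(
        intercept=float(params[0]),
        coefficients={m: float(params[1 + j]) for j, m in enumerate(MARKERS)},
        winsor_caps=caps,
        separation_flag=separated,
    )


def score_poc(model: POCModel, records) -> np.ndarray | float:
    """POC index for one record (Series/dict/ParticipantRecord) or a table.

    Returns a float for single-record input, else an array aligned with the
    rows.  Raises on nonpositive marker concentrations.
    """
    single = False
    if hasattr(records, "ptm"):  # ParticipantRecord
        records = pd.DataFrame([records.ptm])
        single = True
    elif isinstance(records, (pd.Series, dict)):
        records = pd.DataFrame([dict(records)])
        single = True
    X = _marker_matrix(records, model.winsor_caps)
    beta = np.array([model.coefficients[m] for m in MARKERS])
    lin = model.intercept + X @ beta
    poc = 1.0 / (1.0 + np.exp(-lin))
    return float(poc[0]) if single else poc


def classify_poc(poc, cutoff: float = POC_CUTOFF):
    """Screen call from a POC index: positive iff POC >= cutoff."""
    arr = np.asarray(poc, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("POC values must lie in [0, 1]")
    calls = np.where(arr >= cutoff, "positive", "negative")
    return str(calls[()]) if arr.ndim == 0 else calls


def save_poc_model(model: POCModel, path) -> None:
    payload = {
        "transform": model.transform,
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "winsor_caps": model.winsor_caps,
        "separation_flag": model.separation_flag,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_poc_model(path) -> POCModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return POCModel(
        intercept=payload["intercept"],
        coefficients=payload["coefficients"],
        winsor_caps=payload["winsor_caps"],
        transform=payload.get("transform", "log10"),
        separation_flag=payload.get("separation_flag", False),
    )
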