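"""Cancer risk score (CRS): weighted integration of five feature scores.

The CRS is a linear combination of the four cfDNA genomic feature scores
(CNA, FS, end motif, virus) and the protein-marker POC index:

    CRS_raw = a*cna + b*fs + c*endmotif + d*virus + e*poc

The five nonnegative weights are constrained to the unit simplex (sum 1) —
AUC is invariant to positive rescaling, so only the direction matters — and
chosen by exhaustive grid search on a step-0.05 lattice to maximize the
empirical (Mann-Whitney) AUC.  Before weighting, each feature is z-scored
against the training noncancer mean/SD so the weights are comparable across
feature scales.

The weighted score is then calibrated with a two-anchor affine map: the
training noncancer median goes to 0 and the noncancer 98th percentile
(type-7, linearly interpolated) goes to 2.0, so that CRS >= 2.0 is the
98%-specificity positive call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GENOMIC_FEATURES

__all__ = [
    "CRS_FEATURES", "CRS_CUTOFF", "CRS_TARGET_SPECIFICITY",
    "CRSWeights", "CRSCalibration", "CRSModel",
    "raw_crs", "weight_lattice", "grid_search_weights", "grid_search_leaderboard",
    "calibrate_crs", "classify_crs", "fit_crs", "score_crs",
    "save_crs_model", "load_crs_model",
]

#: CRS inputs in weight order (a..e): four genomic features, then the POC.
CRS_FEATURES = (*GENOMIC_FEATURES, "poc")

CRS_CUTOFF = 2.0
CRS_TARGET_SPECIFICITY = 0.98


@dataclass(frozen=True)
class CRSWeights:
    """Nonnegative CRS weights (a..e) on the unit simplex."""

    a: float  # cna
    b: float  # fs
    c: float  # endmotif
    d: float  # virus
    e: float  # poc (protein tumor markers)

    def __post_init__(self):
        w = self.as_array()
        if (w < 0).any():
            raise ValueError("CRS weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"CRS weights must sum to 1, got {w.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CRS_FEATURES, self.as_array()))


@dataclass(frozen=True)
class CRSCalibration:
    """Affine map putting the noncancer 98th percentile of the score at 2.0."""

    scale: float
    offset: float
    cutoff: float = CRS_CUTOFF
    target_specificity: float = CRS_TARGET_SPECIFICITY

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("calibration scale must be positive")

    def apply(self, raw_scores):
        return self.scale * np.asarray(raw_scores, dtype=float) + self.offset


def raw_crs(weights: CRSWeights, features) -> float | np.ndarray:
    """Weighted linear score: exact dot product of weights and features.

    ``features`` is a 5-vector ordered (cna, fs, endmotif, virus, poc), or
    an (n, 5) array of such rows.
    """
    x = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("CRS features must be finite")
    if x.shape[-1] != 5:
        raise ValueError("CRS expects 5 features (cna, fs, endmotif, virus, poc)")
    out = x @ weights.as_array()
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# grid search on the simplex lattice
# ---------------------------------------------------------------------------

def weight_lattice(step: float = 0.05) -> np.ndarray:
    """All nonnegative 5-tuples on the step-lattice summing to 1.

    Rows are sorted lexicographically in (a, b, c, d, e) order, which fixes
    the deterministic tie-break (first argmax = lexicographically smallest
    optimum).
    """
    k = round(1.0 / step)
    if abs(k * step - 1.0) > 1e-9 or k < 1:
        raise ValueError(f"step must divide 1 evenly, got {step!r}")
    # compositions of k into 5 nonnegative parts via stars and bars
    tuples = []
    for bars in combinations(range(k + 4), 4):
        prev = -1
        parts = []
        for b in bars:
            parts.append(b - prev - 1)
            prev = b
        parts.append(k + 3 - prev)
        tuples.append(parts)
    lat = np.array(tuples, dtype=float) / k
    order = np.lexsort(tuple(lat[:, j] for j in range(4, -1, -1)))
    return lat[order]


def _auc_rows(score_rows: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC for each row of an (r, n) score matrix."""
    y = labels.astype(bool)
    m = int(y.sum())
    n = int((~y).sum())
    ranks = stats.rankdata(score_rows, axis=1)
    r_pos = ranks[:, y].sum(axis=1)
    return (r_pos - m * (m + 1) / 2.0) / (m * n)


def grid_search_weights(features_by_subject, labels, step: float = 0.05) -> CRSWeights:
    """Exhaustive simplex-lattice search for the AUC-maximizing weights.

    ``features_by_subject`` is (n, 5) in CRS feature order; ``labels`` is
    boolean-like (True = cancer).  Ties break to the lexicographically
    smallest tuple.  Deterministic.
    """
    w, _ = _grid_search(features_by_subject, labels, step)
    return w


def grid_search_leaderboard(features_by_subject, labels, step: float = 0.05,
                            top: int = 10) -> pd.DataFrame:
    """Top weight tuples by AUC, for audit (columns a..e and auc)."""
    X, y = _check_grid_inputs(features_by_subject, labels)
    lat = weight_lattice(step)
    aucs = _auc_rows(lat @ X.T, y)
    # stable sort keeps lexicographic order within equal AUCs
    order = np.argsort(-aucs, kind="stable")[:top]
    rows = pd.DataFrame(lat[order], columns=["a", "b", "c", "d", "e"])
    rows["auc"] = aucs[order]
    return rows


def _check_grid_inputs(features_by_subject, labels):
    X = np.asarray(features_by_subject, dtype=float)
    y = np.asarray(labels, dtype=bool).ravel()
    if X.ndim != 2 or X.shape[1] != 5:
        raise ValueError("features_by_subject must be an (n, 5) array")
    if X.shape[0] != y.size:
        raise ValueError("features and labels must align")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 subjects per class for the grid search")
    return X, y


def _grid_search(features_by_subject, labels, step):
    X, y = _check_grid_inputs(features_by_subject, labels)
    lat = weight_lattice(step)
    aucs = _auc_rows(lat @ X.T, y)
    best = int(np.argmax(aucs))  # first max = lexicographically smallest
    w = lat[best]
    return CRSWeights(*w), float(aucs[best])


# ---------------------------------------------------------------------------
# calibration and classification
# ---------------------------------------------------------------------------

def calibrate_crs(raw_noncancer_scores, target_specificity: float = CRS_TARGET_SPECIFICITY,
                  cutoff: float = CRS_CUTOFF) -> CRSCalibration:
    """Affine calibration anchoring the noncancer score distribution.

    Maps the noncancer median to 0 and the noncancer ``target_specificity``
    percentile (type-7 interpolation) to ``cutoff``, so the fraction of
    training noncancer at or above the cutoff is at most
    ``1 - target_specificity`` up to 1/n percentile resolution.
    """
    scores = np.asarray(raw_noncancer_scores, dtype=float).ravel()
    if scores.size < 50:
        raise ValueError("calibration needs at least 50 noncancer scores "
                         f"(got {scores.size}) to resolve the upper percentile")
    med = float(np.quantile(scores, 0.5))
    upper = float(np.quantile(scores, target_specificity))
    if not upper > med:
        raise ValueError("degenerate noncancer scores: upper percentile does not "
                         "exceed the median, calibration is undefined")
    scale = cutoff / (upper - med)
    offset = -scale * med
    return CRSCalibration(scale=scale, offset=offset, cutoff=cutoff,
                          target_specificity=target_specificity)


def classify_crs(crs, cutoff: float = CRS_CUTOFF):
    """Positive iff CRS >= cutoff (inclusive boundary)."""
    arr = np.asarray(crs, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("CRS values must be finite")
    calls = np.where(arr >= cutoff, "positive", "negative")
    return str(calls[()]) if arr.ndim == 0 else calls


# ---------------------------------------------------------------------------
# fitted-model bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CRSModel:
    """Weights + feature standardization + calibration, as fitted."""

    weights: CRSWeights
    calibration: CRSCalibration
    feature_means: dict[str, float]   # noncancer means, per CRS feature
    feature_sds: dict[str, float]     # noncancer SDs, per CRS feature
    train_auc: float

    def standardize(self, feature_frame: pd.DataFrame) -> np.ndarray:
        X = np.empty((len(feature_frame), len(CRS_FEATURES)))
        for j, f in enumerate(CRS_FEATURES):
            X[:, j] = (np.asarray(feature_frame[f], dtype=float)
                       - self.feature_means[f]) / self.feature_sds[f]
        return X


def _feature_frame(records: pd.DataFrame, poc_scores) -> pd.DataFrame:
    frame = records[list(GENOMIC_FEATURES)].copy().reset_index(drop=True)
    frame["poc"] = np.asarray(poc_scores, dtype=float)
    return frame


def fit_crs(records: pd.DataFrame, poc_scores, step: float = 0.05) -> CRSModel:
    """Fit the CRS on a labeled cohort given per-subject POC scores.

    z-scores every feature against the noncancer subjects, grid-searches the
    simplex lattice for the AUC-maximizing weights, then calibrates the
    weighted score so the noncancer 98th percentile sits at 2.0.
    """
    y = np.asarray(records["group"] == "cancer", dtype=bool)
    frame = _feature_frame(records, poc_scores)
    nc = frame.loc[~y]
    means = {f: float(nc[f].mean()) for f in CRS_FEATURES}
    sds = {f: float(nc[f].std(ddof=1)) for f in CRS_FEATURES}
    for f, sd in sds.items():
        if not sd > 0:
            raise ValueError(f"feature {f!r} is constant among noncancer; cannot z-score")
    Z = np.column_stack([
        (frame[f].to_numpy(dtype=float) - means[f]) / sds[f] for f in CRS_FEATURES])
    weights, auc = _grid_search(Z, y, step)
    raw = Z @ weights.as_array()
    calibration = calibrate_crs(raw[~y])
    return CRSModel(weights=weights, calibration=calibration,
                    feature_means=means, feature_sds=sds, train_auc=auc)


def score_crs(model: CRSModel, records: pd.DataFrame, poc_scores) -> np.ndarray:
    """Calibrated CRS for each row of a cohort table."""
    frame = _feature_frame(records, poc_scores)
    Z = model.standardize(frame)
    return model.calibration.apply(Z @ model.weights.as_array())


def save_crs_model(model: CRSModel, path) -> None:
    payload = {
        "weights": model.weights.as_dict(),
        "calibration": {
            "scale": model.calibration.scale,
            "offset": model.calibration.offset,
            "cutoff": model.calibration.cutoff,
            "target_specificity": model.calibration.target_specificity,
        },
        "feature_means": model.feature_means,
        "feature_sds": model.feature_sds,
        "train_auc": model.train_auc,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_crs_model(path) -> CRSModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    w = payload["weights"]
    cal = payload["calibration"]
    return CRSModel(
        weights=CRSWeights(*(w[f] for f in CRS_FEATURES)),
        calibration=CRSCalibration(scale=cal["scale"], offset=cal["offset"],
                                   cutoff=cal["cutoff"],
                                   target_specificity=cal["target_specificity"]),
        feature_means=payload["feature_means"],
        feature_sds=payload["feature_sds"],
        train_auc=payload["train_auc"],
    )
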