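"""Synthetic case-control cohort generation for MCED model development.

Real multi-cancer early detection cohorts combine a panel of seven protein
tumor markers (PTMs: AFP, CA125, CA15-3, CA19-9, CA72-4, CEA, CYFRA 21-1)
with four cfDNA genomic feature scores derived from shallow whole-genome
sequencing (copy-number aberration, fragment size, end motif, oncogenic
virus).  This module simulates such a cohort at the level of per-sample
scores and concentrations, calibrated so that each feature's empirical
cancer-vs-noncancer AUC matches a configurable target.

Model
-----
* Genomic features are unit-variance Gaussian per subject.  Noncancer mean
  is 0; cancer mean is the binormal shift ``delta = sqrt(2) * Phi^-1(AUC)``
  so the theoretical AUC equals its target exactly.  Features share a latent
  "tumor burden" factor (equicorrelation ``feature_corr``), reflecting that
  cfDNA-derived signals co-vary with tumor fraction.
* PTM concentrations are log-normal around marker-specific healthy medians.
  Every cancer gets a mild continuous elevation of all markers
  (``cancer_continuous_shift`` in units of each marker's log10 SD), and
  each marker can additionally undergo a discrete "elevation" event whose
  probability increases with stage.  For cancer, the elevation indicator is
  coupled to the same latent burden factor through a probit link, so
  marker-positive cancers also tend to carry stronger genomic signal.
  Noncancer subjects have a small benign-elevation probability (clinical
  tumor markers are not perfectly specific); benign elevations cluster
  within a subject (a comorbidity affects several markers) but are driven
  by their own latent factor, independent of the genomic scores.

The cohort is returned as a :class:`pandas.DataFrame` with one row per
participant (columns ``COHORT_COLUMNS``); :class:`ParticipantRecord` is the
typed single-row view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MARKERS",
    "GENOMIC_FEATURES",
    "STAGES",
    "UPPER_REFERENCE_LIMITS",
    "COHORT_COLUMNS",
    "MarkerParams",
    "PTMParams",
    "CohortSpec",
    "ParticipantRecord",
    "binormal_shift",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Protein tumor markers, in panel order (CSV column names).
MARKERS = ("afp", "ca125", "ca153", "ca199", "ca724", "cea", "cyfra211")

#: cfDNA genomic feature scores, in CSV column order.
GENOMIC_FEATURES = ("cna", "fs", "endmotif", "virus")

#: Stage labels; "not_staged" covers malignancies outside AJCC staging
#: (e.g. leukemia), "missing" is an unrecorded stage.  Both count as cancer.
STAGES = ("I", "II", "III", "IV", "not_staged", "missing")

#: Clinical upper reference limits (assay units) used to define PTM
#: "positivity" (AFP ng/mL; CA markers U/mL; CEA ng/mL; CYFRA 21-1 ng/mL).
UPPER_REFERENCE_LIMITS = {
    "afp": 7.0,
    "ca125": 35.0,
    "ca153": 25.0,
    "ca199": 37.0,
    "ca724": 6.9,
    "cea": 5.0,
    "cyfra211": 3.3,
}

COHORT_COLUMNS = (
    "id", "group", "stage", "age", "sex",
    *MARKERS, *GENOMIC_FEATURES,
)

_FLOAT_FMT = "%.6g"  # cohort files carry 6 significant digits


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerParams:
    """Log-normal parameters for one protein tumor marker.

    ``log10_median``/``log10_sd`` describe the healthy (noncancer) baseline
    on the log10 scale; ``elevation_shift`` is the mean log10 increase when
    a cancer elevates the marker, with subject-level spread
    ``elevation_shift_sd``.
    """

    log10_median: float
    log10_sd: float
    elevation_shift: float
    elevation_shift_sd: float


def _default_marker_params() -> dict[str, MarkerParams]:
    # Healthy medians near the middle of clinical reference ranges; spread
    # chosen so only a small healthy tail crosses the upper reference limit.
    return {
        "afp":      MarkerParams(np.log10(3.0),  0.150, 1.0, 0.25),
        "ca125":    MarkerParams(np.log10(12.0), 0.165, 1.0, 0.25),
        "ca153":    MarkerParams(np.log10(12.0), 0.150, 1.0, 0.25),
        "ca199":    MarkerParams(np.log10(9.0),  0.225, 1.0, 0.25),
        "ca724":    MarkerParams(np.log10(2.0),  0.225, 1.0, 0.25),
        "cea":      MarkerParams(np.log10(2.0),  0.165, 1.0, 0.25),
        "cyfra211": MarkerParams(np.log10(1.8),  0.135, 1.0, 0.25),
    }


@dataclass(frozen=True)
class PTMParams:
    """Panel-level PTM simulation parameters.

    ``elevation_prob_by_stage`` gives the per-marker Bernoulli elevation
    probability for cancer subjects, indexed by stage (must be
    non-decreasing over I..IV so marker positivity rises with stage).
    ``noncancer_elevation_prob`` models benign elevations;
    ``noncancer_shift_scale`` shrinks the elevation shift for those.
    ``burden_corr`` couples cancer elevation events to the latent
    tumor-burden factor shared with the genomic features (0 = independent);
    noncancer elevations cluster through a separate benign factor.
    ``cancer_continuous_shift`` is the graded elevation every cancer adds
    to every marker, in units of that marker's baseline log10 SD.
    """

    markers: dict[str, MarkerParams] = field(default_factory=_default_marker_params)
    elevation_prob_by_stage: dict[str, float] = field(default_factory=lambda: {
        "I": 0.147, "II": 0.203, "III": 0.259, "IV": 0.343,
        "not_staged": 0.231, "missing": 0.231,
    })
    noncancer_elevation_prob: float = 0.05
    noncancer_shift_scale: float = 0.9
    burden_corr: float = 0.45
    cancer_continuous_shift: float = 0.25

    def validate(self) -> None:
        missing = set(MARKERS) - set(self.markers)
        if missing:
            raise ValueError(f"ptm_params missing markers: {sorted(missing)}")
        for st in STAGES:
            if st not in self.elevation_prob_by_stage:
                raise ValueError(f"elevation_prob_by_stage missing stage {st!r}")
            p = self.elevation_prob_by_stage[st]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"elevation probability for stage {st!r} not in [0,1]")
        if not 0.0 <= self.noncancer_elevation_prob <= 1.0:
            raise ValueError("noncancer_elevation_prob not in [0,1]")
        if not 0.0 <= self.burden_corr < 1.0:
            raise ValueError("burden_corr must be in [0,1)")


def _default_stage_probs() -> dict[str, float]:
    return {
        "I": 0.263, "II": 0.186, "III": 0.214, "IV": 0.222,
        "not_staged": 0.053, "missing": 0.062,
    }


def _default_auc_targets() -> dict[str, float]:
    return {"cna": 0.797, "fs": 0.865, "endmotif": 0.877, "virus": 0.654}


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of one synthetic case-control cohort.

    Defaults reproduce the reference cohort: 617 cancer / 580 noncancer,
    stage mix I 26.3% / II 18.6% / III 21.4% / IV 22.2% (plus 5.3% not
    expected to be staged and 6.2% missing), and genomic feature AUC
    targets CNA 0.797, FS 0.865, end motif 0.877, virus 0.654.
    """

    n_cancer: int = 617
    n_noncancer: int = 580
    stage_probs: dict[str, float] = field(default_factory=_default_stage_probs)
    feature_auc_targets: dict[str, float] = field(default_factory=_default_auc_targets)
    ptm_params: PTMParams = field(default_factory=PTMParams)
    feature_corr: float = 0.80
    age_mean_cancer: float = 56.0
    age_sd_cancer: float = 13.7
    age_mean_noncancer: float = 48.3
    age_sd_noncancer: float = 12.9
    male_frac_cancer: float = 0.569
    male_frac_noncancer: float = 0.510
    seed: int = 0

    def validate(self) -> None:
        if self.n_cancer <= 0 or self.n_noncancer <= 0:
            raise ValueError("n_cancer and n_noncancer must be positive")
        if set(self.stage_probs) != set(STAGES):
            raise ValueError(f"stage_probs must have exactly the keys {STAGES}")
        total = sum(self.stage_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage_probs must sum to 1 (got {total!r})")
        if any(p < 0 for p in self.stage_probs.values()):
            raise ValueError("stage probabilities must be nonnegative")
        if set(self.feature_auc_targets) != set(GENOMIC_FEATURES):
            raise ValueError(
                f"feature_auc_targets must have exactly the keys {GENOMIC_FEATURES}")
        for name, auc in self.feature_auc_targets.items():
            if not 0.5 <= auc < 1.0:
                raise ValueError(f"AUC target for {name!r} must lie in [0.5, 1)")
        if not 0.0 <= self.feature_corr < 1.0:
            raise ValueError("feature_corr must be in [0,1)")
        self.ptm_params.validate()


@dataclass(frozen=True)
class ParticipantRecord:
    """Typed view of one cohort row."""

    id: str
    group: str                      # "cancer" | "noncancer"
    stage: str | None               # None for noncancer
    age: float
    sex: str                        # "male" | "female"
    ptm: dict[str, float]           # marker -> concentration, strictly positive
    features: dict[str, float]      # feature -> score

    @classmethod
    def from_series(cls, row: pd.Series) -> "ParticipantRecord":
        stage = row["stage"]
        if stage is None or (isinstance(stage, float) and np.isnan(stage)) or stage == "":
            stage = None
        return cls(
            id=str(row["id"]), group=str(row["group"]), stage=stage,
            age=float(row["age"]), sex=str(row["sex"]),
            ptm={m: float(row[m]) for m in MARKERS},
            features={f: float(row[f]) for f in GENOMIC_FEATURES},
        )

    def to_series(self) -> pd.Series:
        data = {"id": self.id, "group": self.group,
                "stage": self.stage if self.stage is not None else "",
                "age": self.age, "sex": self.sex}
        data.update(self.ptm)
        data.update(self.features)
        return pd.Series(data)[list(COHORT_COLUMNS)]


# ---------------------------------------------------------------------------
# binormal calibration
# ---------------------------------------------------------------------------

def binormal_shift(auc_target: float) -> float:
    """Mean separation delta giving a theoretical binormal AUC.

    For two unit-variance Gaussian score distributions separated by
    ``delta``, AUC = Phi(delta / sqrt(2)); inverting gives
    ``delta = sqrt(2) * Phi^-1(AUC)``.

    Parameters
    ----------
    auc_target : float in [0.5, 1)

    Returns
    -------
    float
        Nonnegative mean separation (0 at AUC 0.5).
    """
    if not 0.5 <= auc_target < 1.0:
        raise ValueError(f"auc_target must lie in [0.5, 1), got {auc_target!r}")
    return float(np.sqrt(2.0) * stats.norm.ppf(auc_target))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Generate a seeded synthetic case-control cohort.

    Returns a DataFrame with ``COHORT_COLUMNS``; cancer rows first.  The
    output is a pure function of ``(spec, seed)`` — the same pair always
    yields an identical table.  ``seed`` overrides ``spec.seed`` when given.
    """
    spec = spec if spec is not None else CohortSpec()
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)

    n_ca, n_nc = spec.n_cancer, spec.n_noncancer
    n = n_ca + n_nc
    is_cancer = np.zeros(n, dtype=bool)
    is_cancer[:n_ca] = True

    stage_labels = list(STAGES)
    stage_p = np.array([spec.stage_probs[s] for s in stage_labels])
    stages_ca = rng.choice(stage_labels, size=n_ca, p=stage_p / stage_p.sum())
    stage_col = np.array([""] * n, dtype=object)
    stage_col[:n_ca] = stages_ca

    age = np.empty(n)
    age[:n_ca] = rng.normal(spec.age_mean_cancer, spec.age_sd_cancer, n_ca)
    age[n_ca:] = rng.normal(spec.age_mean_noncancer, spec.age_sd_noncancer, n_nc)
    age = np.clip(np.round(age, 1), 18.0, 95.0)

    male = np.empty(n, dtype=bool)
    male[:n_ca] = rng.random(n_ca) < spec.male_frac_cancer
    male[n_ca:] = rng.random(n_nc) < spec.male_frac_noncancer
    sex = np.where(male, "male", "female")

    # Latent tumor-burden factor shared by genomic features and PTM
    # elevations; N(0,1) in both groups so marginal feature variance is 1.
    burden = rng.standard_normal(n)

    rho = spec.feature_corr
    feat = {}
    for name in GENOMIC_FEATURES:
        delta = binormal_shift(spec.feature_auc_targets[name])
        eps = rng.standard_normal(n)
        x = np.sqrt(rho) * burden + np.sqrt(1.0 - rho) * eps
        x[:n_ca] += delta
        feat[name] = x

    pp = spec.ptm_params
    r = pp.burden_corr
    p_elev = np.full(n, pp.noncancer_elevation_prob)
    for st in STAGES:
        mask = np.zeros(n, dtype=bool)
        mask[:n_ca] = stages_ca == st
        p_elev[mask] = pp.elevation_prob_by_stage[st]
    shift_scale = np.where(is_cancer, 1.0, pp.noncancer_shift_scale)

    # Cancer elevations ride on the tumor-burden factor; benign (noncancer)
    # elevations cluster through their own factor, independent of genomics.
    benign = rng.standard_normal(n)
    elev_factor = np.where(is_cancer, burden, benign)

    ptm = {}
    for m in MARKERS:
        mp = pp.markers[m]
        z = rng.standard_normal(n)
        base = mp.log10_median + mp.log10_sd * z
        base[:n_ca] += pp.cancer_continuous_shift * mp.log10_sd
        # probit-coupled elevation: marginal P(elevated) = p_elev exactly
        eta = rng.standard_normal(n)
        latent = np.sqrt(r) * elev_factor + np.sqrt(1.0 - r) * eta
        elevated = latent > stats.norm.ppf(1.0 - p_elev)
        shift = np.maximum(
            mp.elevation_shift + mp.elevation_shift_sd * rng.standard_normal(n), 0.0)
        log10_val = base + elevated * shift * shift_scale
        ptm[m] = 10.0 ** log10_val

    df = pd.DataFrame({
        "id": [f"S{i + 1:05d}" for i in range(n)],
        "group": np.where(is_cancer, "cancer", "noncancer"),
        "stage": stage_col,
        "age": age,
        "sex": sex,
        **{m: ptm[m] for m in MARKERS},
        **{f: feat[f] for f in GENOMIC_FEATURES},
    }, columns=list(COHORT_COLUMNS))
    return df


# ---------------------------------------------------------------------------
# cohort file I/O (CSV, UTF-8, 6 significant digits)
# ---------------------------------------------------------------------------

def write_cohort(records: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (UTF-8, floats at 6 significant digits)."""
    missing = [c for c in COHORT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    df = records[list(COHORT_COLUMNS)]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


class CohortParseError(ValueError):
    """Raised when a cohort file fails schema or numeric validation."""


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, enforcing the schema written by :func:`write_cohort`.

    Raises :class:`CohortParseError` naming the offending row and column on
    a malformed header or a non-numeric cell.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if list(df.columns) != list(COHORT_COLUMNS):
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        extra = [c for c in df.columns if c not in COHORT_COLUMNS]
        raise CohortParseError(
            f"malformed cohort header: missing columns {missing}, unexpected {extra}")
    numeric_cols = ("age",) + MARKERS + GENOMIC_FEATURES
    out = df.copy()
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise CohortParseError(
                f"non-numeric value {df[col].iloc[row]!r} in row {row}, column {col!r}")
        out[col] = converted
    bad_group = ~out["group"].isin(["cancer", "noncancer"])
    if bad_group.any():
        row = int(bad_group.idxmax())
        raise CohortParseError(
            f"invalid group {out['group'].iloc[row]!r} in row {row}, column 'group'")
    for m in MARKERS:
        if len(out) and (out[m] <= 0).any():
            row = int((out[m] <= 0).idxmax())
            raise CohortParseError(
                f"nonpositive marker concentration in row {row}, column {m!r}")
    return out
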