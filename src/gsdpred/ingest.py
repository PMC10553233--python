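"""Cohort ingestion: exclusion filters, feature encoding, PMM imputation.

Reproduces the study's data-preparation stage: subjects flagged for
equipment error, heavily missing survey data, or missing balance-board data
are removed; the remaining subjects' 25 scalar features (age, sex, 19
survey responses, 4 grip measures) are encoded to a fixed numeric order;
subjects with 1-4 missing values are imputed by predictive mean matching
within chained equations, and subjects with more than 4 missing values are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schema
from .schema import (
    DIFFICULTY_LEVELS,
    FEATURE_ORDER,
    HEALTH_LEVELS,
    SEX_LEVELS,
    SURVEY_ITEMS,
    YESNO_LEVELS,
)

# Exclusion-reason priority when a subject carries several flags.
EXCLUSION_PRIORITY = ("equipment_error", "missing_survey", "missing_wbb")


@dataclass(frozen=True)
class ExclusionReport:
    """Counts of excluded subjects by (single, prioritized) reason."""

    n_input: int
    n_equipment_error: int
    n_missing_survey: int
    n_missing_wbb: int
    n_retained: int

    def __post_init__(self):
        total = (
            self.n_equipment_error + self.n_missing_survey + self.n_missing_wbb
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError("exclusion counts do not conserve subjects")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "equipment_error": self.n_equipment_error,
            "missing_survey": self.n_missing_survey,
            "missing_wbb": self.n_missing_wbb,
            "n_retained": self.n_retained,
        }


def apply_exclusions(roster: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove flagged subjects; count each under exactly one reason.

    Priority order equipment_error > missing_survey > missing_wbb decides the
    reported reason for multiply-flagged subjects.  Unable-to-complete
    subjects are retained (they are analyzed through the prediction
    override, not excluded).
    """
    if roster.empty:
        return roster.copy(), ExclusionReport(0, 0, 0, 0, 0)
    if roster["subject_id"].duplicated().any():
        dupes = roster.loc[roster["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject IDs: {dupes}")

    eq = roster["flag_equipment_error"].astype(bool)
    sv = roster["flag_missing_survey"].astype(bool) & ~eq
    wb = roster["flag_missing_wbb"].astype(bool) & ~eq & ~sv
    excluded = eq | sv | wb
    retained = roster.loc[~excluded].reset_index(drop=True)
    report = ExclusionReport(
        n_input=len(roster),
        n_equipment_error=int(eq.sum()),
        n_missing_survey=int(sv.sum()),
        n_missing_wbb=int(wb.sum()),
        n_retained=len(retained),
    )
    return retained, report


# ---------------------------------------------------------------------------
# Feature encoding
# ---------------------------------------------------------------------------

_HEALTH_CODE = {s: i for i, s in enumerate(HEALTH_LEVELS)}
_DIFFICULTY_CODE = {s: i for i, s in enumerate(DIFFICULTY_LEVELS)}
_YESNO_CODE = {s: i for i, s in enumerate(YESNO_LEVELS)}
_SEX_CODE = {s: i for i, s in enumerate(SEX_LEVELS)}


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        isinstance(value, str) and value.strip() == ""
    )


def _encode_one(name: str, kind: str, value):
    if _is_missing(value):
        return np.nan
    if kind in ("pass", "count"):
        v = float(value)
        if kind == "count" and (v < 0 or v != int(v)):
            raise ValueError(f"{name}: expected a non-negative integer count, got {value!r}")
        if kind == "pass" and v < 0:
            raise ValueError(f"{name}: negative value {value!r}")
        return v
    table = {
        "likert_health": _HEALTH_CODE,
        "likert_difficulty": _DIFFICULTY_CODE,
        "yesno": _YESNO_CODE,
        "sex": _SEX_CODE,
    }[kind]
    key = str(value).strip()
    if key not in table:
        raise ValueError(
            f"unrecognized response {value!r} for item {name!r}; "
            f"expected one of {sorted(table)}"
        )
    return float(table[key])


def encode_features(record) -> np.ndarray:
    """Encode one raw roster row into the canonical 25-feature vector.

    Order: age, sex (female=1), the 19 survey items, grip R1/L1/R2/L2 (kg).
    Likert responses map to 0-4, yes/no to 0/1; missing cells become NaN.
    An out-of-vocabulary response raises, naming the offending item.
    """
    kinds = {"age": "pass", "sex": "sex"}
    kinds.update({name: kind for name, kind in SURVEY_ITEMS})
    kinds.update({g: "pass" for g in schema.GRIP_COLUMNS})
    out = np.empty(len(FEATURE_ORDER))
    for j, name in enumerate(FEATURE_ORDER):
        out[j] = _encode_one(name, kinds[name], record[name])
    return out


def encode_cohort(roster: pd.DataFrame) -> pd.DataFrame:
    """Encode every roster row; returns a subject_id-indexed feature frame."""
    mat = np.vstack([encode_features(row) for _, row in roster.iterrows()])
    return pd.DataFrame(mat, columns=list(FEATURE_ORDER), index=roster["subject_id"])


def missingness_gate(encoded: np.ndarray) -> str:
    """Disposition by missing-value count: 0 -> complete, 1-4 -> impute, >4 -> exclude."""
    n_missing = int(np.isnan(np.asarray(encoded, dtype=float)).sum())
    if n_missing == 0:
        return "complete"
    if n_missing <= 4:
        return "impute"
    return "exclude"


# ---------------------------------------------------------------------------
# Predictive mean matching within chained equations
# ---------------------------------------------------------------------------

def impute_pmm(
    matrix,
    n_iterations: int = 10,
    n_donors: int = 5,
    seed: int = 0,
) -> pd.DataFrame | np.ndarray:
    """Impute missing cells by predictive mean matching (chained equations).

    Each incomplete column is regressed (OLS with intercept, complete cases)
    on all other columns; a missing cell receives the observed value of one
    of the ``n_donors`` donors whose fitted means are closest to its own
    fitted mean, chosen uniformly at random.  Columns are visited in order
    for ``n_iterations`` sweeps.  Missing cells are initialized at their
    column medians before the first sweep.

    Observed cells are never altered, and every imputed value is an observed
    value of its column (so imputations cannot leave the observed support).
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float, copy=True) if is_df else np.array(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    miss = np.isnan(X)
    if not miss.any():
        return matrix.copy() if is_df else X

    n, p = X.shape
    for j in range(p):
        if miss[:, j].all():
            name = matrix.columns[j] if is_df else j
            raise ValueError(f"column {name!r} has no observed values")
    row_missing = miss.sum(axis=1)
    if (row_missing > 4).any():
        raise ValueError("rows with more than 4 missing cells must be excluded, not imputed")

    rng = np.random.default_rng(seed)
    filled = X.copy()
    col_medians = np.nanmedian(X, axis=0)
    filled[miss] = np.take(col_medians, np.where(miss)[1])

    incomplete_cols = np.flatnonzero(miss.any(axis=0))
    for _ in range(n_iterations):
        for j in incomplete_cols:
            obs = ~miss[:, j]
            others = np.delete(np.arange(p), j)
            A = np.column_stack([np.ones(n), filled[:, others]])
            coef, *_ = np.linalg.lstsq(A[obs], X[obs, j], rcond=None)
            fitted = A @ coef
            donor_fit = fitted[obs]
            donor_val = X[obs, j]
            for i in np.flatnonzero(miss[:, j]):
                k = min(n_donors, len(donor_val))
                nearest = np.argpartition(np.abs(donor_fit - fitted[i]), k - 1)[:k]
                filled[i, j] = donor_val[rng.choice(nearest)]

    if is_df:
        return pd.DataFrame(filled, columns=matrix.columns, index=matrix.index)
    return filled


def ingest_cohort(
    roster: pd.DataFrame,
    n_iterations: int = 10,
    n_donors: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionReport]:
    """Full ingestion: exclusions, encoding, gate, single PMM imputation.

    Returns ``(features, retained_roster, report)`` where ``features`` is the
    completed subject x 25 matrix for subjects passing the missingness gate.
    Subjects gated out for excess missingness are dropped from both outputs
    (and folded into the report's missing_survey count).
    """
    retained, report = apply_exclusions(roster)
    encoded = encode_cohort(retained)
    disposition = encoded.apply(lambda r: missingness_gate(r.to_numpy()), axis=1)
    keep = disposition != "exclude"
    n_gated = int((~keep).sum())
    if n_gated:
        report = ExclusionReport(
            n_input=report.n_input,
            n_equipment_error=report.n_equipment_error,
            n_missing_survey=report.n_missing_survey + n_gated,
            n_missing_wbb=report.n_missing_wbb,
            n_retained=report.n_retained - n_gated,
        )
    retained = retained.loc[keep.to_numpy()].reset_index(drop=True)
    encoded = encoded.loc[keep]
    features = impute_pmm(encoded, n_iterations=n_iterations, n_donors=n_donors, seed=seed)
    return features, retained, report
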