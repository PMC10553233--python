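"""Cross-validated evaluation with per-fold selection and thresholding.

The evaluation mirrors the study design: subjects are randomly split into
10 like-sized folds (no stratification); within each fold's training set,
backward selection with AIC picks the scalar features, and the functional
model combining those features with one functional covariate is fitted on
the training subjects who completed their balance tests.  Held-out subjects
receive out-of-fold probabilities, with subjects unable to complete the
tests overridden to probability 1.0 (predicted GSD+).

A single classification threshold is then chosen on the pooled out-of-fold
probabilities as the smallest candidate threshold guaranteeing specificity
of at least 0.75, and specificity, sensitivity, accuracy, and AUC are
reported per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import fglm
from .features import ALL_SCOPES, KINDS
from .fglm import BasisSpec

SPECIFICITY_FLOOR = 0.75


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of each subject to one of k cross-validation folds."""

    assignments: np.ndarray  # fold index per subject, 0..k-1
    k: int
    seed: int

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.assignments == fold
        return ~test, test


def make_folds(n_subjects: int, k: int = 10, seed: int = 0) -> FoldPlan:
    """Random partition into k folds whose sizes differ by at most one."""
    if n_subjects < k:
        raise ValueError(f"cannot split {n_subjects} subjects into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_subjects)
    assignments = np.empty(n_subjects, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignments[chunk] = fold
    return FoldPlan(assignments=assignments, k=k, seed=seed)


@dataclass
class CVResult:
    """Out-of-fold probabilities and per-fold bookkeeping for one model."""

    probabilities: np.ndarray  # one out-of-fold probability per subject
    folds: FoldPlan
    selected: dict[int, list[str]]  # fold -> selected scalar features
    functional_key: tuple[str, str] | None = None
    fits: dict[int, fglm.FittedFGLM] = field(default_factory=dict)


def cross_validate(
    features: pd.DataFrame,
    y: np.ndarray,
    unable: np.ndarray,
    functional: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
    basis: BasisSpec | None = None,
    ridge_penalty: float = 1e-4,
    folds: FoldPlan | None = None,
    selected_per_fold: dict[int, list[str]] | None = None,
    functional_key: tuple[str, str] | None = None,
) -> CVResult:
    """K-fold cross-validation of one model (scalar-only or one functional).

    Unable-to-complete subjects are assigned to folds and scored through
    the probability-1 override but never enter model fitting.  Pass
    ``selected_per_fold`` to reuse scalar selections across models sharing
    the same folds (the scalar selection step does not depend on the
    functional covariate).
    """
    y = np.asarray(y, dtype=float)
    unable = np.asarray(unable, dtype=bool)
    n = len(y)
    if folds is None:
        folds = make_folds(n, k=k, seed=seed)
    if basis is None:
        basis = BasisSpec()

    probs = np.full(n, np.nan)
    selected_out: dict[int, list[str]] = {}
    fits: dict[int, fglm.FittedFGLM] = {}
    for fold in range(folds.k):
        train, test = folds.train_test(fold)
        fit_mask = train & ~unable
        classes = np.unique(y[fit_mask])
        if len(classes) < 2:
            raise RuntimeError(
                f"fold {fold}: training set contains a single class "
                f"({int(fit_mask.sum())} subjects, labels {classes}); "
                "cannot fit a classifier"
            )
        if selected_per_fold is not None:
            selected = selected_per_fold[fold]
        else:
            selected, _ = fglm.backward_select_aic(features.loc[fit_mask], y[fit_mask])
        selected_out[fold] = list(selected)

        func_train = functional[fit_mask] if functional is not None else None
        fit = fglm.fit_with_functional(
            features.loc[fit_mask], selected, func_train, y[fit_mask],
            basis=basis, ridge_penalty=ridge_penalty,
        )
        fits[fold] = fit

        for i in np.flatnonzero(test):
            probs[i] = fglm.predict_probability(
                fit,
                features.iloc[i][selected].to_numpy(float),
                functional[i] if functional is not None else None,
                unable_flag=bool(unable[i]),
            )
    assert not np.isnan(probs).any()
    return CVResult(
        probabilities=probs, folds=folds, selected=selected_out,
        functional_key=functional_key, fits=fits,
    )


def threshold_for_specificity(
    probabilities: np.ndarray, y: np.ndarray, floor: float = SPECIFICITY_FLOOR
) -> float:
    """Smallest threshold giving specificity >= floor (predict GSD+ iff p > c).

    Candidates are {0} plus the observed probabilities; because specificity
    is non-decreasing in the threshold, the smallest qualifying candidate
    maximizes sensitivity subject to the floor.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    y = np.asarray(y, dtype=float)
    neg = probabilities[y == 0]
    if len(neg) == 0:
        raise ValueError("no negative-class subjects: specificity undefined")
    for c in np.concatenate([[0.0], np.unique(probabilities)]):
        spec = np.mean(neg <= c)
        if spec >= floor:
            return float(c)
    return float(np.max(probabilities))  # unreachable: max prob always qualifies


def classification_metrics(
    probabilities: np.ndarray, y: np.ndarray, threshold: float
) -> dict[str, float]:
    """Specificity, sensitivity, accuracy, and AUC at the given threshold.

    AUC is the rank (pair-counting) estimator with ties counted one half —
    the probability a random positive outranks a random negative.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute metrics")
    pred = probabilities > threshold
    pos, neg = y == 1, y == 0
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[neg]))
    acc = float(np.mean(pred == pos))
    auc = float(roc_auc_score(y, probabilities))
    return {"specificity": spec, "sensitivity": sens, "accuracy": acc, "auc": auc}


def model_rows() -> list[tuple[str, str] | None]:
    """The 21 evaluated models: 20 functional covariates plus scalar-only."""
    rows: list[tuple[str, str] | None] = [
        (scope, kind) for kind in KINDS for scope in ALL_SCOPES
    ]
    rows.append(None)
    return rows


def evaluate_models(
    features: pd.DataFrame,
    y: np.ndarray,
    unable: np.ndarray,
    functional: dict[tuple[str, str], np.ndarray],
    k: int = 10,
    seed: int = 0,
    basis: BasisSpec | None = None,
    ridge_penalty: float = 1e-4,
    floor: float = SPECIFICITY_FLOOR,
    models: list | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cross-validate every requested model and tabulate its metrics.

    The fold plan and the per-fold scalar selections are shared across
    models (selection uses scalars only).  Returns the per-model metric
    table and {model: CVResult}.
    """
    n = len(y)
    folds = make_folds(n, k=k, seed=seed)
    base = cross_validate(
        features, y, unable, None, basis=basis, ridge_penalty=ridge_penalty,
        folds=folds,
    )
    selected_per_fold = base.selected
    if models is None:
        models = model_rows()

    rows, results = [], {}
    for key in models:
        if key is None:
            res = base
            label = ("non-WBB only", "")
        else:
            res = cross_validate(
                features, y, unable, functional[key], basis=basis,
                ridge_penalty=ridge_penalty, folds=folds,
                selected_per_fold=selected_per_fold, functional_key=key,
            )
            label = key
        thr = threshold_for_specificity(res.probabilities, y, floor=floor)
        metrics = classification_metrics(res.probabilities, y, thr)
        rows.append({"scope": label[0], "kind": label[1], "threshold": thr, **metrics})
        results[key] = res
    return pd.DataFrame(rows), results
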