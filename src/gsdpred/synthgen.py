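"""Synthetic cohort generator: balance-board sway traces plus a roster table.

The study whose analysis this package reimplements did not deposit its raw
data, so every downstream stage is exercised on synthetic cohorts with the
same statistical structure: two classes (self-identified users and non-users
of a gait-stabilizing device, GSD+ / GSD-) whose center-of-pressure sway
velocity differs inside an early time window of each 30 s balance test, and
whose age, grip strength and survey responses show class shifts shaped like
the study's characteristics table.

Sway model
----------
Per axis, positions follow a discrete-time mean-reverting Gaussian step
process (an AR(1) walk):

    x_i = (1 - kappa) * x_{i-1} + e_i,   e_i ~ N(0, s_i^2),  x_0 = 0

at the board's ~0.02 s sampling interval.  The step scale ``s_i`` is
``baseline_sd`` times a per-pose difficulty multiplier and a per-subject
log-normal sway multiplier, and is additionally multiplied by the subject's
within-window effect (log-normal around 1 for GSD-, around
``class_velocity_ratio`` for GSD+) while the sample time lies inside
``effect_window``.  This gives a stationary, bounded-in-practice process
whose instantaneous velocity scale — the quantity the downstream functional
covariates measure — is directly controllable, with the between-subject
heterogeneity real cohorts show.  Positions are clipped to
+/- ``board_halfwidth``.

Questionnaire responses are ordinal draws from thresholded Gaussian latent
variables with class-specific means; binary items are Bernoulli with
class-specific rates; fall counts are shifted Poisson conditional on having
fallen.  All survey items share a per-subject frailty factor through a
Gaussian copula, so they are positively correlated within subject while
keeping their configured marginal rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import norm as _norm

from . import schema
from .schema import LABEL_NEGATIVE, LABEL_POSITIVE, POSES


@dataclass(frozen=True)
class BalanceTrace:
    """One 30 s balance test: timestamps (s) and X/Y board coordinates."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pose: str
    trial: int
    subject_id: str | None = None

    def __post_init__(self):
        if self.pose not in POSES:
            raise ValueError(f"unknown pose {self.pose!r}; expected one of {POSES}")
        if self.trial not in (1, 2):
            raise ValueError(f"trial must be 1 or 2, got {self.trial}")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")

    def __len__(self) -> int:
        return len(self.t)


# Per-pose step-scale multipliers: closing the eyes and narrowing the stance
# both make quiet standing harder, so sway grows monotonically over the four
# poses. A single multiplier per pose is all the generator models.
DEFAULT_POSE_SCALE = {"EO_FA": 1.0, "EO_FT": 1.2, "EC_FA": 1.3, "EC_FT": 1.5}


@dataclass(frozen=True)
class SwayParams:
    """Parameters of the sway-trace process (board units, seconds)."""

    sampling_interval: float = 0.02
    duration: float = 30.0
    baseline_sd: float = 0.1
    class_velocity_ratio: float = 2.0
    effect_window: tuple[float, float] = (2.0, 6.5)
    mean_reversion: float = 0.02
    board_halfwidth: float = 20.0
    pose_scale: dict = field(default_factory=lambda: dict(DEFAULT_POSE_SCALE))
    # sd of the log per-subject sway multiplier: postural stability varies
    # widely between individuals, and without it any class velocity ratio
    # above 1 becomes almost perfectly separable once 8 tests are averaged
    subject_scale_sigma: float = 0.4
    # sd of the log per-subject within-window effect multiplier around its
    # class mean (1 for GSD-, class_velocity_ratio for GSD+): individual
    # class effects overlap, as they do in real cohorts — without this the
    # in-window/out-of-window sway contrast identifies the class exactly
    effect_sigma: float = 0.35

    def __post_init__(self):
        n_steps = self.duration / self.sampling_interval
        if not np.isclose(n_steps, round(n_steps)) or n_steps <= 0:
            raise ValueError("duration must be a positive multiple of sampling_interval")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")
        if self.class_velocity_ratio < 1:
            raise ValueError("class_velocity_ratio must be >= 1")
        lo, hi = self.effect_window
        if not (0 <= lo < hi <= self.duration):
            raise ValueError("effect_window must be a nonempty subinterval of [0, duration]")
        if not (0 <= self.mean_reversion < 1):
            raise ValueError("mean_reversion must be in [0, 1)")
        if self.board_halfwidth <= 0:
            raise ValueError("board_halfwidth must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.sampling_interval)) + 1


def simulate_cop_trace(
    label: str,
    pose: str,
    params: SwayParams | None = None,
    seed: int = 0,
    trial: int = 1,
    subject_id: str | None = None,
    subject_scale: float = 1.0,
    subject_effect: float | None = None,
) -> BalanceTrace:
    """Simulate one balance test trace for a subject of the given class.

    ``subject_scale`` is the subject's individual sway multiplier (drawn
    once per subject by :func:`simulate_cohort`), applied on top of
    ``baseline_sd``; ``subject_effect`` is the subject's within-window step
    multiplier, defaulting to the deterministic class value (1 for GSD-,
    ``class_velocity_ratio`` for GSD+).  Deterministic in its arguments:
    the same call always produces the identical trace.
    """
    if params is None:
        params = SwayParams()
    if subject_scale <= 0:
        raise ValueError("subject_scale must be > 0")
    if subject_effect is not None and subject_effect <= 0:
        raise ValueError("subject_effect must be > 0")
    if label not in (LABEL_POSITIVE, LABEL_NEGATIVE):
        raise ValueError(f"unknown class label {label!r}")
    if pose not in POSES:
        raise ValueError(f"unknown pose {pose!r}; expected one of {POSES}")

    rng = np.random.default_rng(seed)
    n_steps = params.n_samples - 1
    dt = params.sampling_interval
    t = np.arange(params.n_samples) * dt

    sd = np.full(
        n_steps, params.baseline_sd * subject_scale * params.pose_scale.get(pose, 1.0)
    )
    if subject_effect is None:
        subject_effect = params.class_velocity_ratio if label == LABEL_POSITIVE else 1.0
    if subject_effect != 1.0:
        t_step = t[1:]  # step i produces the sample at its right endpoint
        lo, hi = params.effect_window
        sd[(t_step >= lo) & (t_step <= hi)] *= subject_effect

    steps = rng.standard_normal((2, n_steps)) * sd
    phi = 1.0 - params.mean_reversion
    # AR(1) recursion x_i = phi*x_{i-1} + e_i via an IIR filter, per axis.
    pos = lfilter([1.0], [1.0, -phi], steps, axis=1)
    pos = np.clip(pos, -params.board_halfwidth, params.board_halfwidth)
    x = np.concatenate([[0.0], pos[0]])
    y = np.concatenate([[0.0], pos[1]])
    return BalanceTrace(t=t, x=x, y=y, pose=pose, trial=trial, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Roster generation
# ---------------------------------------------------------------------------

# Latent-Gaussian cutpoints shared by all 5-level ordinal items.
_ORDINAL_CUTS = np.array([-1.5, -0.5, 0.5, 1.5])

# Per-item generative parameters, shaped to the study's characteristics
# table: (GSD- latent mean, GSD+ latent mean) for ordinal items, (GSD- yes
# rate, GSD+ yes rate) for binary items, (GSD- rate, GSD+ rate) of a shifted
# Poisson for counts. health_rating runs 0=Poor..4=Excellent (non-users
# healthier); difficulty items run 0=None..4=Unable (users worse).
DEFAULT_ITEM_PARAMS: dict[str, tuple[float, float]] = {
    "near_fall_past_year": (0.477, 0.619),
    "n_near_falls": (0.6, 1.2),
    "fallen_past_year": (0.284, 0.598),
    "n_falls": (0.5, 1.0),
    "fall_inside_home": (0.174, 0.536),
    "fall_outside_home": (0.128, 0.124),
    "fall_in_community": (0.073, 0.093),
    "diff_shopping": (0.009, 0.155),
    "diff_managing_money": (0.01, 0.041),
    "diff_walking_across_room": (0.018, 0.062),
    "diff_light_housework": (0.01, 0.082),
    "diff_bathing": (0.009, 0.330),
    "health_rating": (0.9, 0.0),
    "diff_stooping": (-0.7, 0.7),
    "diff_lifting_10lb": (-1.2, -0.3),
    "diff_reaching_overhead": (-1.8, -1.0),
    "diff_writing_grasping": (-1.6, -0.8),
    "diff_walking_quarter_mile": (-1.2, 0.0),
    "diff_heavy_housework": (-0.3, 0.9),
}


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic roster.

    Defaults reproduce the study's participant flow: 268 consented, 21
    flagged for equipment error, 39 for missing survey data, 2 for missing
    balance-board data, with roughly balanced classes among the remainder.
    """

    n_subjects: int = 268
    prevalence: float = 0.47
    missing_rate: float = 0.01
    n_equipment_error: int = 21
    n_missing_survey_heavy: int = 39
    n_missing_wbb: int = 2
    unable_rate: float = 0.05
    unable_in_negative: bool = False
    age_loc: tuple[float, float] = (79.0, 87.0)  # (GSD-, GSD+) means, years
    age_sd: float = 6.0
    grip_loc: tuple[float, float] = (24.0, 16.0)  # right-hand mean, kg
    grip_sd: float = 6.5
    female_rate: tuple[float, float] = (0.633, 0.680)
    item_params: dict = field(default_factory=lambda: dict(DEFAULT_ITEM_PARAMS))
    frailty_loading: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        for r in (self.missing_rate, self.unable_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must be in [0, 1]")
        n_flag = self.n_equipment_error + self.n_missing_survey_heavy + self.n_missing_wbb
        if min(self.n_equipment_error, self.n_missing_survey_heavy, self.n_missing_wbb) < 0:
            raise ValueError("flag counts must be non-negative")
        if n_flag > self.n_subjects:
            raise ValueError(
                f"flag counts ({n_flag}) exceed n_subjects ({self.n_subjects})"
            )


def simulate_roster(params: CohortParams | None = None) -> pd.DataFrame:
    """Simulate a cohort roster with class labels, flags, and raw responses.

    Returns one row per subject: ``subject_id``, ``gsd_label``, the four
    exclusion/override flags, and the 25 raw feature columns (survey items
    as vocabulary strings, grips in kg).  Missing cells are NaN.
    """
    if params is None:
        params = CohortParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects

    labels = np.where(rng.random(n) < params.prevalence, LABEL_POSITIVE, LABEL_NEGATIVE)
    pos = labels == LABEL_POSITIVE
    cls = pos.astype(int)  # index into (GSD-, GSD+) parameter pairs

    age = np.clip(np.round(rng.normal(np.take(params.age_loc, cls), params.age_sd)), 70, 100)
    sex_female = rng.random(n) < np.take(params.female_rate, cls)

    grip_base = np.maximum(rng.normal(np.take(params.grip_loc, cls), params.grip_sd), 2.0)
    grips = {}
    for col, offset in zip(schema.GRIP_COLUMNS, (0.0, -2.0, 0.3, -1.8)):
        grips[col] = np.round(np.maximum(grip_base + offset + rng.normal(0, 1.5, n), 2.0), 1)

    data = {
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "gsd_label": labels,
        "age": age,
        "sex": np.where(sex_female, "Female", "Male"),
    }

    # Survey items share a per-subject frailty factor through a Gaussian
    # copula: marginal rates stay at their configured (characteristics-table
    # shaped) values, but items are positively correlated within subject, as
    # real functional-status questionnaires are.
    lam = params.frailty_loading
    frailty = rng.standard_normal(n)

    def item_z():
        return lam * frailty + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)

    fallen = np.zeros(n, dtype=bool)
    near_fallen = np.zeros(n, dtype=bool)
    for name, kind in schema.SURVEY_ITEMS:
        p_minus, p_plus = params.item_params[name]
        par = np.where(pos, p_plus, p_minus)
        if kind == "yesno":
            # yes iff the subject's copula uniform falls in the top par mass:
            # frailer subjects are likelier to report the adverse item
            vals = _norm.cdf(item_z()) > 1.0 - par
            if name == "fallen_past_year":
                fallen = vals
            elif name == "near_fall_past_year":
                near_fallen = vals
            # fall-location items only make sense for subjects who fell
            if name.startswith("fall_"):
                vals = vals & fallen
            data[name] = np.where(vals, "Yes", "No")
        elif kind == "count":
            gate = fallen if name == "n_falls" else near_fallen
            vals = np.where(gate, 1 + rng.poisson(par), 0)
            data[name] = vals
        else:  # ordinal likert via thresholded latent Gaussian
            sign = -1.0 if kind == "likert_health" else 1.0  # health runs good-high
            latent = par + sign * item_z()
            data[name] = np.searchsorted(_ORDINAL_CUTS, latent)
    data.update(grips)

    roster = pd.DataFrame(data)

    # Ordinal codes -> vocabulary strings for the raw roster.
    for name, kind in schema.SURVEY_ITEMS:
        if kind == "likert_health":
            roster[name] = np.take(schema.HEALTH_LEVELS, roster[name].to_numpy())
        elif kind == "likert_difficulty":
            roster[name] = np.take(schema.DIFFICULTY_LEVELS, roster[name].to_numpy())

    # Exclusion flags on disjoint subjects.
    for col in schema.FLAG_COLUMNS:
        roster[col] = 0
    n_flag = params.n_equipment_error + params.n_missing_survey_heavy + params.n_missing_wbb
    flagged = rng.choice(n, size=n_flag, replace=False)
    i0 = params.n_equipment_error
    i1 = i0 + params.n_missing_survey_heavy
    roster.loc[flagged[:i0], "flag_equipment_error"] = 1
    roster.loc[flagged[i0:i1], "flag_missing_survey"] = 1
    roster.loc[flagged[i1:], "flag_missing_wbb"] = 1

    # Unable-to-complete: an override, not an exclusion. By default only
    # GSD+ subjects (a user of a stabilizing device is far more likely to be
    # unable to stand unassisted for 30 s).
    unflagged = roster[list(schema.FLAG_COLUMNS[:3])].sum(axis=1).to_numpy() == 0
    eligible = unflagged & (pos | params.unable_in_negative)
    unable = eligible & (rng.random(n) < params.unable_rate)
    roster.loc[unable, "flag_unable_to_complete"] = 1

    # Missingness. Survey-heavy flagged subjects get >4 empty survey cells
    # (the reason they are excluded); retained subjects get MCAR missingness
    # at missing_rate, capped at 4 cells so they remain imputable.
    imputable_cols = list(schema.FEATURE_ORDER)
    survey_cols = [c for c, _ in schema.SURVEY_ITEMS]
    heavy = roster["flag_missing_survey"].to_numpy() == 1
    for i in np.flatnonzero(heavy):
        cols = rng.choice(survey_cols, size=6, replace=False)
        roster.loc[i, cols] = np.nan
    if params.missing_rate > 0:
        mask = rng.random((n, len(imputable_cols))) < params.missing_rate
        mask[~unflagged] = False
        for i in np.flatnonzero(mask.any(axis=1)):
            cols = np.flatnonzero(mask[i])
            if len(cols) > 4:
                cols = rng.choice(cols, size=4, replace=False)
            roster.loc[i, [imputable_cols[j] for j in cols]] = np.nan

    return roster


def simulate_cohort(
    cohort_params: CohortParams | None = None,
    sway_params: SwayParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full dataset: roster plus 8 traces per testable subject.

    Subjects flagged for missing balance-board data or unable to complete
    get no traces.  Pose order is randomized per subject and repeated in the
    same order for the second trial, mirroring the study protocol.  Returns
    ``(roster, traces)`` where ``traces[(subject_id, pose, trial)]`` is a
    :class:`BalanceTrace`.
    """
    if cohort_params is None:
        cohort_params = CohortParams()
    if sway_params is None:
        sway_params = SwayParams()
    roster = simulate_roster(cohort_params)
    rng = np.random.default_rng(np.random.default_rng(cohort_params.seed).integers(2**31))

    traces: dict[tuple[str, str, int], BalanceTrace] = {}
    pose_orders = {}
    for _, row in roster.iterrows():
        sid = row["subject_id"]
        if row["flag_missing_wbb"] or row["flag_unable_to_complete"]:
            continue
        order = list(rng.permutation(POSES))
        pose_orders[sid] = order
        scale = float(np.exp(sway_params.subject_scale_sigma * rng.standard_normal()))
        log_ratio = (
            np.log(sway_params.class_velocity_ratio)
            if row["gsd_label"] == LABEL_POSITIVE else 0.0
        )
        effect = float(np.exp(log_ratio + sway_params.effect_sigma * rng.standard_normal()))
        for trial in (1, 2):
            for pose in order:
                seed = int(rng.integers(2**31))
                traces[(sid, pose, trial)] = simulate_cop_trace(
                    row["gsd_label"], pose, sway_params, seed=seed,
                    trial=trial, subject_id=sid, subject_scale=scale,
                    subject_effect=effect,
                )
    roster.attrs["pose_orders"] = pose_orders
    return roster, traces
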