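"""Center-of-pressure functional covariates.

Each 30 s balance trace (X/Y board coordinates at ~0.02 s) is turned into
squared-magnitude velocity and acceleration curves on a common 0.1 s grid
(300 points: 0.1, 0.2, ..., 30.0 s):

* velocity  = per-axis first difference / local time step (board-units/s),
  assigned to the right endpoint of each step;
* acceleration = first difference of velocity / local time step
  (board-units/s^2);
* each series is subsampled to the grid by nearest-timestamp lookup, then
  the two axes are squared and summed pointwise, giving a non-negative
  curve v_x(t)^2 + v_y(t)^2.

Per subject this yields 20 functional covariates: one per test (4 poses x 2
trials), a trial-1 aggregate, and a both-trials aggregate — for velocity and
acceleration each.  Aggregates are pointwise means, which keeps them on the
same scale as single tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import POSES
from .synthgen import BalanceTrace

GRID_STEP = 0.1
DURATION = 30.0
N_GRID = int(round(DURATION / GRID_STEP))  # 300
GRID = np.round(np.arange(1, N_GRID + 1) * GRID_STEP, 10)

# Scope labels for the 20-covariate set.
SINGLE_SCOPES = tuple(f"{pose}_t{trial}" for trial in (1, 2) for pose in POSES)
AGG_SCOPES = ("trial1", "both")
ALL_SCOPES = SINGLE_SCOPES + AGG_SCOPES
KINDS = ("velocity", "acceleration")


@dataclass(frozen=True)
class FunctionalCovariate:
    """A 300-point squared-magnitude velocity or acceleration curve."""

    grid: np.ndarray
    values: np.ndarray
    kind: str
    scope: str

    def __post_init__(self):
        if len(self.values) != N_GRID:
            raise ValueError(f"expected {N_GRID} grid values, got {len(self.values)}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")


@dataclass(frozen=True)
class TimeSeries:
    """An irregular 2-axis series (e.g. velocity) with its timestamps."""

    t: np.ndarray
    vx: np.ndarray
    vy: np.ndarray


def differentiate(trace: BalanceTrace) -> tuple[TimeSeries, TimeSeries]:
    """First and second finite differences of a trace, per axis.

    Velocity is the change in X and Y per local time step, assigned to the
    right endpoint; acceleration is the same operation applied to velocity.
    Output lengths are n-1 and n-2 for an n-sample trace.
    """
    t = np.asarray(trace.t, dtype=float)
    if len(t) < 3:
        raise ValueError("trace too short to differentiate twice")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise ValueError("timestamps must be strictly increasing")
    vx = np.diff(trace.x) / dt
    vy = np.diff(trace.y) / dt
    vel = TimeSeries(t=t[1:], vx=vx, vy=vy)
    dt2 = np.diff(vel.t)
    acc = TimeSeries(t=vel.t[1:], vx=np.diff(vel.vx) / dt2, vy=np.diff(vel.vy) / dt2)
    return vel, acc


def resample_to_grid(
    series: TimeSeries,
    grid_step: float = GRID_STEP,
    duration: float = DURATION,
    tolerance: float = 0.2,
    name: str = "series",
) -> np.ndarray:
    """Subsample a series to the regular grid by nearest timestamp.

    Returns a (n_grid, 2) array.  Ties between two equally near samples go
    to the earlier one.  A series that stops more than ``tolerance`` seconds
    short of ``duration`` is rejected.
    """
    t = np.asarray(series.t, dtype=float)
    if t[-1] < duration - tolerance:
        raise ValueError(
            f"{name}: series ends at {t[-1]:.3f} s, short of {duration} s "
            f"(tolerance {tolerance} s)"
        )
    n_grid = int(round(duration / grid_step))
    grid = np.arange(1, n_grid + 1) * grid_step
    # nearest sample; on a tie prefer the earlier (left) sample
    right = np.searchsorted(t, grid, side="left")
    right = np.clip(right, 0, len(t) - 1)
    left = np.clip(right - 1, 0, len(t) - 1)
    choose_left = (grid - t[left]) <= (t[right] - grid)
    idx = np.where(choose_left & (right > 0), left, right)
    return np.column_stack([series.vx[idx], series.vy[idx]])


def squared_magnitude(gridded: np.ndarray) -> np.ndarray:
    """Pointwise squared magnitude v_x(t)^2 + v_y(t)^2 of a gridded 2-axis series."""
    gridded = np.asarray(gridded, dtype=float)
    if gridded.ndim != 2 or gridded.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array, got shape {gridded.shape}")
    return gridded[:, 0] ** 2 + gridded[:, 1] ** 2


def aggregate(covariates: list[FunctionalCovariate], scope: str) -> FunctionalCovariate:
    """Pointwise mean of covariates of one kind on a common grid."""
    if not covariates:
        raise ValueError("need at least one covariate to aggregate")
    kinds = {c.kind for c in covariates}
    if len(kinds) > 1:
        raise ValueError(f"cannot aggregate mixed kinds {sorted(kinds)}")
    for c in covariates[1:]:
        if not np.array_equal(c.grid, covariates[0].grid):
            raise ValueError("covariates must share a common grid")
    values = np.mean([c.values for c in covariates], axis=0)
    return FunctionalCovariate(
        grid=covariates[0].grid, values=values, kind=covariates[0].kind, scope=scope
    )


def trace_covariates(trace: BalanceTrace) -> dict[str, FunctionalCovariate]:
    """Velocity and acceleration squared-magnitude covariates of one trace."""
    vel, acc = differentiate(trace)
    scope = f"{trace.pose}_t{trace.trial}"
    out = {}
    for kind, series in (("velocity", vel), ("acceleration", acc)):
        gridded = resample_to_grid(series, name=f"{trace.subject_id or '?'}/{scope}/{kind}")
        out[kind] = FunctionalCovariate(
            grid=GRID.copy(), values=squared_magnitude(gridded), kind=kind, scope=scope
        )
    return out


def build_functional_set(traces: dict) -> dict[tuple[str, str], FunctionalCovariate]:
    """Build a subject's 20 functional covariates from their 8 traces.

    ``traces`` maps (pose, trial) -> BalanceTrace for all 4 poses x 2
    trials.  Returns {(scope, kind): covariate} with 8 single-test scopes
    plus 'trial1' and 'both' aggregates, per kind.
    """
    expected = {(pose, trial) for pose in POSES for trial in (1, 2)}
    missing = expected - set(traces)
    if missing:
        raise ValueError(f"missing traces for tests: {sorted(missing)}")

    out: dict[tuple[str, str], FunctionalCovariate] = {}
    for (pose, trial), trace in traces.items():
        if (pose, trial) not in expected:
            raise ValueError(f"unexpected test key {(pose, trial)}")
        for kind, cov in trace_covariates(trace).items():
            out[(cov.scope, kind)] = cov
    for kind in KINDS:
        trial1 = [out[(f"{pose}_t1", kind)] for pose in POSES]
        both = trial1 + [out[(f"{pose}_t2", kind)] for pose in POSES]
        out[("trial1", kind)] = aggregate(trial1, "trial1")
        out[("both", kind)] = aggregate(both, "both")
    return out


def cohort_functional_matrices(
    all_traces: dict, subject_ids: list[str]
) -> dict[tuple[str, str], np.ndarray]:
    """Stack per-subject covariates into (n_subjects, 300) matrices.

    ``all_traces`` maps (subject_id, pose, trial) -> BalanceTrace.  Subjects
    with no traces (unable to complete) get NaN rows: they carry no
    functional information and are handled downstream by the prediction
    override.
    """
    mats = {
        (scope, kind): np.full((len(subject_ids), N_GRID), np.nan)
        for scope in ALL_SCOPES
        for kind in KINDS
    }
    by_subject: dict[str, dict] = {}
    for (s, pose, trial), tr in all_traces.items():
        by_subject.setdefault(s, {})[(pose, trial)] = tr
    for i, sid in enumerate(subject_ids):
        subj = by_subject.get(sid)
        if not subj:
            continue
        covs = build_functional_set(subj)
        for key, cov in covs.items():
            mats[key][i] = cov.values
    return mats
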