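"""Delimited-text input/output for rosters, traces, and derived tables.

Traces are one CSV per subject-pose-trial (columns time_s, x, y) named
``<subject>_<pose>_<trial>.csv``; the roster is a single CSV with empty
cells for missing responses.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import ALL_SCOPES, GRID, KINDS, N_GRID
from .schema import POSES, TRIALS
from .synthgen import BalanceTrace


def trace_filename(subject_id: str, pose: str, trial: int) -> str:
    return f"{subject_id}_{pose}_{trial}.csv"


def write_trace(trace: BalanceTrace, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / trace_filename(trace.subject_id or "anon", trace.pose, trace.trial)
    df = pd.DataFrame({"time_s": trace.t, "x": trace.x, "y": trace.y})
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_trace(path) -> BalanceTrace:
    path = Path(path)
    stem = path.stem
    subject_id, pose, trial = stem.rsplit("_", 2)[0], None, None
    for p in POSES:
        for tr in TRIALS:
            if stem.endswith(f"_{p}_{tr}"):
                pose, trial = p, tr
                subject_id = stem[: -len(f"_{p}_{tr}")]
    if pose is None:
        raise ValueError(f"cannot parse pose/trial from filename {path.name!r}")
    df = pd.read_csv(path)
    return BalanceTrace(
        t=df["time_s"].to_numpy(float), x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float), pose=pose, trial=trial, subject_id=subject_id,
    )


def write_cohort(roster: pd.DataFrame, traces: dict, out_dir) -> Path:
    """Write a simulated cohort: roster.csv plus a traces/ directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    roster.to_csv(out_dir / "roster.csv", index=False)
    tdir = out_dir / "traces"
    for trace in traces.values():
        write_trace(trace, tdir)
    return out_dir


def read_roster(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_traces(directory) -> dict:
    traces = {}
    for path in sorted(Path(directory).glob("*.csv")):
        tr = read_trace(path)
        traces[(tr.subject_id, tr.pose, tr.trial)] = tr
    return traces


def write_exclusion_report(report, path) -> None:
    with open(path, "w") as fh:
        for key, value in report.to_dict().items():
            fh.write(f"{key}: {value}\n")


def write_functional_matrices(mats: dict, subject_ids, out_dir) -> Path:
    """One wide CSV: subject_id, scope, kind, then the 300 grid columns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = [f"t{g:.1f}" for g in GRID]
    frames = []
    for (scope, kind), mat in mats.items():
        df = pd.DataFrame(mat, columns=cols)
        df.insert(0, "kind", kind)
        df.insert(0, "scope", scope)
        df.insert(0, "subject_id", list(subject_ids))
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    path = out_dir / "functional_covariates.csv"
    out.to_csv(path, index=False, float_format="%.8g")
    return path


def read_functional_matrices(path) -> tuple[dict, list[str]]:
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns if c.startswith("t")]
    assert len(value_cols) == N_GRID
    mats = {}
    subject_ids: list[str] = []
    for (scope, kind), grp in df.groupby(["scope", "kind"], sort=False):
        if scope not in ALL_SCOPES or kind not in KINDS:
            raise ValueError(f"unknown scope/kind {(scope, kind)}")
        mats[(scope, kind)] = grp[value_cols].to_numpy(float)
        subject_ids = grp["subject_id"].tolist()
    return mats, subject_ids


def write_curve(curve, path) -> None:
    pd.DataFrame({
        "time_s": curve.grid, "estimate": curve.estimate,
        "lower": curve.lower, "upper": curve.upper,
    }).to_csv(path, index=False)


def write_fit(fit, path) -> None:
    """Structured-text dump of a fitted model: header plus coefficient table."""
    with open(path, "w") as fh:
        fh.write(f"loglik: {fit.loglik:.6f}\n")
        fh.write(f"aic: {fit.aic:.6f}\n")
        fh.write(f"converged: {fit.converged}\n")
        fh.write(f"separation: {fit.separation}\n")
        fh.write("coefficients:\n")
        for name, c, se in zip(fit.names, fit.coef, np.sqrt(np.diag(fit.cov))):
            fh.write(f"  {name}\t{c:.6g}\t{se:.6g}\n")
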