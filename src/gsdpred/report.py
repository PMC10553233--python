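"""Cohort characteristics table and trace/curve figures.

The characteristics table summarizes each of the 25 scalar features by
class: median (IQR) with a Kruskal-Wallis p-value for continuous variables,
N (%) per level with a Fisher exact p-value for categorical ones.  Fisher's
test is exact (hypergeometric) for 2x2 tables; for r x 2 tables with more
than two levels the p-value is Monte-Carlo, sampling category counts from
the exact conditional null given the margins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact, kruskal

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import schema  # noqa: E402
from .fglm import RegressionCurve  # noqa: E402

CONTINUOUS = ("age",) + schema.GRIP_COLUMNS + ("n_falls", "n_near_falls")


def _log_table_prob(counts1: np.ndarray, totals: np.ndarray, n1: int) -> np.ndarray:
    """Log multivariate-hypergeometric probability of group-1 counts."""
    counts1 = np.atleast_2d(counts1)
    N = totals.sum()
    lp = (
        gammaln(totals + 1).sum()
        - gammaln(counts1 + 1).sum(axis=1)
        - gammaln(totals - counts1 + 1).sum(axis=1)
    )
    lp -= gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1)
    return lp


def fisher_exact_mc(
    table: np.ndarray, n_draws: int = 100_000, seed: int = 0
) -> float:
    """Fisher exact p-value for an r x 2 contingency table.

    2x2 tables use the exact hypergeometric test.  Larger tables use a
    seeded Monte-Carlo estimate: under the null, the group-1 column of the
    table is multivariate hypergeometric given the margins, so tables are
    sampled directly from that distribution and p is the fraction whose
    probability does not exceed the observed table's (the standard
    probability-ordering Fisher criterion), with the +1 correction.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError(f"expected an r x 2 table, got shape {table.shape}")
    if table.shape[0] == 2:
        return float(fisher_exact(table)[1])
    rng = np.random.default_rng(seed)
    totals = table.sum(axis=1)
    n1 = int(table[:, 0].sum())
    obs = _log_table_prob(table[:, 0], totals, n1)[0]
    draws = rng.multivariate_hypergeometric(totals, n1, size=n_draws)
    lp = _log_table_prob(draws, totals, n1)
    return float((1 + np.sum(lp <= obs + 1e-12)) / (n_draws + 1))


def _is_categorical(name: str) -> bool:
    return name not in CONTINUOUS


def characteristics_table(
    features: pd.DataFrame,
    y: np.ndarray,
    n_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Class-wise summary of the 25 scalar features with p-values.

    One row per variable (and per level for categorical variables with more
    than two levels).  Continuous variables report median (IQR) per class
    and a Kruskal-Wallis p; categorical variables report N (%) per class
    and a Fisher exact p (Monte-Carlo for >2 levels).
    """
    y = np.asarray(y, dtype=float)
    pos, neg = y == 1, y == 0
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("both classes must be non-empty")

    rows = []
    for name in features.columns:
        v = features[name].to_numpy(float)
        vp, vn = v[pos], v[neg]
        if not _is_categorical(name):
            def fmt(a):
                q1, med, q3 = np.percentile(a, [25, 50, 75])
                return f"{med:.1f} ({q1:.1f}, {q3:.1f})"
            try:
                p = float(kruskal(vp, vn).pvalue)
            except ValueError:  # all values identical across both groups
                p = 1.0
            rows.append({
                "variable": name, "level": "", "type": "continuous",
                "gsd_plus": fmt(vp), "gsd_minus": fmt(vn),
                "n_plus": np.nan, "pct_plus": np.nan,
                "n_minus": np.nan, "pct_minus": np.nan,
                "p_value": p,
            })
        else:
            levels = np.unique(v)
            tab = np.array([
                [(vp == lev).sum(), (vn == lev).sum()] for lev in levels
            ], dtype=int)
            if len(levels) < 2:
                p = 1.0
            else:
                p = fisher_exact_mc(tab, n_draws=n_draws, seed=seed)
            for lev, (np_, nn) in zip(levels, tab):
                rows.append({
                    "variable": name, "level": f"{lev:g}", "type": "categorical",
                    "gsd_plus": f"{np_} ({100 * np_ / pos.sum():.1f})",
                    "gsd_minus": f"{nn} ({100 * nn / neg.sum():.1f})",
                    "n_plus": int(np_), "pct_plus": 100 * np_ / pos.sum(),
                    "n_minus": int(nn), "pct_minus": 100 * nn / neg.sum(),
                    "p_value": p,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def render_trace_figure(trace, out_path) -> str:
    """Plot one balance test: X-Y sway path plus velocity/acceleration panels."""
    from .features import differentiate

    if len(trace) == 0:
        raise ValueError("empty trace")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    axes[0].plot(trace.x, trace.y, lw=0.5)
    axes[0].set_xlabel("X (board units)")
    axes[0].set_ylabel("Y (board units)")
    axes[0].set_title(f"Center of balance ({trace.pose}, trial {trace.trial})")
    try:
        vel, acc = differentiate(trace)
        axes[1].plot(vel.t, np.hypot(vel.vx, vel.vy), lw=0.5)
        axes[2].plot(acc.t, np.hypot(acc.vx, acc.vy), lw=0.5)
    except ValueError:
        pass  # single-point traces still render the path panel
    axes[1].set_xlabel("time (s)")
    axes[1].set_title("|velocity| (units/s)")
    axes[2].set_xlabel("time (s)")
    axes[2].set_title("|acceleration| (units/s$^2$)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return str(out_path)


def render_curve_figure(curve: RegressionCurve, out_path, title: str = "") -> str:
    """Plot a regression curve with its confidence band and significant region."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(curve.grid, curve.lower, curve.upper, color="0.8", label="95% band")
    ax.plot(curve.grid, curve.estimate, "k-", label=r"$\hat\beta(t)$")
    ax.axhline(0.0, ls="--", color="k", lw=0.8)
    for lo, hi in curve.significant_region:
        ax.axvspan(lo, hi, color="tab:red", alpha=0.15)
    ax.set_xlabel("time since test start (s)")
    ax.set_ylabel("log-odds per unit covariate per s")
    if title:
        ax.set_title(title)
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return str(out_path)
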