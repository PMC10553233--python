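"""Controlled simulation experiments with generator-known truth.

The full synthetic study (roster + 8 traces per subject) is the realistic
testbed; the cohorts built here are its stripped-down counterpart for
parameter-recovery experiments: balanced classes, two mildly informative
scalar features, and a single trial-1 velocity-aggregate functional
covariate whose class effect is confined to the generator's effect window.

With ``scale_sigma=0`` (homogeneous baseline sway) the true coefficient
curve is exactly null outside the effect window, which makes the recovered
significant region directly checkable against the generator truth.  With
heterogeneous baselines, out-of-window sway becomes informative about the
subject's sway scale and the population-optimal curve acquires genuine
out-of-window structure — useful to know when interpreting fitted curves
on realistic cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import trace_covariates
from .schema import POSES
from .synthgen import SwayParams, simulate_cop_trace


def simulate_known_effect_cohort(
    n: int = 400,
    seed: int = 0,
    ratio: float = 3.0,
    scale_sigma: float | None = None,
    effect_sigma: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Simulate a cohort with a known within-window functional effect.

    Returns ``(scalar_features, labels, functional)`` where ``functional``
    is the (n, 300) trial-1 velocity-aggregate matrix.  ``ratio`` is the
    class velocity ratio inside the effect window; ``scale_sigma`` /
    ``effect_sigma`` override the generator's subject-heterogeneity
    defaults when given.
    """
    kwargs: dict = {"class_velocity_ratio": ratio}
    if scale_sigma is not None:
        kwargs["subject_scale_sigma"] = scale_sigma
    if effect_sigma is not None:
        kwargs["effect_sigma"] = effect_sigma
    params = SwayParams(**kwargs)

    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(float)
    func = np.empty((n, 300))
    for i in range(n):
        label = "GSD+" if y[i] else "GSD-"
        scale = float(np.exp(params.subject_scale_sigma * rng.standard_normal()))
        log_ratio = np.log(ratio) if y[i] else 0.0
        effect = float(np.exp(log_ratio + params.effect_sigma * rng.standard_normal()))
        curves = [
            trace_covariates(
                simulate_cop_trace(label, pose, params,
                                   seed=int(rng.integers(2**31)),
                                   subject_scale=scale, subject_effect=effect)
            )["velocity"].values
            for pose in POSES
        ]
        func[i] = np.mean(curves, axis=0)
    features = pd.DataFrame({
        "age": rng.normal(80 + 4 * y, 6.0),
        "grip": rng.normal(24 - 4 * y, 6.0),
    })
    return features, y, func
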