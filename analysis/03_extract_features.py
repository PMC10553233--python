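#!/usr/bin/env python
"""Build the 20 functional covariates per retained subject.

Each balance trace is differentiated (velocity, acceleration), subsampled
to the 0.1 s grid, squared and summed across the X/Y axes; per-test curves
are aggregated over trial 1 and over both trials.  Writes
results/functional_covariates.csv (one wide row per subject x scope x kind).

Run after 02:  python analysis/03_extract_features.py
"""

from pathlib import Path

import pandas as pd

from gsdpred import io
from gsdpred.features import cohort_functional_matrices

OUT = Path("results")


def main():
    retained = pd.read_csv(OUT / "retained_roster.csv")
    traces = io.read_traces(OUT / "data" / "traces")
    ids = retained["subject_id"].tolist()
    mats = cohort_functional_matrices(traces, ids)
    path = io.write_functional_matrices(mats, ids, OUT)
    n_unable = int(retained["flag_unable_to_complete"].sum())
    print(f"built {len(mats)} covariate matrices for {len(ids)} subjects "
          f"({n_unable} unable-to-complete subjects carry empty rows)")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
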