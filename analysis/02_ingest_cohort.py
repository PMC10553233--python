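#!/usr/bin/env python
"""Apply the study's exclusion filters and encode/impute the scalar features.

Reads results/data/roster.csv, removes flagged subjects (equipment error >
missing survey > missing balance-board data), encodes the 25 scalar
features, and fills 1-4 missing values per subject by predictive mean
matching within chained equations.  Writes results/features.csv,
results/retained_roster.csv and results/exclusion_report.txt.

Run after 01:  python analysis/02_ingest_cohort.py [seed]
"""

import sys
from pathlib import Path

import gsdpred as g
from gsdpred import io

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results")


def main():
    roster = io.read_roster(OUT / "data" / "roster.csv")
    features, retained, report = g.ingest_cohort(roster, seed=SEED)
    features.to_csv(OUT / "features.csv")
    retained.to_csv(OUT / "retained_roster.csv", index=False)
    io.write_exclusion_report(report, OUT / "exclusion_report.txt")
    d = report.to_dict()
    print(f"{d['n_input']} consented -> removed {d['equipment_error']} (equipment "
          f"error), {d['missing_survey']} (missing survey), {d['missing_wbb']} "
          f"(missing WBB) -> {d['n_retained']} retained")
    n_plus = (retained["gsd_label"] == "GSD+").sum()
    print(f"retained cohort: {n_plus} GSD+, {len(retained) - n_plus} GSD-")


if __name__ == "__main__":
    main()
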