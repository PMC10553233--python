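#!/usr/bin/env python
"""Simulate the synthetic study cohort.

Generates a 268-subject cohort at the published design — exclusion flags
21 (equipment error) / 39 (missing survey) / 2 (missing balance-board data),
~47% device users, Table-1-shaped feature shifts, and 8 balance-test traces
per testable subject — and writes it under results/data/ (roster.csv plus
one trace CSV per subject-pose-trial).

Run from the repository root:  python analysis/01_simulate_cohort.py [seed]
"""

import sys
from pathlib import Path

import gsdpred as g
from gsdpred import io

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/data")


def main():
    params = g.CohortParams(seed=SEED)
    roster, traces = g.simulate_cohort(params)
    io.write_cohort(roster, traces, OUT)
    n_flagged = roster[["flag_equipment_error", "flag_missing_survey",
                        "flag_missing_wbb"]].sum().sum()
    print(f"simulated {len(roster)} subjects ({n_flagged} flagged for exclusion, "
          f"{roster['flag_unable_to_complete'].sum()} unable to complete)")
    print(f"wrote {len(traces)} traces to {OUT}/traces")


if __name__ == "__main__":
    main()
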