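#!/usr/bin/env python
"""Cross-validated evaluation of all 21 models.

For each of the 20 functional covariates (velocity/acceleration x 8 single
tests, trial-1 aggregate, both-trials aggregate) plus the scalar-only
model: 10-fold CV with per-fold AIC backward selection on the 25 scalar
features, the unable-to-complete override, a pooled threshold enforcing
specificity >= 0.75, and AUC/accuracy/sensitivity/specificity.  Writes
results/performance.csv and results/oof_probabilities.csv.

Run after 03:  python analysis/04_crossvalidate_models.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

import gsdpred as g
from gsdpred import io

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results")


def main():
    features = pd.read_csv(OUT / "features.csv", index_col=0)
    retained = pd.read_csv(OUT / "retained_roster.csv")
    mats, ids = io.read_functional_matrices(OUT / "functional_covariates.csv")
    assert ids == retained["subject_id"].tolist()
    y = (retained["gsd_label"] == "GSD+").to_numpy(float)
    unable = retained["flag_unable_to_complete"].to_numpy(bool)

    table, results = g.evaluate_models(features, y, unable, mats, k=10, seed=SEED)
    table.to_csv(OUT / "performance.csv", index=False)

    oof = pd.DataFrame({"subject_id": ids, "label": retained["gsd_label"]})
    for key, res in results.items():
        oof["non_wbb" if key is None else f"{key[0]}_{key[1]}"] = res.probabilities
    oof.to_csv(OUT / "oof_probabilities.csv", index=False)

    print(table.round(3).to_string(index=False))
    best = table.loc[table["auc"].idxmax()]
    print(f"\nbest model by AUC: {best['scope']} {best['kind']} "
          f"(AUC {best['auc']:.3f}, accuracy {best['accuracy']:.3f})")
    scalar_auc = table.loc[table["scope"] == "non-WBB only", "auc"].iloc[0]
    print(f"scalar-only (non-WBB) AUC: {scalar_auc:.3f}")


if __name__ == "__main__":
    main()
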