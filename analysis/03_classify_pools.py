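"""Per-pool QDA classification with SFS inside leave-one-patient-out CV.

Reads results/features.csv, sweeps the SFS feature count (1..7, capped at
the pool size) for each of the three feature pools, reports the best
F-score operating point per pool (accuracy/sensitivity/specificity/F and the
aggregate confusion matrix), and ranks features by their selection frequency
across folds (>= 50% defines each pool's fselected set).  Writes
results/pool_summary.csv, results/selection_frequency_<pool>.csv and
results/fselected.json.
"""

import json
from pathlib import Path

import pandas as pd

from maflim.classification import fselected, selection_frequency, sweep_n_sfs
from maflim.features import POOLS

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    feats = pd.read_csv(ROOT / "results" / "features.csv")
    rows, selected_sets = [], {}
    for pool_name, pool in POOLS.items():
        n_sel, cv, sweep_table = sweep_n_sfs(feats, list(pool))
        tn, fp, fn, tp = cv.confusion
        rows.append({"pool": pool_name, "n_selected": n_sel, **cv.metrics,
                     "TN": tn, "FP": fp, "FN": fn, "TP": tp})
        table = selection_frequency(cv)
        table.to_csv(ROOT / "results" / f"selection_frequency_{pool_name}.csv",
                     index=False)
        selected_sets[pool_name] = fselected(cv)
        print(f"{pool_name}: n_selected={n_sel} "
              f"acc={cv.metrics['accuracy']:.1f}% sn={cv.metrics['sensitivity']:.1f}% "
              f"sp={cv.metrics['specificity']:.1f}% F={cv.metrics['f_score']:.1f}%")
        print(f"  fselected (>=50% of folds): {selected_sets[pool_name]}")
    summary = pd.DataFrame(rows)
    summary.to_csv(ROOT / "results" / "pool_summary.csv", index=False)
    (ROOT / "results" / "fselected.json").write_text(
        json.dumps(selected_sets, indent=2)
    )
    print(f"wrote {ROOT / 'results' / 'pool_summary.csv'}")


if __name__ == "__main__":
    main()
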