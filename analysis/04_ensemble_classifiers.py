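"""Weighted-posterior ensembles of the pool-specific QDA classifiers.

Reads results/features.csv and results/fselected.json (from
03_classify_pools.py) and evaluates ensemble combinations of the pools'
fselected feature sets under outer LOPO-CV, with the posterior weights
optimised per fold on a 0.1-step simplex grid inside an inner LOPO loop
(operating point closest to the ideal ROC corner).  Writes
results/ensemble_summary.csv and the per-fold weights.
"""

import json
from pathlib import Path

import pandas as pd

from maflim.classification import ensemble_lopo

ROOT = Path(__file__).resolve().parents[1]

COMBINATIONS = [
    ("biexponential", "intensity"),
    ("phasor", "biexponential"),
    ("phasor", "intensity"),
    ("phasor", "biexponential", "intensity"),
]


def main() -> None:
    feats = pd.read_csv(ROOT / "results" / "features.csv")
    selected = json.loads((ROOT / "results" / "fselected.json").read_text())
    rows, weight_rows = [], []
    for combo in COMBINATIONS:
        pools = {name: selected[name] for name in combo}
        if any(not v for v in pools.values()):
            print(f"skipping {'+'.join(combo)}: a pool has no fselected features")
            continue
        cv = ensemble_lopo(feats, pools)
        tn, fp, fn, tp = cv.confusion
        name = "+".join(combo)
        rows.append({"ensemble": name, **cv.metrics,
                     "TN": tn, "FP": fp, "FN": fn, "TP": tp})
        for fold in cv.folds:
            weight_rows.append({"ensemble": name, "patient_id": fold.patient_id,
                                **{f"w_{p}": w for p, w in zip(combo, fold.weights)}})
        print(f"{name}: acc={cv.metrics['accuracy']:.1f}% "
              f"sn={cv.metrics['sensitivity']:.1f}% sp={cv.metrics['specificity']:.1f}% "
              f"F={cv.metrics['f_score']:.1f}%")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "ensemble_summary.csv", index=False)
    pd.DataFrame(weight_rows).to_csv(ROOT / "results" / "ensemble_weights.csv",
                                     index=False)
    print(f"wrote {ROOT / 'results' / 'ensemble_summary.csv'}")


if __name__ == "__main__":
    main()
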