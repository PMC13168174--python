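"""Train both classifiers under repeated stratified CV and evaluate them.

Uses the imputed markers as predictors and the estimated selection-index
classes as the response; writes confusion matrices, class-level and overall
metric tables, and the misclassification-severity summary per model family.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd

import soyclass as sc
from _common import CV_PROTOCOL, MODEL_SPECS, RESULTS, SCRATCH, ensure_dirs
from soyclass.evaluation import report_frames
from soyclass.io import read_marker_csv


def main() -> None:
    ensure_dirs()
    markers = read_marker_csv(SCRATCH / "markers_imputed.csv")
    msi = pd.read_csv(SCRATCH / "msi.csv")

    for tag, spec in MODEL_SPECS.items():
        preds = sc.run_repeated_cv(markers, msi, spec, CV_PROTOCOL)
        preds.to_csv(SCRATCH / f"cv_predictions_{tag}.csv", index=False)
        frames = report_frames(preds)
        for name, df in frames.items():
            df.to_csv(RESULTS / f"{name}_{tag}.csv")
        overall = frames["overall_metrics"].iloc[0]
        sev = frames["severity"].iloc[0]
        print(f"[{tag}] pooled n={len(preds)}  "
              f"accuracy {overall['accuracy']:.2f} "
              f"(95% CI {overall['ci95_lower']:.2f}-{overall['ci95_upper']:.2f})  "
              f"kappa {overall['kappa']:.2f}  NIR {overall['nir']:.2f}  "
              f"P[acc>NIR] {overall['p_acc_gt_nir']:.1e}")
        print(f"[{tag}] macro: balanced accuracy "
              f"{overall['macro_balanced_accuracy']:.2f}  "
              f"sensitivity {overall['macro_sensitivity']:.2f}  "
              f"specificity {overall['macro_specificity']:.2f}  "
              f"F1 {overall['macro_f1']:.2f}")
        print(f"[{tag}] severity: correct {sev['correct']:.1%}  "
              f"mild {sev['mild']:.1%}  extreme {sev['extreme']:.1%}")


if __name__ == "__main__":
    main()
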