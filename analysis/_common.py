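"""Shared configuration for the numbered analysis scripts.

The desk-scale study: 300 F4:5-derived lines from 60 bi-parental families
plus 6 checks, 400 SNPs, 6 environments (3 locations x 2 years) under 55%
sparse testing, 2% missing marker calls.  Large intermediates are kept under
scratch/analysis; small summary tables land in results/analysis.
"""
from pathlib import Path

import soyclass as sc

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results" / "analysis"

SEED = 2026


def study_config() -> sc.SimConfig:
    return sc.small_config(seed=SEED, missing_rate=0.02, n_monomorphic=8)


CV_PROTOCOL = sc.CVProtocol(outer_reps=3, inner_folds=3, inner_repeats=1,
                            seed=SEED)
MODEL_SPECS = {
    "glmnet": sc.ModelSpec(
        "elastic_net_multinomial",
        tuning_grid=[{"clf__l1_ratio": [0.1, 1.0], "clf__C": [0.01, 0.1],
                      "clf__tol": [1e-3]}]),
    "rf": sc.ModelSpec(
        "random_forest",
        tuning_grid={"n_estimators": [200], "max_features": [10, 20, 40]}),
}


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
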