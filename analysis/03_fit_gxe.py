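"""Fit the FA1 genomic mixed model and the separate check model.

Estimates variance components by AI-REML, predicts the complete genotype x
environment GBLUP matrix (observed and unobserved cells), and builds the
per-environment, per-maturity-group check reference.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd

import soyclass as sc
from _common import RESULTS, SCRATCH, ensure_dirs
from soyclass.io import read_grm_csv, read_phenotypes


def main() -> None:
    ensure_dirs()
    pheno = read_phenotypes(SCRATCH / "data" / "phenotypes.csv")
    grm = read_grm_csv(SCRATCH / "grm.csv")

    fit = sc.fit_fa1_gblup(pheno[~pheno["is_check"]], grm)
    summary = {
        "converged": fit.converged, "n_iter": fit.n_iter,
        "loglik": round(fit.loglik, 3),
        "sigma2_g": round(fit.sigma2_g, 1), "sigma2_e": round(fit.sigma2_e, 1),
        "loadings": {k: round(v, 2) for k, v in fit.loadings.items()},
        "psi": {k: round(v, 1) for k, v in fit.psi.items()},
        "mu": round(fit.mu, 1),
        "location_effects": {k: round(v, 1) for k, v in fit.location_effects.items()},
    }
    (RESULTS / "fa1_fit_summary.json").write_text(json.dumps(summary, indent=2))
    print("FA1 fit:", json.dumps(summary, indent=2))

    gblups = sc.predict_gblups(fit, grm)
    gblups.to_frame().to_csv(SCRATCH / "gblups.csv")
    gblups.observed_mask.astype(int).to_csv(SCRATCH / "gblups_mask.csv")
    n_unobs = int((~gblups.observed_mask.to_numpy()).sum())
    print(f"GBLUP matrix complete: {gblups.values.shape[0]} genotypes x "
          f"{gblups.values.shape[1]} environments "
          f"({n_unobs} unobserved cells predicted)")

    checks = sc.fit_check_model(pheno[pheno["is_check"]])
    checks.table.to_csv(SCRATCH / "check_reference.csv")
    print("check reference (environment x MG):")
    print(checks.table.round(1))


if __name__ == "__main__":
    main()
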