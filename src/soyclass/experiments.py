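"""Reusable simulation studies: parameter recovery, sparse-testing benefit,
and the end-to-end classification signal check.

These are the package's validation experiments; the analysis scripts and the
test suite both drive them.  Problem sizes are desk-scale study designs
chosen once and documented in the methods note:

* Recovery / masked-cell design: 300 lines (30 families x 10 sibs, matching
  a realistic family depth), 300 SNPs, 6 locations x 1 year at 55% observed
  cells, with strongly heterogeneous FA1 loadings (one negative, i.e. a
  crossover environment) -- loading heterogeneity is what identifies the
  main-effect variance against the factor term.
* Signal-check design: 400 lines (40 x 10), 250 SNPs, high additive variance
  and weak interaction/noise so yield class is strongly genetically
  determined.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .classification import CVProtocol, ModelSpec, run_repeated_cv
from .evaluation import confusion_matrix, overall_metrics
from .gxe import fit_fa1_gblup, predict_gblups
from .markers import compute_grm
from .simdata import SimConfig, simulate_dataset, small_config

RECOVERY_TRUTH = {
    "sigma2_g": 36_000.0,
    "loadings": np.array([240.0, -60.0, 60.0, 120.0, 180.0, 300.0]),
    "psi": np.full(6, 15_000.0),
    "sigma2_e": 15_000.0,
}


def recovery_config(seed: int) -> SimConfig:
    return small_config(
        seed=seed, n_families=30, lines_per_family=10, n_markers=300,
        n_checks=6, n_locations=6, n_years=1, sparsity=0.55,
        sigma2_g=RECOVERY_TRUTH["sigma2_g"],
        lambda_loadings=RECOVERY_TRUTH["loadings"],
        psi_diag=RECOVERY_TRUTH["psi"],
        sigma2_e=RECOVERY_TRUTH["sigma2_e"],
    )


def signal_config(seed: int) -> SimConfig:
    return small_config(
        seed=seed, n_families=40, lines_per_family=10, n_markers=250,
        n_checks=6, n_locations=3, n_years=2, sparsity=0.55,
        sigma2_g=60_000.0, lambda_loadings=[60.0, 90.0, 120.0],
        psi_diag=[2000.0] * 3, sigma2_e=20_000.0,
    )


def _line_inputs(data):
    lines = ~data.markers.genotype_meta["is_check"].to_numpy()
    markers = data.markers_complete.subset_genotypes(lines)
    grm = compute_grm(markers)
    pheno = data.pheno[~data.pheno["is_check"]]
    return lines, markers, grm, pheno


def _aligned_loadings(est: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Resolve the FA1 global sign indeterminacy before comparison."""
    if np.sum((est - truth) ** 2) > np.sum((est + truth) ** 2):
        return -est
    return est


def parameter_recovery_study(n_seeds: int = 10, base_seed: int = 0) -> dict:
    """Refit the FA1 model on datasets simulated from known parameters.

    Returns per-seed estimates and the relative error of the seed-averaged
    estimate for each variance parameter (sigma2_g, Lambda as a vector,
    mean Psi, sigma2_e).
    """
    truth = RECOVERY_TRUTH
    rows = []
    for k in range(n_seeds):
        data = simulate_dataset(recovery_config(base_seed + k))
        _, _, grm, pheno = _line_inputs(data)
        fit = fit_fa1_gblup(pheno, grm)
        lam = _aligned_loadings(fit.loadings.to_numpy(), truth["loadings"])
        rows.append({
            "seed": base_seed + k, "sigma2_g": fit.sigma2_g,
            "sigma2_e": fit.sigma2_e, "converged": fit.converged,
            **{f"lambda_{i}": v for i, v in enumerate(lam)},
            **{f"psi_{i}": v for i, v in enumerate(fit.psi.to_numpy())},
        })
    est = pd.DataFrame(rows)
    lam_cols = [f"lambda_{i}" for i in range(len(truth["loadings"]))]
    psi_cols = [f"psi_{i}" for i in range(len(truth["psi"]))]
    lam_mean = est[lam_cols].mean(axis=0).to_numpy()
    errors = {
        "sigma2_g": abs(est["sigma2_g"].mean() / truth["sigma2_g"] - 1.0),
        "loadings": float(np.linalg.norm(lam_mean - truth["loadings"])
                          / np.linalg.norm(truth["loadings"])),
        "psi": abs(est[psi_cols].to_numpy().mean() / truth["psi"].mean() - 1.0),
        "sigma2_e": abs(est["sigma2_e"].mean() / truth["sigma2_e"] - 1.0),
    }
    return {"estimates": est, "relative_errors": errors, "truth": truth}


def masked_cell_study(n_seeds: int = 10, base_seed: int = 0,
                      mask_fraction: float = 0.20) -> pd.DataFrame:
    """Hide observed cells, refit, and score predictions of the hidden cells.

    For each seed a fraction of the lines' observed genotype x environment
    records is masked, the FA1 model is refitted on the remainder, and the
    correlation between predicted and simulated true genetic values on the
    masked cells is compared with a per-environment means baseline (each
    genotype's mean deviation from its observed environments' means, carried
    to the masked environment).
    """
    rows = []
    for k in range(n_seeds):
        seed = base_seed + k
        data = simulate_dataset(recovery_config(seed))
        lines, _, grm, pheno = _line_inputs(data)
        rng = np.random.default_rng([seed, 2])
        mask = rng.random(len(pheno)) < mask_fraction
        train = pheno[~mask]
        held = pheno[mask]
        fit = fit_fa1_gblup(train, grm)
        gblups = predict_gblups(fit, grm).to_frame()

        truth = data.truth
        env_pos = {e: i for i, e in enumerate(truth.environments)}
        gen_pos = {g: i for i, g in enumerate(truth.genotype_ids)}
        loc_pos = {l: i for i, l in enumerate(truth.locations)}
        gi = held["genotype"].map(gen_pos).to_numpy()
        li = held["location"].map(loc_pos).to_numpy()
        true_gen = truth.true_u[gi] + truth.true_w[gi, li]

        pred_gen = np.array([
            gblups.loc[g, e] - fit.env_means[e]
            for g, e in zip(held["genotype"], held["env"])
        ])
        env_means = train.groupby("env")["yield"].mean()
        dev = (train["yield"] - train["env"].map(env_means)).groupby(
            train["genotype"]).mean()
        base_pred = held["genotype"].map(dev).fillna(0.0).to_numpy()

        rows.append({
            "seed": seed,
            "n_masked": int(mask.sum()),
            "cor_fa1": float(np.corrcoef(pred_gen, true_gen)[0, 1]),
            "cor_env_means": float(np.corrcoef(base_pred, true_gen)[0, 1]),
        })
    return pd.DataFrame(rows)


#: reduced tuning grids for the desk-scale signal check (strong penalties
#: keep the saga solver fast; the full defaults are documented in
#: classification.ModelSpec)
SIGNAL_GLMNET_GRID = [{"clf__l1_ratio": [0.1, 1.0],
                       "clf__C": [0.01, 0.1],
                       "clf__tol": [1e-3]}]
SIGNAL_RF_GRID = {"n_estimators": [200], "max_features": [16, 32]}


def signal_check_study(seed: int = 0, permuted: bool = False,
                       outer_reps: int = 4) -> dict:
    """Repeated-CV classification of genetically determined classes.

    Trains both model families on markers against the generating model's
    true yield classes (or a random permutation of them for the null) and
    returns the pooled overall metrics per family.
    """
    data = simulate_dataset(signal_config(seed))
    lines = ~data.markers.genotype_meta["is_check"].to_numpy()
    markers = data.markers_complete.subset_genotypes(lines)
    classes = pd.Series(data.truth.true_class[lines], index=markers.genotype_ids)
    if permuted:
        rng = np.random.default_rng([seed, 3])
        classes = pd.Series(rng.permutation(classes.to_numpy()),
                            index=classes.index)
    protocol = CVProtocol(outer_reps=outer_reps, inner_folds=3,
                          inner_repeats=1, seed=seed)
    out = {}
    for family, grid in [("elastic_net_multinomial", SIGNAL_GLMNET_GRID),
                         ("random_forest", SIGNAL_RF_GRID)]:
        preds = run_repeated_cv(markers, classes,
                                ModelSpec(family, tuning_grid=grid), protocol)
        cm = confusion_matrix(preds)
        out[family] = {"preds": preds, "overall": overall_metrics(cm)}
    return out
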