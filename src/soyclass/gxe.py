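"""Genomic multi-environment mixed model with a factor-analytic (FA1) GxL term.

Model, at the genotype x environment (BLUE) level:

    y_{lyg} = mu + L_l + (L:Y)_{ly} + u_g + w_{lg} + e_{lyg}

with u ~ N(0, sigma2_g * G), w_{lg} = lambda_l f_g + delta_{lg} so that
w ~ N(0, (Lambda Lambda' + Psi) (x) G), and iid residuals.  The fixed part
mu + L_l + (L:Y)_{ly} saturates the environment means and is fitted as one
mean per environment, decomposed afterwards under a sum-to-zero convention.

Because every random term carries the genotype covariance G, the marginal
covariance between two records i, k reduces elementwise to

    V_ik = (sigma2_g + lambda_{l_i} lambda_{l_k} + psi_{l_i} [l_i = l_k])
           * G_{g_i g_k} + sigma2_e [i = k],

which makes REML scores and average-information terms cheap to assemble.
Variance parameters are estimated by average-information REML with
step-halving so the restricted log-likelihood never decreases across
accepted iterations; variance components are clamped at zero (boundary
flagged) rather than allowed negative.  The FA1 loading sign is anchored so
the first nonzero loading is non-negative.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .io import aggregate_to_blues, validate_phenotypes
from .markers import GenomicRelationshipMatrix

logger = logging.getLogger(__name__)

_VAR_FLOOR = 0.0


class ConvergenceError(RuntimeError):
    pass


@dataclasses.dataclass
class FitOptions:
    """Controls for the REML fit."""

    tol: float = 1e-6            # relative log-likelihood change at convergence
    param_tol: float = 1e-4      # relative parameter change at convergence
    plateau_iters: int = 3       # accepted steps meeting tol alone that also
                                 # declare convergence (ridge crawling guard)
    max_iter: int = 100
    estimate_fa: bool = True     # False: Lambda and Psi held at zero (main-effects model)
    ly_random: bool = False      # treat (L:Y) as random with its own variance
    aggregate_plots: bool = True  # reduce plot-level records to per-env genotype means
    fixed: dict | None = None    # hold parameters at given values, keys among
                                 # sigma2_g, sigma2_e, loadings, psi, sigma2_ly


@dataclasses.dataclass
class FA1Fit:
    """REML estimates, BLUPs, and bookkeeping for the FA1 genomic model."""

    mu: float
    location_effects: pd.Series
    ly_effects: pd.DataFrame          # locations x years, sum-to-zero decomposition
    sigma2_g: float
    loadings: pd.Series               # per location
    psi: pd.Series                    # per location
    sigma2_e: float
    sigma2_ly: float
    u_hat: pd.Series                  # per genotype additive GBLUP
    f_hat: pd.Series                  # per genotype factor score
    delta_hat: pd.DataFrame           # genotype x location deviations
    loglik: float
    loglik_trace: list
    converged: bool
    n_iter: int
    boundary: list
    genotype_ids: np.ndarray
    locations: list
    environments: list
    env_means: pd.Series              # fitted fixed mean per environment
    env_location: pd.Series
    env_year: pd.Series
    observed: pd.DataFrame            # bool genotype x environment


@dataclasses.dataclass
class GBLUPMatrix:
    """Complete genotype x environment predicted yields with the design mask."""

    genotype_ids: np.ndarray
    environment_ids: list
    values: np.ndarray
    observed_mask: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("GBLUP matrix must be complete (no missing cells)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotype_ids, columns=self.environment_ids)


@dataclasses.dataclass
class CheckReference:
    """Mean check BLUP yield per (environment, maturity group)."""

    table: pd.DataFrame   # index: environment, columns: maturity groups

    def get(self, env, mg):
        """Return (check mean, maturity group used); nearest MG on fallback."""
        if env not in self.table.index:
            raise KeyError(f"environment {env} absent from check reference")
        cols = list(self.table.columns)
        if mg in cols:
            return float(self.table.loc[env, mg]), mg
        nearest = min(cols, key=lambda c: (abs(c - mg), c))
        logger.warning("no checks of MG %s; using nearest MG %s", mg, nearest)
        return float(self.table.loc[env, nearest]), nearest


# --------------------------------------------------------------------------
# internal REML machinery


def _reml_pieces(V, X, y):
    """Restricted log-likelihood, projection P, and P @ y for given V."""
    n, p = X.shape
    cho = cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Vi = cho_solve(cho, np.eye(n))
    ViX = Vi @ X
    XtViX = X.T @ ViX
    cx = cho_factor(XtViX, lower=True)
    logdet_x = 2.0 * np.sum(np.log(np.diag(cx[0])))
    P = Vi - ViX @ cho_solve(cx, ViX.T)
    Py = P @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    beta = cho_solve(cx, X.T @ (Vi @ y))
    return ll, P, Py, beta


def _build_V(theta, L, G_rec, loc_idx, env_idx, ly_random):
    sigma2_g = theta[0]
    lam = theta[1:1 + L]
    psi = theta[1 + L:1 + 2 * L]
    sigma2_e = theta[1 + 2 * L]
    lam_r = lam[loc_idx]
    same_loc = loc_idx[:, None] == loc_idx[None, :]
    A = sigma2_g + np.outer(lam_r, lam_r) + same_loc * psi[loc_idx][None, :]
    V = A * G_rec
    V[np.diag_indices_from(V)] += sigma2_e
    if ly_random:
        sigma2_ly = theta[2 + 2 * L]
        V += sigma2_ly * (env_idx[:, None] == env_idx[None, :])
    return V


def _vdots(theta, L, G_rec, loc_idx, env_idx, ly_random, free):
    """Yield (index, dV/dtheta_index) for the free parameters."""
    lam = theta[1:1 + L]
    lam_r = lam[loc_idx]
    N = G_rec.shape[0]
    for i in free:
        if i == 0:
            yield i, G_rec
        elif 1 <= i <= L:
            Il = (loc_idx == i - 1).astype(float)
            yield i, (np.outer(Il, lam_r) + np.outer(lam_r, Il)) * G_rec
        elif L < i <= 2 * L:
            Il = (loc_idx == i - 1 - L).astype(float)
            yield i, np.outer(Il, Il) * G_rec
        elif i == 1 + 2 * L:
            yield i, np.eye(N)
        else:
            yield i, (env_idx[:, None] == env_idx[None, :]).astype(float)


def _clamp(theta, L, ly_random, boundary):
    out = theta.copy()
    var_idx = [0] + list(range(1 + L, 2 + 2 * L))
    if ly_random:
        var_idx.append(2 + 2 * L)
    for i in var_idx:
        if out[i] < _VAR_FLOOR:
            out[i] = _VAR_FLOOR
            boundary.add(i)
    return out


# --------------------------------------------------------------------------


def fit_fa1_gblup(
    pheno: pd.DataFrame,
    grm: GenomicRelationshipMatrix,
    opts: FitOptions | None = None,
) -> FA1Fit:
    """Fit the FA1 genomic mixed model by AI-REML and return estimates + BLUPs.

    ``pheno`` is the tidy phenotype table; every phenotyped genotype must be
    present in ``grm`` (the check model passes an identity relationship).
    Needs at least two locations unless the FA1 term is disabled or held at
    zero through ``opts``.
    """
    opts = opts or FitOptions()
    pheno = validate_phenotypes(pheno)
    if opts.aggregate_plots:
        pheno = aggregate_to_blues(pheno)

    grm_pos = {g: i for i, g in enumerate(grm.genotype_ids)}
    missing = sorted(set(pheno["genotype"]) - set(grm_pos))
    if missing:
        raise ValueError(f"phenotyped genotypes absent from GRM: {missing[:5]}")

    locations = sorted(pheno["location"].unique())
    envs = sorted(pheno["env"].unique())
    L = len(locations)
    fa_active = opts.estimate_fa or (opts.fixed or {}).get("loadings") is not None
    if L < 2 and opts.estimate_fa:
        raise ValueError("FA1 model needs >= 2 locations (or disable estimate_fa)")

    loc_of = {l: i for i, l in enumerate(locations)}
    env_of = {e: i for i, e in enumerate(envs)}
    env_loc = pheno.groupby("env")["location"].first()
    env_year = pheno.groupby("env")["year"].first()
    if (pheno.groupby("env")["location"].nunique() > 1).any():
        raise ValueError("an environment maps to more than one location")

    y = pheno["yield"].to_numpy(float)
    g_idx = pheno["genotype"].map(grm_pos).to_numpy(int)
    loc_idx = pheno["location"].map(loc_of).to_numpy(int)
    env_idx = pheno["env"].map(env_of).to_numpy(int)
    N, E = len(y), len(envs)
    X = np.zeros((N, E))
    X[np.arange(N), env_idx] = 1.0
    if np.linalg.matrix_rank(X.T @ X) < E:
        raise ValueError("singular fixed-effect design")

    G = grm.values
    if grm.min_eigenvalue() < -1e-6:
        raise ValueError("GRM is not positive semi-definite beyond tolerance")
    G_rec = G[np.ix_(g_idx, g_idx)]

    observed = pd.DataFrame(False, index=grm.genotype_ids, columns=envs)
    for g, e in zip(pheno["genotype"], pheno["env"]):
        observed.loc[g, e] = True

    # ---- degenerate no-variance data -----------------------------------
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta_ols
    if float(np.var(resid)) < 1e-12 * (1.0 + float(np.var(y))):
        return _zero_variance_fit(pheno, grm, beta_ols, locations, envs,
                                  env_loc, env_year, observed, opts)

    n_par = 2 + 2 * L + (1 if opts.ly_random else 0)
    theta = np.zeros(n_par)
    vy = float(np.var(resid, ddof=1))
    gbar = float(np.mean(np.diag(G_rec))) or 1.0
    theta[0] = 0.3 * vy / gbar
    if fa_active and L >= 1:
        theta[1:1 + L] = np.sqrt(0.1 * vy / gbar)
        theta[1 + L:1 + 2 * L] = 0.1 * vy / gbar
    theta[1 + 2 * L] = 0.5 * vy
    if opts.ly_random:
        theta[2 + 2 * L] = 0.05 * vy

    # fixed / free bookkeeping
    fixed = dict(opts.fixed or {})
    if not opts.estimate_fa and "loadings" not in fixed:
        fixed["loadings"] = np.zeros(L)
    if not opts.estimate_fa and "psi" not in fixed:
        fixed["psi"] = np.zeros(L)
    fixed_idx: dict[int, float] = {}
    if "sigma2_g" in fixed:
        fixed_idx[0] = float(fixed["sigma2_g"])
    if "loadings" in fixed:
        lam_fix = np.broadcast_to(np.asarray(fixed["loadings"], float), (L,))
        for l in range(L):
            fixed_idx[1 + l] = lam_fix[l]
    if "psi" in fixed:
        psi_fix = np.broadcast_to(np.asarray(fixed["psi"], float), (L,))
        for l in range(L):
            fixed_idx[1 + L + l] = psi_fix[l]
    if "sigma2_e" in fixed:
        fixed_idx[1 + 2 * L] = float(fixed["sigma2_e"])
    if opts.ly_random and "sigma2_ly" in fixed:
        fixed_idx[2 + 2 * L] = float(fixed["sigma2_ly"])
    for i, v in fixed_idx.items():
        theta[i] = v
    free = [i for i in range(n_par) if i not in fixed_idx]

    boundary: set[int] = set()
    theta = _clamp(theta, L, opts.ly_random, boundary)
    V = _build_V(theta, L, G_rec, loc_idx, env_idx, opts.ly_random)
    ll, P, Py, beta = _reml_pieces(V, X, y)
    trace = [ll]
    converged = False
    n_iter = 0
    plateau = 0

    for it in range(opts.max_iter):
        n_iter = it + 1
        if not free:
            converged = True
            break
        dots = list(_vdots(theta, L, G_rec, loc_idx, env_idx, opts.ly_random, free))
        score = np.empty(len(free))
        W = np.empty((N, len(free)))
        for k, (i, D) in enumerate(dots):
            w = D @ Py
            W[:, k] = w
            score[k] = -0.5 * (np.sum(P * D) - float(Py @ w))
        AI = 0.5 * (W.T @ (P @ W))
        AI[np.diag_indices_from(AI)] += 1e-8 * max(1.0, float(np.trace(AI)) / max(len(free), 1))
        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            step = score / np.maximum(np.diag(AI), 1e-12)

        accepted = False
        alpha = 1.0
        for _ in range(30):
            cand = theta.copy()
            for k, i in enumerate(free):
                cand[i] = theta[i] + alpha * step[k]
            cand = _clamp(cand, L, opts.ly_random, boundary)
            try:
                V = _build_V(cand, L, G_rec, loc_idx, env_idx, opts.ly_random)
                ll_new, P_new, Py_new, beta_new = _reml_pieces(V, X, y)
            except np.linalg.LinAlgError:
                alpha *= 0.5
                continue
            if ll_new >= ll - 1e-9:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            # no uphill step available: numerically at the optimum
            converged = True
            break
        dll = ll_new - ll
        dpar = max(abs(cand[i] - theta[i]) / (abs(theta[i]) + 1.0) for i in free)
        theta, ll, P, Py, beta = cand, ll_new, P_new, Py_new, beta_new
        trace.append(ll)
        if abs(dll) < opts.tol * (abs(ll) + 1.0):
            plateau += 1
            # on a likelihood ridge the parameters can keep crawling while
            # the objective is flat; a sustained plateau also counts
            if dpar < opts.param_tol or plateau >= opts.plateau_iters:
                converged = True
                break
        else:
            plateau = 0

    if not converged:
        logger.warning("AI-REML did not converge after %d iterations", n_iter)

    sigma2_g = float(theta[0])
    lam = theta[1:1 + L].copy()
    psi = theta[1 + L:1 + 2 * L].copy()
    sigma2_e = float(theta[1 + 2 * L])
    sigma2_ly = float(theta[2 + 2 * L]) if opts.ly_random else 0.0

    # anchor FA1 sign: first nonzero loading >= 0
    flip = False
    for v in lam:
        if abs(v) > 1e-12:
            flip = v < 0
            break
    if flip:
        lam = -lam

    # BLUPs via covariance with the data at the converged parameters
    G_cols = G[:, g_idx]                       # all genotypes x records
    lam_r = lam[loc_idx]
    u_hat = sigma2_g * (G_cols @ Py)
    f_hat = (G_cols * lam_r[None, :]) @ Py
    delta_hat = np.zeros((grm.n, L))
    for l in range(L):
        mask = loc_idx == l
        if mask.any():
            delta_hat[:, l] = psi[l] * (G_cols[:, mask] @ Py[mask])

    env_means = pd.Series(beta, index=envs)
    mu, loc_eff, ly_eff = _decompose_fixed(env_means, env_loc, env_year, locations)

    return FA1Fit(
        mu=mu,
        location_effects=loc_eff,
        ly_effects=ly_eff,
        sigma2_g=sigma2_g,
        loadings=pd.Series(lam, index=locations),
        psi=pd.Series(psi, index=locations),
        sigma2_e=sigma2_e,
        sigma2_ly=sigma2_ly,
        u_hat=pd.Series(u_hat, index=grm.genotype_ids),
        f_hat=pd.Series(f_hat, index=grm.genotype_ids),
        delta_hat=pd.DataFrame(delta_hat, index=grm.genotype_ids, columns=locations),
        loglik=float(ll),
        loglik_trace=trace,
        converged=converged,
        n_iter=n_iter,
        boundary=sorted(boundary),
        genotype_ids=grm.genotype_ids.copy(),
        locations=locations,
        environments=envs,
        env_means=env_means,
        env_location=env_loc.reindex(envs),
        env_year=env_year.reindex(envs),
        observed=observed,
    )


def _decompose_fixed(env_means, env_loc, env_year, locations):
    """Split saturated environment means into mu + L_l + (L:Y)_ly (sum-to-zero)."""
    mu = float(env_means.mean())
    by_loc = {}
    for l in locations:
        envs_l = [e for e in env_means.index if env_loc[e] == l]
        by_loc[l] = float(env_means[envs_l].mean() - mu)
    loc_eff = pd.Series(by_loc)
    years = sorted(env_year.unique())
    ly = pd.DataFrame(np.nan, index=locations, columns=years)
    for e, m in env_means.items():
        ly.loc[env_loc[e], env_year[e]] = m - mu - loc_eff[env_loc[e]]
    return mu, loc_eff, ly


def _zero_variance_fit(pheno, grm, beta, locations, envs, env_loc, env_year,
                       observed, opts):
    L = len(locations)
    env_means = pd.Series(beta, index=envs)
    mu, loc_eff, ly_eff = _decompose_fixed(env_means, env_loc, env_year, locations)
    zeros_g = pd.Series(0.0, index=grm.genotype_ids)
    return FA1Fit(
        mu=mu, location_effects=loc_eff, ly_effects=ly_eff,
        sigma2_g=0.0, loadings=pd.Series(0.0, index=locations),
        psi=pd.Series(0.0, index=locations), sigma2_e=0.0, sigma2_ly=0.0,
        u_hat=zeros_g, f_hat=zeros_g.copy(),
        delta_hat=pd.DataFrame(0.0, index=grm.genotype_ids, columns=locations),
        loglik=float("nan"), loglik_trace=[], converged=True, n_iter=0,
        boundary=[], genotype_ids=grm.genotype_ids.copy(), locations=locations,
        environments=envs, env_means=env_means,
        env_location=env_loc.reindex(envs), env_year=env_year.reindex(envs),
        observed=observed,
    )


def predict_gblups(
    fit: FA1Fit,
    grm: GenomicRelationshipMatrix,
    environments: list | None = None,
) -> GBLUPMatrix:
    """Predicted yield for every genotype x environment cell.

    Cell (g, e) = fixed environment mean + u_hat_g + lambda_l f_hat_g +
    delta_hat_lg with l the location of e.  Genotypes without records in an
    environment (or anywhere) borrow information through G and the FA1
    loadings; the observed mask records which cells had data.
    """
    if not fit.converged:
        raise ConvergenceError("cannot predict from a non-converged fit")
    environments = list(environments) if environments is not None else list(fit.environments)
    unknown = [e for e in environments if e not in fit.environments]
    if unknown:
        raise KeyError(f"environments absent from fit: {unknown}")
    if set(grm.genotype_ids) - set(fit.genotype_ids):
        raise KeyError("GRM contains genotypes unknown to the fit")
    ids = grm.genotype_ids
    u = fit.u_hat.reindex(ids).to_numpy()
    f = fit.f_hat.reindex(ids).to_numpy()
    values = np.empty((len(ids), len(environments)))
    for j, e in enumerate(environments):
        l = fit.env_location[e]
        values[:, j] = (fit.env_means[e] + u + fit.loadings[l] * f
                        + fit.delta_hat[l].reindex(ids).to_numpy())
    mask = fit.observed.reindex(index=ids, columns=environments).fillna(False).astype(bool)
    return GBLUPMatrix(np.asarray(ids, dtype=object), environments, values, mask)


def fit_check_model(
    pheno_checks: pd.DataFrame,
    opts: FitOptions | None = None,
) -> CheckReference:
    """Fit the check model (no GRM) and return per-(environment, MG) means.

    Same mixed model as :func:`fit_fa1_gblup` with the genomic relationship
    replaced by the identity, as checks carry no marker data.  Requires at
    least two checks and a check record in (nearly) every environment.
    """
    pheno_checks = validate_phenotypes(pheno_checks)
    checks = sorted(pheno_checks["genotype"].unique())
    if len(checks) < 2:
        raise ValueError(
            "check model needs >= 2 checks; a single check cannot separate "
            "genotype effects from environment means")
    envs = sorted(pheno_checks["env"].unique())
    mg_of = pheno_checks.groupby("genotype")["maturity_group"].agg(
        lambda s: s.iloc[0] if s.nunique() == 1 else (_ for _ in ()).throw(
            ValueError(f"check {s.name} has inconsistent maturity groups")))
    n_obs = pheno_checks.groupby("env")["genotype"].nunique()
    empty = [e for e in envs if n_obs.get(e, 0) == 0]
    if empty:
        raise ValueError(f"environments with zero check records: {empty}")

    identity = GenomicRelationshipMatrix(
        np.asarray(checks, dtype=object), np.eye(len(checks)), 1.0)
    fit = fit_fa1_gblup(pheno_checks, identity, opts=opts)
    preds = predict_gblups(fit, identity).to_frame()

    mgs = sorted(pd.unique(mg_of))
    table = pd.DataFrame(index=fit.environments, columns=mgs, dtype=float)
    for mg in mgs:
        members = [c for c in checks if mg_of[c] == mg]
        table[mg] = preds.loc[members].mean(axis=0)
    if table.isna().any().any():
        cell = table.stack(dropna=False)
        bad = cell[cell.isna()].index[0]
        raise ValueError(f"no check BLUP for environment x MG cell {bad}")
    return CheckReference(table)
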