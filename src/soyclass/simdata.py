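"""Synthetic marker, trial-design, and phenotype generation.

The generator emulates an early-stage soybean testing program: inbred lines
derived from bi-parental crosses among elite parents, a small panel of
commercial reference checks observed in every trial, and sparse
multi-environment yield trials in which each line is phenotyped in only a
subset of location x year combinations.

Yield records follow the multi-environment genomic mixed model

    y_{lyg} = mu + L_l + (L:Y)_{ly} + u_g + w_{lg} + e_{lyg}

with u ~ N(0, sigma2_g * G) for marker-derived G, and a factor-analytic
order-1 genotype-by-location term w_{lg} = lambda_l * f_g + delta_{lg},
i.e. w ~ N(0, (Lambda Lambda' + Psi) (x) G).  Checks have no marker data;
their latent genetic values are drawn independently of G with a positive
mean advantage, which is what makes the check-referenced selection index
negative on average for the lines.

Randomness: each operation consumes a single ``numpy`` Generator seeded as
``default_rng([seed, k])`` with k = 0 for :func:`simulate_markers` and k = 1
for :func:`simulate_trials`, so regenerating with the same config is
byte-identical and the two stages are independent streams.  Draw order
within :func:`simulate_trials` is documented in its docstring.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .markers import MarkerMatrix, compute_grm
from .selection_index import ClassThresholds, assign_class

#: Fraction of genotypes observed per environment in the default ten-trial
#: design, mimicking the very uneven coverage of a two-year sparse-testing
#: program (a few nearly complete trials, several thin ones).
DEFAULT_SPARSITY_10 = (0.570, 0.584, 0.103, 0.103, 0.501,
                       0.481, 0.046, 0.480, 0.469, 0.078)

MG_LEVELS = (3, 4, 5)


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the synthetic breeding dataset.

    Defaults reproduce the scale and structure of a two-year early-stage
    soybean program: 172 bi-parental families of F4:5-derived lines plus 9
    checks, ~2.5k SNPs, 10 environments (5 locations x 2 years) with very
    sparse testing, and variance components chosen so the induced
    selection-index class split is roughly 17/50/33% high/moderate/low.
    Yield units are kg/ha.
    """

    n_families: int = 172
    lines_per_family: int = 10
    n_checks: int = 9
    n_markers: int = 2479
    n_locations: int = 5
    n_years: int = 2
    maf_range: tuple[float, float] = (0.05, 0.5)
    sigma2_g: float = 36_000.0
    lambda_loadings: np.ndarray | None = None   # default: linspace(100, 140, L)
    psi_diag: np.ndarray | None = None          # default: 8000 per location
    sigma2_e: float = 40_000.0
    mu: float = 4000.0
    location_effects: np.ndarray | None = None  # default: linspace(-400, 400, L)
    ly_effects: np.ndarray | None = None        # default: linspace(-150, 150, L*Y)
    sparsity: float | tuple | np.ndarray | None = None
    missing_rate: float = 0.02
    n_monomorphic: int = 0
    seed: int = 0
    # residual heterozygosity of F4:5-derived lines at segregating loci
    heterozygosity: float = 1.0 / 16.0
    # mean genetic advantage of checks over the line population (kg/ha);
    # elite commercial checks out-yield unselected early-stage lines
    check_advantage: float = 540.0
    # checks are a selected, genetically narrow set: their additive spread is
    # modelled at this fraction of the line-population scale
    check_sd_scale: float = 0.5
    # family-level maturity-group probabilities for MG III / IV / V
    mg_probs: tuple[float, float, float] = (0.082, 0.863, 0.055)
    # draw f and delta with genomic covariance G (the model the fit assumes);
    # False falls back to iid draws across genotypes
    interaction_kinship: bool = True
    thresholds: ClassThresholds = dataclasses.field(default_factory=ClassThresholds)

    def __post_init__(self) -> None:
        for name in ("n_families", "lines_per_family", "n_checks", "n_markers",
                     "n_locations", "n_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo < 1 and 0 < hi < 1 and lo <= hi):
            raise ValueError("maf_range must lie within (0, 1)")
        if self.n_monomorphic >= self.n_markers:
            raise ValueError("n_monomorphic must be smaller than n_markers")
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variances must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    # ---- resolved parameter vectors -------------------------------------
    @property
    def n_lines(self) -> int:
        return self.n_families * self.lines_per_family

    @property
    def n_genotypes(self) -> int:
        return self.n_lines + self.n_checks

    @property
    def n_environments(self) -> int:
        return self.n_locations * self.n_years

    def locations(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.n_locations)]

    def years(self) -> list[int]:
        return [2023 + i for i in range(self.n_years)]

    def environments(self) -> list[str]:
        # year-major enumeration: all locations of year 1, then year 2, ...
        return [f"{l}:{y}" for y in self.years() for l in self.locations()]

    def loadings(self) -> np.ndarray:
        if self.lambda_loadings is not None:
            lam = np.asarray(self.lambda_loadings, dtype=float)
        else:
            lam = np.linspace(100.0, 140.0, self.n_locations)
        if lam.shape != (self.n_locations,):
            raise ValueError("lambda_loadings must have one entry per location")
        return lam

    def psi(self) -> np.ndarray:
        if self.psi_diag is not None:
            psi = np.asarray(self.psi_diag, dtype=float)
        else:
            psi = np.full(self.n_locations, 8000.0)
        if psi.shape != (self.n_locations,):
            raise ValueError("psi_diag must have one entry per location")
        if (psi < 0).any():
            raise ValueError("psi_diag entries must be non-negative")
        return psi

    def loc_effects(self) -> np.ndarray:
        if self.location_effects is not None:
            le = np.asarray(self.location_effects, dtype=float)
        else:
            le = np.linspace(-400.0, 400.0, self.n_locations)
        if le.shape != (self.n_locations,):
            raise ValueError("location_effects must have one entry per location")
        return le

    def locyear_effects(self) -> np.ndarray:
        if self.ly_effects is not None:
            ly = np.asarray(self.ly_effects, dtype=float)
        else:
            ly = np.linspace(-150.0, 150.0, self.n_environments).reshape(
                self.n_years, self.n_locations).T
        if ly.shape != (self.n_locations, self.n_years):
            raise ValueError("ly_effects must be n_locations x n_years")
        return ly

    def sparsity_per_env(self) -> np.ndarray:
        if self.sparsity is None:
            if self.n_environments == 10:
                return np.asarray(DEFAULT_SPARSITY_10, dtype=float)
            return np.full(self.n_environments, 0.55)
        s = np.asarray(self.sparsity, dtype=float)
        if s.ndim == 0:
            s = np.full(self.n_environments, float(s))
        if s.ndim == 1:
            if s.shape != (self.n_environments,):
                raise ValueError("per-environment sparsity must have one entry per environment")
            if ((s < 0) | (s > 1)).any():
                raise ValueError("sparsity probabilities must lie in [0, 1]")
        return s


@dataclasses.dataclass
class SimTruth:
    """Latent values underlying a simulated dataset (for tests and oracles)."""

    genotype_ids: np.ndarray
    locations: list[str]
    environments: list[str]
    true_u: np.ndarray            # per-genotype additive value
    true_f: np.ndarray            # per-genotype factor score
    true_w: np.ndarray            # genotype x location interaction (lambda*f + delta)
    true_msi: np.ndarray          # selection index under the generating model
    true_class: np.ndarray        # yield class implied by true_msi
    observed: pd.DataFrame        # bool genotype x environment design mask

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"genotype": self.genotype_ids, "true_u": self.true_u,
             "true_f": self.true_f, "true_msi": self.true_msi,
             "true_class": self.true_class}
        )
        for i, loc in enumerate(self.locations):
            df[f"true_w_{loc}"] = self.true_w[:, i]
        return df


def _marker_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 0])


def _trial_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1])


def simulate_markers(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    return_complete: bool = False,
):
    """Simulate the marker matrix of breeding lines plus check rows.

    Each family is a cross of two independently drawn inbred parents; lines
    inherit the parental code at loci where parents agree and segregate by
    per-marker Mendelian sampling elsewhere, retaining residual
    heterozygosity ``config.heterozygosity`` (default 1/16, appropriate to
    F4:5-derived lines).  Check rows are included so the matrix covers every
    genotype id, but their marker data are never used downstream (flagged by
    ``genotype_meta.is_check``).  ``n_monomorphic`` columns are forced
    invariant and missing cells are injected at ``missing_rate``.
    """
    rng = _marker_rng(config) if rng is None else rng
    n_fam, lpf, m = config.n_families, config.lines_per_family, config.n_markers
    p = rng.uniform(*config.maf_range, size=m)

    mono_idx = rng.choice(m, size=config.n_monomorphic, replace=False) if config.n_monomorphic else np.array([], dtype=int)
    mono_mask = np.zeros(m, dtype=bool)
    mono_mask[mono_idx] = True
    mono_value = 2.0 * rng.integers(0, 2, size=config.n_monomorphic).astype(float)

    # inbred parent alleles (0/1), two parents per family
    parents = rng.random((2 * n_fam, m)) < p
    # guarantee every non-invariant column is polymorphic across parents
    fixed = parents.all(axis=0) | (~parents).all(axis=0)
    for j in np.flatnonzero(fixed & ~mono_mask):
        flip_row = rng.integers(0, 2 * n_fam)
        parents[flip_row, j] = ~parents[flip_row, j]

    h = config.heterozygosity
    codes = np.empty((config.n_genotypes, m))
    for f in range(n_fam):
        p1 = 2.0 * parents[2 * f].astype(float)
        p2 = 2.0 * parents[2 * f + 1].astype(float)
        seg = p1 != p2
        block = np.tile(p1, (lpf, 1))
        if seg.any():
            u = rng.random((lpf, int(seg.sum())))
            draw = np.where(u < h, 1.0, np.where(u < h + (1 - h) / 2, 0.0, 2.0))
            block[:, seg] = draw
        codes[f * lpf:(f + 1) * lpf] = block
    # checks: unrelated inbreds drawn from the panel allele frequencies
    codes[config.n_lines:] = 2.0 * (rng.random((config.n_checks, m)) < p)
    if config.n_monomorphic:
        codes[:, mono_idx] = mono_value[None, :]

    line_ids = [f"F{f + 1:03d}-{i + 1:02d}" for f in range(n_fam) for i in range(lpf)]
    check_ids = [f"CHK{i + 1:02d}" for i in range(config.n_checks)]
    genotype_ids = np.asarray(line_ids + check_ids, dtype=object)

    fam_mg = rng.choice(MG_LEVELS, size=n_fam, p=config.mg_probs)
    check_mg = np.sort(np.resize(np.asarray(MG_LEVELS), config.n_checks))
    genotype_meta = pd.DataFrame(
        {
            "family": [f"F{f + 1:03d}" for f in range(n_fam) for _ in range(lpf)]
            + ["CHECK"] * config.n_checks,
            "is_check": [False] * config.n_lines + [True] * config.n_checks,
            "maturity_group": list(np.repeat(fam_mg, lpf)) + list(check_mg),
        },
        index=genotype_ids,
    )
    marker_ids = np.asarray([f"SNP{j + 1:05d}" for j in range(m)], dtype=object)
    marker_meta = pd.DataFrame(
        {"chrom": (np.arange(m) % 20) + 1, "pos": (np.arange(m) // 20 + 1) * 1000},
        index=marker_ids,
    )

    complete = MarkerMatrix(genotype_ids, marker_ids, codes.copy(),
                            marker_meta=marker_meta, genotype_meta=genotype_meta)
    released = codes
    if config.missing_rate > 0:
        released = released.copy()
        released[rng.random(released.shape) < config.missing_rate] = np.nan
    markers = MarkerMatrix(genotype_ids, marker_ids, released,
                           marker_meta=marker_meta.copy(), genotype_meta=genotype_meta.copy())
    if return_complete:
        return markers, complete
    return markers


def simulate_trials(
    markers: MarkerMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate sparse multi-environment yield records from a marker matrix.

    ``markers`` must be complete (effects are generated from the true codes,
    before any missingness).  Draw order on the single RNG stream: line
    effects (u, f, delta per location), check effects (u, f, delta), the
    per-environment Bernoulli design mask with its guard rails, then the
    residual matrix.
    """
    rng = _trial_rng(config) if rng is None else rng
    if not markers.is_complete:
        raise ValueError("simulate_trials requires a complete marker matrix "
                         "(generate effects before injecting missingness)")
    if markers.n_genotypes != config.n_genotypes:
        raise ValueError(
            f"marker matrix has {markers.n_genotypes} genotypes, config implies {config.n_genotypes}")
    if markers.genotype_meta is None or "is_check" not in markers.genotype_meta:
        raise ValueError("marker matrix lacks genotype_meta.is_check")

    lam, psi = config.loadings(), config.psi()
    loc_eff, ly_eff = config.loc_effects(), config.locyear_effects()
    L, Y, E = config.n_locations, config.n_years, config.n_environments
    locations, years, envs = config.locations(), config.years(), config.environments()
    is_check = markers.genotype_meta["is_check"].to_numpy(bool)
    n_lines, n_checks, n = int((~is_check).sum()), int(is_check.sum()), markers.n_genotypes

    # genomic square root for G-correlated draws among lines
    G = compute_grm(markers.subset_genotypes(~is_check)).values
    evals, evecs = np.linalg.eigh(G)
    B = evecs * np.sqrt(np.clip(evals, 0.0, None))

    def draw_lines() -> np.ndarray:
        z = rng.standard_normal(n_lines)
        return B @ z if config.interaction_kinship else z

    u = np.empty(n)
    f = np.empty(n)
    delta = np.empty((n, L))
    u[~is_check] = np.sqrt(config.sigma2_g) * (B @ rng.standard_normal(n_lines))
    f[~is_check] = draw_lines()
    for l in range(L):
        delta[~is_check, l] = np.sqrt(psi[l]) * draw_lines()
    # checks: no marker data; latent values drawn independently of G,
    # centered on the elite-check yield advantage
    u[is_check] = config.check_advantage + config.check_sd_scale * np.sqrt(
        config.sigma2_g) * rng.standard_normal(n_checks)
    f[is_check] = rng.standard_normal(n_checks)
    delta[is_check] = np.sqrt(psi)[None, :] * rng.standard_normal((n_checks, L))

    w = lam[None, :] * f[:, None] + delta          # genotype x location
    env_loc = np.array([e % L for e in range(E)])  # year-major enumeration
    env_year = np.array([e // L for e in range(E)])
    fixed_env = config.mu + loc_eff[env_loc] + ly_eff[env_loc, env_year]
    T = fixed_env[None, :] + (u[:, None] + w)[:, env_loc]   # noiseless cell values

    # true selection index: deviation from the same-MG check mean, all envs
    mg = markers.genotype_meta["maturity_group"].to_numpy()
    check_T = T[is_check]
    check_mg = mg[is_check]
    ref = np.empty((len(MG_LEVELS), E))
    for k, level in enumerate(MG_LEVELS):
        sel = check_mg == level
        ref[k] = check_T[sel].mean(axis=0) if sel.any() else np.nan
    # fall back to the nearest maturity group with checks
    have = ~np.isnan(ref[:, 0])
    nearest = {lv: min(np.asarray(MG_LEVELS)[have], key=lambda c, lv=lv: abs(c - lv))
               for lv in MG_LEVELS}
    mg_row = np.array([list(MG_LEVELS).index(nearest[v]) for v in mg])
    true_msi = np.mean(T / ref[mg_row] * 100.0 - 100.0, axis=1)
    true_class = np.asarray([assign_class(v, config.thresholds) for v in true_msi], dtype=object)

    # sparse design: per-environment Bernoulli masks with guard rails
    s = config.sparsity_per_env()
    if isinstance(s, np.ndarray) and s.ndim == 2:
        obs = s.astype(bool)
        if obs.shape != (n, E):
            raise ValueError("explicit design mask must be n_genotypes x n_environments")
        obs = obs.copy()
    else:
        obs = rng.random((n, E)) < s[None, :]
    obs[is_check] = True
    empty = ~obs.any(axis=1)
    for g in np.flatnonzero(empty):
        obs[g, rng.integers(0, E)] = True

    eps = np.sqrt(config.sigma2_e) * rng.standard_normal((n, E))
    yields = T + eps

    recs = []
    for e in range(E):
        for g in np.flatnonzero(obs[:, e]):
            recs.append((markers.genotype_ids[g], locations[env_loc[e]],
                         years[env_year[e]], envs[e], mg[g], bool(is_check[g]),
                         yields[g, e]))
    pheno = pd.DataFrame(
        recs, columns=["genotype", "location", "year", "env", "maturity_group", "is_check", "yield"]
    )
    truth = SimTruth(
        genotype_ids=markers.genotype_ids.copy(),
        locations=locations,
        environments=envs,
        true_u=u,
        true_f=f,
        true_w=w,
        true_msi=true_msi,
        true_class=true_class,
        observed=pd.DataFrame(obs, index=markers.genotype_ids, columns=envs),
    )
    return pheno, truth


@dataclasses.dataclass
class SimulatedDataset:
    markers: MarkerMatrix           # with missing cells injected
    markers_complete: MarkerMatrix  # the underlying complete codes
    pheno: pd.DataFrame
    truth: SimTruth
    config: SimConfig


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate markers and trials in one deterministic run."""
    markers, complete = simulate_markers(config, return_complete=True)
    pheno, truth = simulate_trials(complete, config)
    return SimulatedDataset(markers, complete, pheno, truth, config)


def small_config(**overrides) -> SimConfig:
    """A desk-scale preset (300 lines, 400 markers, 6 environments).

    Same statistical structure as the full-scale default, sized for quick
    runs; keyword overrides are passed through to :class:`SimConfig`.
    """
    base = dict(
        n_families=60, lines_per_family=5, n_checks=6, n_markers=400,
        n_locations=3, n_years=2, sparsity=0.55, missing_rate=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)
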