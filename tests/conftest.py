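import numpy as np
import pandas as pd
import pytest

import soyclass as sc


@pytest.fixture(scope="session")
def tiny_sim():
    """A small complete simulated dataset shared across tests."""
    cfg = sc.small_config(seed=42, n_families=20, lines_per_family=5,
                          n_markers=120, n_checks=6)
    return sc.simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_markers(codes, prefix="g"):
    codes = np.asarray(codes, dtype=float)
    n, m = codes.shape
    return sc.MarkerMatrix([f"{prefix}{i}" for i in range(n)],
                           [f"m{j}" for j in range(m)], codes)


def make_pheno(rows):
    """rows: (genotype, location, year, maturity_group, is_check, yield)."""
    recs = [(g, l, y, f"{l}:{y}", mg, chk, val) for g, l, y, mg, chk, val in rows]
    return pd.DataFrame(recs, columns=["genotype", "location", "year", "env",
                                       "maturity_group", "is_check", "yield"])


def make_gblups(values, genotypes=None, envs=None, observed=None):
    values = np.asarray(values, dtype=float)
    n, e = values.shape
    genotypes = genotypes or [f"g{i}" for i in range(n)]
    envs = envs or [f"E{j}" for j in range(e)]
    mask = pd.DataFrame(True if observed is None else observed,
                        index=genotypes, columns=envs)
    from soyclass.gxe import GBLUPMatrix
    return GBLUPMatrix(np.asarray(genotypes, dtype=object), envs, values, mask)


def make_checks(env_values, envs=None, mgs=(4,)):
    """Constant-per-environment check reference for the given MGs."""
    env_values = np.asarray(env_values, dtype=float)
    envs = envs or [f"E{j}" for j in range(len(env_values))]
    from soyclass.gxe import CheckReference
    table = pd.DataFrame({mg: env_values for mg in mgs}, index=envs)
    return CheckReference(table)
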