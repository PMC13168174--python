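"""Check-referenced selection index (MSI) and three-class yield assignment.

For genotype i the index is the average, over environments j, of its
predicted yield expressed as a percentage deviation from the mean check
BLUP of its maturity group:

    MSI_i = (1/n) * sum_j [ (Y_ij / Check_j) * 100 - 100 ]

so MSI = 0 means performance equal to the checks' mean, -5 means 95% of it,
and +5 means 105%.  Classes: high (MSI >= -5), moderate (-15 <= MSI < -5),
low (MSI < -15); the cutoffs correspond to roughly 95% and 85% of check
performance and are configurable.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_ORDER = ("low", "moderate", "high")
CLASS_RANK = {c: i for i, c in enumerate(CLASS_ORDER)}


@dataclasses.dataclass(frozen=True)
class ClassThresholds:
    """MSI cutoffs for the three yield classes."""

    high_min: float = -5.0
    moderate_min: float = -15.0

    def __post_init__(self) -> None:
        if not self.high_min > self.moderate_min:
            raise ValueError("high_min must exceed moderate_min")


def assign_class(msi: float, thresholds: ClassThresholds | None = None) -> str:
    """Map an MSI value to its yield class (boundaries inclusive upward)."""
    thresholds = thresholds or ClassThresholds()
    if not np.isfinite(msi):
        raise ValueError(f"MSI must be finite, got {msi}")
    if msi >= thresholds.high_min:
        return "high"
    if msi >= thresholds.moderate_min:
        return "moderate"
    return "low"


def compute_msi(
    gblups,
    checks,
    mg_map,
    thresholds: ClassThresholds | None = None,
    observed_only: bool = False,
) -> pd.DataFrame:
    """Compute the selection index and yield class for every genotype.

    Parameters
    ----------
    gblups : GBLUPMatrix
        Complete genotype x environment predicted yields (observed and
        predicted cells).
    checks : CheckReference
        Per (environment, maturity group) mean check BLUP yields.
    mg_map : mapping genotype -> maturity group
    observed_only
        Average only over environments where the genotype was phenotyped
        instead of all environments (the default averages every environment,
        borrowing the model's predictions for unobserved cells).

    Returns a DataFrame with columns genotype, msi, n_env, yield_class.
    """
    thresholds = thresholds or ClassThresholds()
    mg_map = dict(mg_map) if not isinstance(mg_map, dict) else mg_map
    envs = list(gblups.environment_ids)
    values = gblups.to_frame()
    obs = gblups.observed_mask

    rows = []
    for g in gblups.genotype_ids:
        if g not in mg_map:
            raise KeyError(f"no maturity group for genotype {g}")
        mg = mg_map[g]
        use = envs
        if observed_only:
            use = [e for e in envs if bool(obs.loc[g, e])]
            if not use:
                raise ValueError(f"genotype {g} has no observed environment")
        devs = []
        for e in use:
            ref, used_mg = checks.get(e, mg)
            if not ref > 0:
                raise ValueError(
                    f"non-positive check mean ({ref}) in environment {e} for MG {used_mg}")
            devs.append(values.loc[g, e] / ref * 100.0 - 100.0)
        msi = float(np.mean(devs))
        rows.append((g, msi, len(use), assign_class(msi, thresholds)))
    return pd.DataFrame(rows, columns=["genotype", "msi", "n_env", "yield_class"])
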