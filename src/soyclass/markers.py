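"""Marker quality control, imputation, numeric coding, GRM, and PCA.

Genotypes are coded 0 (homozygous minor), 1 (heterozygous), 2 (homozygous
major); missing cells are ``NaN``.  The genomic relationship matrix follows
the realized-additive-relationship construction: with ``M`` the n x m code
matrix and ``p_j`` the allele frequency of marker ``j`` (column mean / 2),

    Z = M - 2 * 1 p',    G = Z Z' / (2 * sum_j p_j (1 - p_j)),

so that G is scaled by the expected marker heterozygosity.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALLOWED_CODES = (0.0, 1.0, 2.0)


@dataclasses.dataclass
class MarkerMatrix:
    """Genotypes x markers grid over {0, 1, 2, missing}.

    Parameters
    ----------
    genotype_ids, marker_ids
        Ordered, unique identifiers for rows and columns.
    codes
        Float array of shape ``(n_genotypes, n_markers)``; missing cells are
        ``NaN``.
    marker_meta
        Optional per-marker metadata (e.g. chromosome / position), indexed by
        marker id.
    genotype_meta
        Optional per-genotype metadata (e.g. family, maturity_group,
        is_check), indexed by genotype id.
    """

    genotype_ids: np.ndarray
    marker_ids: np.ndarray
    codes: np.ndarray
    marker_meta: pd.DataFrame | None = None
    genotype_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.genotype_ids = np.asarray(self.genotype_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2 or self.codes.shape != (
            len(self.genotype_ids),
            len(self.marker_ids),
        ):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.genotype_ids)} genotypes x {len(self.marker_ids)} markers"
            )
        if len(set(self.genotype_ids)) != len(self.genotype_ids):
            raise ValueError("duplicate genotype ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        observed = self.codes[~np.isnan(self.codes)]
        if observed.size and not np.isin(observed, ALLOWED_CODES).all():
            bad = np.setdiff1d(np.unique(observed), ALLOWED_CODES)
            raise ValueError(f"marker codes outside {{0,1,2,missing}}: {bad[:5]}")

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.codes)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.codes).any()

    def subset_markers(self, keep: np.ndarray) -> "MarkerMatrix":
        """Return a copy restricted to markers selected by ``keep`` (bool or index)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        meta = None
        if self.marker_meta is not None:
            meta = self.marker_meta.iloc[keep].copy()
        return MarkerMatrix(
            self.genotype_ids.copy(),
            self.marker_ids[keep],
            self.codes[:, keep].copy(),
            marker_meta=meta,
            genotype_meta=None if self.genotype_meta is None else self.genotype_meta.copy(),
        )

    def subset_genotypes(self, keep: np.ndarray) -> "MarkerMatrix":
        """Return a copy restricted to genotypes selected by ``keep`` (bool, index, or ids)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        elif keep.dtype == object or keep.dtype.kind in "US":
            pos = {g: i for i, g in enumerate(self.genotype_ids)}
            missing = [g for g in keep if g not in pos]
            if missing:
                raise KeyError(f"genotypes not in matrix: {missing[:5]}")
            keep = np.array([pos[g] for g in keep])
        gmeta = None
        if self.genotype_meta is not None:
            gmeta = self.genotype_meta.iloc[keep].copy()
        return MarkerMatrix(
            self.genotype_ids[keep],
            self.marker_ids.copy(),
            self.codes[keep].copy(),
            marker_meta=None if self.marker_meta is None else self.marker_meta.copy(),
            genotype_meta=gmeta,
        )

    def copy(self) -> "MarkerMatrix":
        return MarkerMatrix(
            self.genotype_ids.copy(),
            self.marker_ids.copy(),
            self.codes.copy(),
            marker_meta=None if self.marker_meta is None else self.marker_meta.copy(),
            genotype_meta=None if self.genotype_meta is None else self.genotype_meta.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.genotype_ids, columns=self.marker_ids)


@dataclasses.dataclass
class GenomicRelationshipMatrix:
    """Realized additive relationship matrix with its heterozygosity scaling."""

    genotype_ids: np.ndarray
    values: np.ndarray
    denom: float

    def __post_init__(self) -> None:
        self.genotype_ids = np.asarray(self.genotype_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genotype_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square and match genotype_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric within 1e-10")
        if self.denom <= 0:
            raise ValueError("GRM denominator must be positive")

    @property
    def n(self) -> int:
        return len(self.genotype_ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotype_ids, columns=self.genotype_ids)

    def reindex(self, ids) -> "GenomicRelationshipMatrix":
        pos = {g: i for i, g in enumerate(self.genotype_ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise KeyError(f"genotypes not in GRM: {missing[:5]}")
        idx = np.array([pos[g] for g in ids])
        return GenomicRelationshipMatrix(
            np.asarray(ids, dtype=object), self.values[np.ix_(idx, idx)], self.denom
        )


@dataclasses.dataclass
class PCAResult:
    """Principal-component scores of genotypes on the centered code matrix."""

    genotype_ids: np.ndarray
    scores: np.ndarray
    explained_variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        evf = np.asarray(self.explained_variance_fraction, dtype=float)
        if np.any(np.diff(evf) > 1e-12):
            raise ValueError("explained variance fractions must be non-increasing")
        if np.any(evf < -1e-12) or np.any(evf > 1 + 1e-12):
            raise ValueError("explained variance fractions must lie in [0, 1]")
        self.explained_variance_fraction = evf


class EmptyMarkerSetError(ValueError):
    """Raised when quality control would remove every marker."""


def qc_filter(
    markers: MarkerMatrix, max_missing: float = 0.20
) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Remove monomorphic markers and markers with too much missing data.

    A marker is removed when its non-missing codes take a single value
    (monomorphic) or when its missing fraction is >= ``max_missing``
    (boundary inclusive).  Genotype rows are never touched.

    Returns the filtered matrix and a removal log with columns
    ``marker_id`` and ``reason``.
    """
    if not 0 < max_missing <= 1:
        raise ValueError("max_missing must be in (0, 1]")
    codes = markers.codes
    miss_frac = np.isnan(codes).mean(axis=0)
    n_unique = np.array(
        [np.unique(codes[~np.isnan(codes[:, j]), j]).size for j in range(markers.n_markers)]
    )
    monomorphic = n_unique <= 1
    too_missing = miss_frac >= max_missing
    drop = monomorphic | too_missing
    reasons = []
    for j in np.flatnonzero(drop):
        r = []
        if monomorphic[j]:
            r.append("monomorphic")
        if too_missing[j]:
            r.append(f"missing>={max_missing:.0%}")
        reasons.append((markers.marker_ids[j], ";".join(r)))
    log = pd.DataFrame(reasons, columns=["marker_id", "reason"])
    if drop.all():
        raise EmptyMarkerSetError(
            f"quality control removed all {markers.n_markers} markers"
        )
    logger.info("qc_filter: removed %d of %d markers", int(drop.sum()), markers.n_markers)
    return markers.subset_markers(~drop), log


def impute_markers(
    markers: MarkerMatrix,
    max_iter: int = 10,
    tol: float = 0.0,
    seed: int = 0,
    n_trees: int = 100,
) -> MarkerMatrix:
    """Fill missing marker codes with an iterative random-forest imputer.

    missForest-style scheme: initialise missing cells with the per-column
    mode, then repeatedly re-predict each incomplete column (visited in order
    of increasing missingness) from all other columns with a random-forest
    classifier over {0, 1, 2}.  Iteration stops when the proportion of imputed
    cells that changed between successive passes falls to ``tol`` or below, or
    after ``max_iter`` passes.  Observed cells are never altered; the result
    is deterministic given ``seed``.
    """
    from sklearn.ensemble import RandomForestClassifier

    codes = markers.codes
    miss = np.isnan(codes)
    if not miss.any():
        return markers.copy()
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = markers.marker_ids[all_missing]
        raise ValueError(f"columns with every cell missing cannot be imputed: {bad[:5]}")

    filled = codes.copy()
    incomplete = np.flatnonzero(miss.any(axis=0))
    for j in incomplete:
        obs = codes[~miss[:, j], j]
        vals, counts = np.unique(obs, return_counts=True)
        filled[miss[:, j], j] = vals[np.argmax(counts)]

    order = incomplete[np.argsort(miss.sum(axis=0)[incomplete], kind="stable")]
    total_missing = int(miss.sum())
    for it in range(max_iter):
        n_changed = 0
        for j in order:
            rows = miss[:, j]
            X = np.delete(filled, j, axis=1)
            y_obs = codes[~rows, j].astype(int)
            if np.unique(y_obs).size == 1:
                pred = np.full(rows.sum(), y_obs[0], dtype=float)
            else:
                clf = RandomForestClassifier(
                    n_estimators=n_trees,
                    random_state=(seed + 100_003 * it + int(j)) % (2**31 - 1),
                    n_jobs=1,
                )
                clf.fit(X[~rows], y_obs)
                pred = clf.predict(X[rows]).astype(float)
            n_changed += int(np.sum(pred != filled[rows, j]))
            filled[rows, j] = pred
        change_rate = n_changed / total_missing
        logger.info("impute_markers: pass %d changed %.3f of imputed cells", it + 1, change_rate)
        if change_rate <= tol:
            break
    out = markers.copy()
    out.codes = filled
    return out


def compute_grm(markers: MarkerMatrix) -> GenomicRelationshipMatrix:
    """Compute the genomic relationship matrix G = ZZ' / (2 sum p_j(1-p_j))."""
    if not markers.is_complete:
        raise ValueError("GRM requires a complete marker matrix (impute first)")
    M = markers.codes
    p = M.mean(axis=0) / 2.0
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers are monomorphic: GRM denominator is zero")
    Z = M - 2.0 * p[None, :]
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0
    return GenomicRelationshipMatrix(markers.genotype_ids.copy(), G, denom)


def pca_markers(markers: MarkerMatrix, k: int = 2) -> PCAResult:
    """Principal components of the column-centered marker code matrix."""
    from sklearn.decomposition import PCA

    if not markers.is_complete:
        raise ValueError("PCA requires a complete marker matrix")
    n, m = markers.codes.shape
    k_max = min(n, m)
    if k > k_max:
        warnings.warn(f"k={k} exceeds min(n, m)={k_max}; reduced to {k_max}")
        k = k_max
    X = markers.codes - markers.codes.mean(axis=0)
    pca = PCA(n_components=k, random_state=0)
    scores = pca.fit_transform(X)
    evf = pca.explained_variance_ratio_
    # Components past the matrix rank carry no variance; drop them.
    total = evf.sum()
    rank_ok = evf > max(1e-12, 1e-12 * total)
    if not rank_ok.all():
        kept = int(rank_ok.sum())
        warnings.warn(f"k={k} exceeds matrix rank; reduced to {kept}")
        scores = scores[:, :kept]
        evf = evf[:kept]
    return PCAResult(markers.genotype_ids.copy(), scores, evf)
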