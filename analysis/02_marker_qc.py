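"""Marker quality control, imputation, GRM, and PCA for the breeding lines.

Removes monomorphic / high-missingness markers, fills the remaining missing
calls with the iterative random-forest imputer, computes the genomic
relationship matrix, and saves the first two principal components.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd

import soyclass as sc
from _common import RESULTS, SCRATCH, SEED, ensure_dirs
from soyclass.io import read_marker_csv, write_grm_csv, write_marker_csv


def main() -> None:
    ensure_dirs()
    data = SCRATCH / "data"
    markers = read_marker_csv(data / "markers.csv")
    meta = pd.read_csv(data / "genotype_meta.csv", index_col=0)
    lines = markers.subset_genotypes((~meta["is_check"]).to_numpy())

    filtered, removal_log = sc.qc_filter(lines)
    removal_log.to_csv(RESULTS / "qc_removed.tsv", sep="\t", index=False)
    print(f"QC: {lines.n_markers} markers in, {filtered.n_markers} retained, "
          f"{len(removal_log)} removed")

    imputed = sc.impute_markers(filtered, max_iter=1, seed=SEED, n_trees=25)
    write_marker_csv(imputed, SCRATCH / "markers_imputed.csv")

    grm = sc.compute_grm(imputed)
    write_grm_csv(grm, SCRATCH / "grm.csv")
    print(f"GRM: {grm.n}x{grm.n}, mean diagonal "
          f"{float(grm.values.diagonal().mean()):.3f}, "
          f"min eigenvalue {grm.min_eigenvalue():.2e}")

    pca = sc.pca_markers(imputed, k=2)
    pd.DataFrame(pca.scores, index=pca.genotype_ids,
                 columns=["PC1", "PC2"]).to_csv(SCRATCH / "pca_scores.csv")
    print("PCA variance fractions:",
          [round(float(v), 3) for v in pca.explained_variance_fraction])


if __name__ == "__main__":
    main()
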