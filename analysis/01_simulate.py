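"""Generate the desk-scale synthetic breeding dataset.

Writes the marker matrix (CSV + VCF), the tidy phenotype table, the latent
truth table, and genotype metadata, then prints the scale of the dataset and
the yield-class split implied by the generating model.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd

import soyclass as sc
from _common import SCRATCH, ensure_dirs, study_config


def main() -> None:
    ensure_dirs()
    data = sc.simulate_dataset(study_config())
    out = SCRATCH / "data"
    out.mkdir(exist_ok=True)
    from soyclass.io import write_marker_csv, write_phenotypes, write_vcf

    write_marker_csv(data.markers, out / "markers.csv")
    write_vcf(data.markers, out / "markers.vcf")
    write_phenotypes(data.pheno, out / "phenotypes.csv")
    data.truth.to_frame().to_csv(out / "sim_truth.csv", index=False)
    data.markers.genotype_meta.to_csv(out / "genotype_meta.csv")

    lines = ~data.markers.genotype_meta["is_check"].to_numpy()
    split = pd.Series(data.truth.true_class[lines]).value_counts(normalize=True)
    print(f"simulated {int(lines.sum())} lines + {int((~lines).sum())} checks, "
          f"{data.markers.n_markers} markers, {len(data.pheno)} yield records")
    print("generating-model class split:",
          {k: f"{v:.1%}" for k, v in split.items()})
    print(f"missing marker calls: {data.markers.missing_mask.mean():.2%}")


if __name__ == "__main__":
    main()
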