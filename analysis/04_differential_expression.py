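"""Per-chemical, per-dose differential expression and DEG counts.

Computes log2 fold-changes vs each chemical's vehicle control, per-dose
two-group ANOVA p with BH FDR, and the per-dose significant-gene counts
(FDR < 0.1) whose dose trend separates hepatotoxic from non-toxic chemicals.
Writes tidy tables under results/differential/.
"""
from pathlib import Path

import pandas as pd

from httox import differential as de, io

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "differential"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    values = pd.read_csv(ROOT / "normalized" / "log2rpm.tsv", sep="\t", index_col=0)
    sheet = io.read_sample_sheet(ROOT / "normalized" / "samples_clean.tsv")

    profiles = de.differential_expression(values, sheet, scope="per_dose")
    tidy = pd.concat(
        [p.table.assign(chemical=p.chemical, dose_level=p.dose_level) for p in profiles]
    ).rename_axis("gene_id")
    tidy.to_csv(OUT / "differential.tsv", sep="\t")

    degs = de.deg_counts(profiles, q_threshold=0.1)
    degs.to_csv(OUT / "deg_counts.tsv", sep="\t", index=False)
    fcmat = de.fold_change_matrix(profiles)
    flat = fcmat.copy()
    flat.columns = [f"{c}|{d}" for c, d in fcmat.columns]
    flat.to_csv(OUT / "fold_change_matrix.tsv", sep="\t")

    top = degs.loc[degs.groupby("chemical")["dose_level"].idxmax()]
    print("significant genes (FDR < 0.1) at the top dose:")
    for _, row in top.sort_values("n_deg", ascending=False).iterrows():
        print(f"  {row.chemical:<6} dose {int(row.dose_level)}: {int(row.n_deg)}")


if __name__ == "__main__":
    main()
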