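"""Condition clustering, pairwise correlation and the common-gene consensus.

Clusters (chemical, dose) fold-change columns, computes pairwise Pearson r,
and intersects highest-dose significant genes (joint dose-response ANOVA,
FDR < 0.1) across the hepatotoxic chemicals, comparing the recovered
consensus against the planted 50-gene shared core.  Writes results/cluster/.
"""
from pathlib import Path

import pandas as pd

from httox import cluster_corr as cc, differential as de, io, synth

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "cluster"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    values = pd.read_csv(ROOT / "normalized" / "log2rpm.tsv", sep="\t", index_col=0)
    sheet = io.read_sample_sheet(ROOT / "normalized" / "samples_clean.tsv")
    fcmat = pd.read_csv(ROOT / "differential" / "fold_change_matrix.tsv", sep="\t",
                        index_col=0)

    cols = cc.cluster(fcmat, axis="cols")
    (OUT / "condition_dendrogram.nwk").write_text(cc.to_newick(cols) + "\n")
    corr = cc.condition_correlation(fcmat)
    corr.to_csv(OUT / "condition_correlation.tsv", sep="\t")

    design = synth.default_design()
    hep = [c for c in design.chemicals if design.toxicity_class[c] == "hepatotoxic"]
    profiles = de.differential_expression(values, sheet, scope="across_doses")
    consensus = cc.common_genes(profiles, hep, q_threshold=0.1)
    (OUT / "common_genes.txt").write_text("\n".join(consensus.members) + "\n")
    cc.pairwise_significant_counts(profiles, hep, q_threshold=0.1).to_csv(
        OUT / "pairwise_significant_counts.tsv", sep="\t")

    core = set((ROOT / "study" / "shared_core.txt").read_text().split())
    members = set(consensus.members)
    top_pairs = []
    for i, a in enumerate(hep):
        for b in hep[i + 1:]:
            ca = f"{a}|{design.n_dose_levels(a)}"
            cb = f"{b}|{design.n_dose_levels(b)}"
            common = sorted(members & set(fcmat.index))
            if len(common) > 3:
                top_pairs.append(fcmat.loc[common, ca].corr(fcmat.loc[common, cb]))
    print(f"consensus: {len(members)} genes; recovers "
          f"{len(members & core)}/{len(core)} of the planted shared core "
          f"({len(members - core)} off-core); median top-dose common-gene r "
          f"between hepatotoxic pairs: {pd.Series(top_pairs).median():.3f}")


if __name__ == "__main__":
    main()
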