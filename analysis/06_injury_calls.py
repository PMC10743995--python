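"""Injury-module activation calls and the phenotype-group summary matrix.

Applies the activation rule (z > 2 and p < 0.05 at >= 2 consecutive dose
levels -> consistent; magnitude without high-dose significance ->
inconsistent) to the AAFC score table and summarizes the three cellular
processes per chemical.  Writes results/injury/.
"""
from pathlib import Path

import pandas as pd

from httox.injury_calls import call_all, summarize_phenotypes

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "injury"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scores = pd.read_csv(ROOT / "scores" / "aafc_scores.tsv", sep="\t")
    modules = scores[scores["phenotype_group"] != "none"]
    calls = call_all(modules)
    pd.DataFrame(
        [{"chemical": c.chemical, "module_id": c.module_id,
          "phenotype_group": c.phenotype_group, "status": c.status,
          "supporting_doses": ",".join(map(str, c.supporting_doses))}
         for c in calls]
    ).to_csv(OUT / "injury_calls.tsv", sep="\t", index=False)
    pheno = summarize_phenotypes(calls)
    pheno.to_csv(OUT / "phenotype_summary.tsv", sep="\t")

    consistent = [c for c in calls if c.status == "activated_consistent"]
    print(f"{len(consistent)}/{len(calls)} chemical x module series consistently "
          f"activated; active chemicals: "
          f"{sorted({c.chemical for c in consistent})}")


if __name__ == "__main__":
    main()
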