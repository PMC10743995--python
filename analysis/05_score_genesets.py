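"""Score gene sets per chemical x dose: AFC (signed, pathway direction) and
AAFC (absolute, injury-module disruption) with a 2,000-draw permutation null.

Writes both score tables under results/scores/.
"""
from pathlib import Path

import pandas as pd

from httox.differential import FoldChangeProfile
from httox.geneset_scoring import read_gmt, score_all

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "scores"
SEED = 29
N_PERM = 2000


def load_profiles() -> list[FoldChangeProfile]:
    tidy = pd.read_csv(ROOT / "differential" / "differential.tsv", sep="\t",
                       index_col=0)
    return [
        FoldChangeProfile(chemical=chem, dose_level=int(d), dose_value=float("nan"),
                          n_treated=0, n_control=0,
                          table=grp.drop(columns=["chemical", "dose_level"]))
        for (chem, d), grp in tidy.groupby(["chemical", "dose_level"])
    ]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    profiles = load_profiles()
    sets = read_gmt(ROOT / "study" / "gene_sets.gmt")
    for method in ("aafc", "afc"):
        table = score_all(profiles, sets, method=method, n_perm=N_PERM, seed=SEED)
        table.to_csv(OUT / f"{method}_scores.tsv", sep="\t", index=False)
        modules = table[table["phenotype_group"] != "none"]
        hits = modules[(modules["z"] > 2) & (modules["p"] < 0.05)]
        print(f"{method.upper()}: {len(table)} set x condition scores; "
              f"{len(hits)} injury-module conditions with z > 2 and p < 0.05")


if __name__ == "__main__":
    main()
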