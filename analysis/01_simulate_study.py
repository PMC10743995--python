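"""Simulate the 18-chemical 5-day study on the probe panel.

Generates the full Table-1-style design (18 chemicals x 8-9 dose levels +
vehicle control x 4 replicates) with planted Hill signatures for hepatotoxic
chemicals (50-gene shared core), negative-binomial probe counts with
attenuation, synthetic alignment statistics (2% of samples seeded to fail each
QC criterion), and injury-module/decoy gene sets.  Writes the raw study files
under results/study/.
"""
from pathlib import Path

from httox import io, synth
from httox.geneset_scoring import write_gmt

SEED = 17
N_GENES = 2000
OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = synth.default_design()
    genes = [f"g{i:05d}" for i in range(N_GENES)]
    sig = synth.make_signatures(design, genes, n_signature=300, core_size=50, seed=SEED)
    counts, sheet = synth.generate_counts(design, sig, genes=genes, seed=SEED,
                                          qc_fail_fraction=0.02)
    sets = synth.generate_genesets(sig, genes, n_decoy_sets=10, seed=SEED)

    io.write_counts_tsv(counts.counts, OUT / "counts.tsv")
    io.write_manifest(counts.manifest, OUT / "probe_manifest.tsv")
    io.write_sample_sheet(sheet, OUT / "samples.tsv")
    write_gmt(sets, OUT / "gene_sets.gmt")
    (OUT / "shared_core.txt").write_text("\n".join(sorted(sig.shared_core)) + "\n")

    n_hep = sum(design.toxicity_class[c] == "hepatotoxic" for c in design.chemicals)
    print(f"simulated {len(design.chemicals)} chemicals ({n_hep} hepatotoxic), "
          f"{counts.counts.shape[0]} probes x {counts.counts.shape[1]} samples -> {OUT}")


if __name__ == "__main__":
    main()
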