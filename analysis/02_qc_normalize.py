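"""QC-flag samples, correct attenuation, normalize to gene-level log2 RPM.

Applies the sample thresholds (depth/alignment < 500 K / 40 % / 30 % / 500 K,
probe breadth < 50 %), drops flagged samples and replicate-correlation
outliers, multiplies attenuation factors back in, and writes the
log2(RPM + 1) gene x sample matrix under results/normalized/.
"""
import json
from pathlib import Path

from httox import io
from httox import qc_normalize as qn

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "normalized"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = io.load_probe_counts(ROOT / "study" / "counts.tsv",
                                  ROOT / "study" / "probe_manifest.tsv")
    sheet = io.read_sample_sheet(ROOT / "study" / "samples.tsv")

    report = qn.qc_flag(sheet, counts)
    report.table.to_csv(OUT / "qc_report.tsv", sep="\t")
    clean, sheet_clean = qn.apply_qc(counts, sheet, report)
    norm = qn.normalize(qn.unattenuate(clean))
    outliers = qn.detect_outliers(norm, sheet_clean, r_min=0.8)
    report.outliers = outliers
    if outliers:
        clean, sheet_clean = qn.apply_qc(clean, sheet_clean, report)
        norm = qn.normalize(qn.unattenuate(clean))
    gene = qn.collapse_probes(norm, counts.manifest, policy="mean")

    gene.values.to_csv(OUT / "log2rpm.tsv", sep="\t")
    io.write_sample_sheet(sheet_clean, OUT / "samples_clean.tsv")
    (OUT / "qc_summary.json").write_text(
        json.dumps({"flagged": report.flagged, "outliers": outliers}, indent=2))
    print(f"flagged {len(report.flagged)} samples, {len(outliers)} correlation outliers; "
          f"kept {gene.values.shape[1]} samples x {gene.values.shape[0]} genes -> {OUT}")


if __name__ == "__main__":
    main()
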