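"""Sample QC, attenuation correction, and log2-RPM normalization.

Targeted probe-panel assays attenuate highly expressed probes (counts are
reported divided by a per-probe attenuation factor); analysis multiplies the
factor back in before reads-per-million normalization.  Samples are flagged on
alignment statistics and probe-expression breadth; within-group replicate
correlation flags outliers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeCounts",
    "QCReport",
    "NormalizedExpression",
    "QC_THRESHOLDS",
    "qc_flag",
    "detect_outliers",
    "unattenuate",
    "normalize",
    "collapse_probes",
    "apply_qc",
]

#: Sample-flagging thresholds (strict "below" comparisons): sequencing depth
#: < 500 K reads, total alignment rate < 40 %, unique alignment rate < 30 %,
#: aligned reads < 500 K, probes with >= 5 reads < 50 %.
QC_THRESHOLDS = {
    "total_reads": 500_000.0,
    "total_alignment_rate": 40.0,
    "unique_alignment_rate": 30.0,
    "aligned_reads": 500_000.0,
    "pct_probes_expressed": 50.0,
}

#: Read-count floor defining an "expressed" probe.
EXPRESSED_MIN_READS = 5


@dataclass
class ProbeCounts:
    """Integer probe x sample counts plus the probe manifest.

    ``manifest`` is indexed by probe_id with columns ``gene_id`` and
    ``attenuation_factor`` (>= 1).  ``unattenuated`` records whether the
    attenuation correction has been applied, so it cannot be applied twice.
    """

    counts: pd.DataFrame
    manifest: pd.DataFrame
    unattenuated: bool = False

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate probe ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = self.counts.index.difference(self.manifest.index)
        if len(missing):
            raise ValueError(f"probes missing from manifest: {list(missing[:5])}")
        fac = self.manifest.loc[self.counts.index, "attenuation_factor"]
        if fac.isna().any() or (fac < 1).any():
            raise ValueError("attenuation factors must be present and >= 1")

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def factors(self) -> np.ndarray:
        return self.manifest.loc[self.counts.index, "attenuation_factor"].to_numpy(dtype=float)


@dataclass
class QCReport:
    """Per-sample QC table: observed value and fail flag per criterion,
    plus an ``any_fail`` column (OR of the criterion flags)."""

    table: pd.DataFrame
    outliers: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["any_fail"]])

    @property
    def removed(self) -> list[str]:
        return sorted(set(self.flagged) | set(self.outliers))


@dataclass
class NormalizedExpression:
    """log2(RPM + pseudocount) matrix with normalization metadata."""

    values: pd.DataFrame
    library_sizes: pd.Series
    pseudocount: float = 1.0
    level: str = "probe"


def qc_flag(sheet: pd.DataFrame, counts: ProbeCounts) -> QCReport:
    """Flag samples below the QC thresholds.

    Depth, alignment-rate and aligned-read criteria come from the sample
    sheet; the probe-expression-breadth criterion (fraction of probes with at
    least :data:`EXPRESSED_MIN_READS` reads) is computed from the count matrix
    itself.  Comparisons are strict: a sample exactly at a threshold passes.
    """
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    missing = counts.samples.difference(sheet.index)
    if len(missing):
        raise ValueError(f"samples missing from sheet: {list(missing[:5])}")
    sub = sheet.loc[counts.samples]
    pct_expressed = (counts.counts >= EXPRESSED_MIN_READS).mean(axis=0) * 100.0

    tab = pd.DataFrame(index=counts.samples.copy())
    observed = {
        "total_reads": sub["total_reads"].astype(float),
        "total_alignment_rate": sub["total_alignment_rate"].astype(float),
        "unique_alignment_rate": sub["unique_alignment_rate"].astype(float),
        "aligned_reads": sub["aligned_reads"].astype(float),
        "pct_probes_expressed": pct_expressed,
    }
    any_fail = pd.Series(False, index=tab.index)
    for crit, thr in QC_THRESHOLDS.items():
        tab[crit] = observed[crit].to_numpy()
        fail = observed[crit].to_numpy() < thr
        tab[f"{crit}_fail"] = fail
        any_fail |= fail
    tab["any_fail"] = any_fail
    return QCReport(table=tab)


def detect_outliers(
    norm: NormalizedExpression, sheet: pd.DataFrame, r_min: float = 0.8
) -> list[str]:
    """List samples whose median Pearson correlation with same-group
    (chemical x dose) replicates falls below ``r_min``.

    Groups of size 1 are skipped with a warning.
    """
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    out: list[str] = []
    vals = norm.values
    groups = sheet.loc[sheet.index.intersection(vals.columns)].groupby(
        ["chemical", "dose_level"], sort=True
    )
    for key, grp in groups:
        ids = [s for s in grp.index if s in vals.columns]
        if len(ids) < 2:
            logger.warning("group %s has a single replicate; outlier check skipped", key)
            continue
        sub = vals[ids]
        corr = sub.corr(method="pearson")
        for s in ids:
            others = corr.loc[s, [t for t in ids if t != s]]
            if float(others.median()) < r_min:
                out.append(s)
    return out


def unattenuate(counts: ProbeCounts) -> ProbeCounts:
    """Multiply each probe's counts by its attenuation factor.

    Applies exactly once: calling on an already-unattenuated matrix raises.
    """
    if counts.unattenuated:
        raise ValueError("counts are already unattenuated")
    fac = counts.factors()
    new = counts.counts.mul(fac, axis=0)
    return ProbeCounts(counts=new, manifest=counts.manifest, unattenuated=True)


def normalize(counts: ProbeCounts, pseudocount: float = 1.0) -> NormalizedExpression:
    """log2(count / library_size * 1e6 + pseudocount), per probe and sample.

    Library size is the per-sample sum of (unattenuated) counts; a sample
    whose column is all zero has no defined library size and raises.
    """
    if not counts.unattenuated:
        raise ValueError("normalize expects unattenuated counts; call unattenuate() first")
    lib = counts.counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"all-zero sample columns: {bad[:5]}")
    rpm = counts.counts.div(lib, axis=1) * 1.0e6
    vals = np.log2(rpm + pseudocount)
    return NormalizedExpression(values=vals, library_sizes=lib, pseudocount=pseudocount)


def collapse_probes(
    norm: NormalizedExpression, manifest: pd.DataFrame, policy: str = "mean"
) -> NormalizedExpression:
    """Collapse probe-level values to gene level (default: mean over a gene's
    probes; ``max`` takes the most responsive probe).  Probes without a gene
    mapping are excluded with a warning."""
    if policy not in {"mean", "max"}:
        raise ValueError(f"unknown collapse policy: {policy}")
    gene = manifest["gene_id"].reindex(norm.values.index)
    unmapped = gene.index[gene.isna()]
    if len(unmapped):
        logger.warning("%d probes with no gene mapping excluded", len(unmapped))
    vals = norm.values.loc[gene.notna()]
    grouped = vals.groupby(gene.dropna(), sort=True)
    collapsed = grouped.mean() if policy == "mean" else grouped.max()
    collapsed.index.name = "gene_id"
    return NormalizedExpression(
        values=collapsed,
        library_sizes=norm.library_sizes,
        pseudocount=norm.pseudocount,
        level="gene",
    )


def apply_qc(
    counts: ProbeCounts,
    sheet: pd.DataFrame,
    report: QCReport,
    keep_flagged: bool = False,
) -> tuple[ProbeCounts, pd.DataFrame]:
    """Drop flagged and outlier samples from counts and sheet (default), or
    keep them all with ``keep_flagged=True``."""
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    if keep_flagged:
        return counts, sheet.reset_index()
    drop = set(report.removed)
    keep = [s for s in counts.samples if s not in drop]
    pc = ProbeCounts(
        counts=counts.counts[keep],
        manifest=counts.manifest,
        unattenuated=counts.unattenuated,
    )
    return pc, sheet.loc[keep].reset_index()
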