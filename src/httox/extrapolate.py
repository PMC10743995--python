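"""Sentinel-panel -> whole-transcriptome extrapolation by PC regression.

A sentinel panel (~2,500 genes, S1500+-style) is measured; the remaining
transcriptome is inferred from a training corpus of full profiles: the top-k
principal axes of the centered whole-transcriptome training matrix are
computed, a least-squares map from centered sentinel values to the k component
scores is fitted, and prediction is ``means + loadings @ (map @ centered
sentinel input)``.  All in log2-normalized expression space.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExtrapolationModel",
    "CorpusFilterReport",
    "filter_corpus",
    "train",
    "predict",
    "choose_k",
]

#: Training-corpus sample filters: minimum aligned reads, minimum fraction of
#: non-zero whole-transcriptome genes, minimum fraction of non-zero sentinel
#: genes, and a library-complexity floor on the read share of the top genes.
CORPUS_FILTERS = {
    "min_aligned_reads": 1_000_000,
    "min_frac_nonzero_whole": 0.25,
    "min_frac_nonzero_sentinel": 0.25,
    "max_top_gene_read_fraction": 0.90,
    "top_gene_count": 1000,
}


@dataclass
class CorpusFilterReport:
    """Per-training-sample filter values and pass/fail flags; ``pass`` is the
    AND of the four criteria."""

    table: pd.DataFrame

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["pass"]])


@dataclass
class ExtrapolationModel:
    """Trained PC-regression model.

    ``loadings`` (genes x k) has orthonormal columns (principal axes of the
    centered training matrix); ``coef`` (k x n_sentinel) maps centered
    sentinel vectors to component scores.
    """

    genes: list[str]
    sentinel_genes: list[str]
    gene_means: np.ndarray
    loadings: np.ndarray
    coef: np.ndarray
    k: int
    n_training_samples: int
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        header = {
            "genes": self.genes,
            "sentinel_genes": self.sentinel_genes,
            "k": self.k,
            "n_training_samples": self.n_training_samples,
            "metadata": self.metadata,
        }
        np.savez(
            path,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            gene_means=self.gene_means,
            loadings=self.loadings,
            coef=self.coef,
        )

    @classmethod
    def load(cls, path) -> "ExtrapolationModel":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"].tobytes()).decode())
            return cls(
                genes=list(header["genes"]),
                sentinel_genes=list(header["sentinel_genes"]),
                gene_means=data["gene_means"].copy(),
                loadings=data["loadings"].copy(),
                coef=data["coef"].copy(),
                k=int(header["k"]),
                n_training_samples=int(header["n_training_samples"]),
                metadata=header.get("metadata", {}),
            )


def filter_corpus(
    profiles: pd.DataFrame,
    stats: pd.DataFrame,
    sentinel_genes: list[str],
    filters: dict | None = None,
) -> tuple[CorpusFilterReport, pd.DataFrame]:
    """Apply training-corpus sample filters.

    ``profiles`` is genes x samples on a scale where zero means undetected
    (counts or RPM); ``stats`` must carry ``aligned_reads`` per sample.
    Non-zero fractions are computed from the matrix; the complexity criterion
    requires the top ``top_gene_count`` genes to account for at most
    ``max_top_gene_read_fraction`` of a sample's total signal.
    """
    f = dict(CORPUS_FILTERS)
    if filters:
        f.update(filters)
    stats = stats.set_index("sample_id") if "sample_id" in stats.columns else stats
    missing = profiles.columns.difference(stats.index)
    if len(missing):
        raise ValueError(f"samples missing from stats: {list(missing[:5])}")
    sent = [g for g in sentinel_genes if g in profiles.index]
    x = profiles.to_numpy(dtype=float)
    frac_whole = (x != 0).mean(axis=0)
    frac_sent = (profiles.loc[sent].to_numpy(dtype=float) != 0).mean(axis=0)
    n_top = min(f["top_gene_count"], x.shape[0])
    part = np.partition(x, x.shape[0] - n_top, axis=0)[-n_top:]
    totals = x.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        top_frac = np.where(totals > 0, part.sum(axis=0) / totals, 1.0)
    aligned = stats.loc[profiles.columns, "aligned_reads"].to_numpy(dtype=float)

    tab = pd.DataFrame(
        {
            "aligned_reads": aligned,
            "frac_nonzero_whole": frac_whole,
            "frac_nonzero_sentinel": frac_sent,
            "top_gene_read_fraction": top_frac,
        },
        index=profiles.columns.copy(),
    )
    tab["aligned_reads_pass"] = aligned >= f["min_aligned_reads"]
    tab["frac_nonzero_whole_pass"] = frac_whole >= f["min_frac_nonzero_whole"]
    tab["frac_nonzero_sentinel_pass"] = frac_sent >= f["min_frac_nonzero_sentinel"]
    tab["complexity_pass"] = top_frac <= f["max_top_gene_read_fraction"]
    tab["pass"] = (
        tab["aligned_reads_pass"]
        & tab["frac_nonzero_whole_pass"]
        & tab["frac_nonzero_sentinel_pass"]
        & tab["complexity_pass"]
    )
    report = CorpusFilterReport(table=tab)
    if not tab["pass"].any():
        raise ValueError("no training sample survives the corpus filters")
    return report, profiles[report.retained]


def train(profiles: pd.DataFrame, sentinel_genes: list[str], k: int) -> ExtrapolationModel:
    """Fit the PC-regression model on whole-transcriptome training profiles.

    Centers genes by training means, takes the top-k principal axes of the
    whole matrix (SVD), and least-squares-fits component scores on centered
    sentinel values.  Constant genes are kept (their loading rows are zero)
    but warned about, since constant sentinel genes add nothing to the fit.
    """
    n_samples = profiles.shape[1]
    sent = [g for g in sentinel_genes if g in profiles.index]
    if len(sent) < len(sentinel_genes):
        raise ValueError("sentinel genes missing from training profiles")
    if k <= 0:
        raise ValueError("k must be >= 1")
    if k > min(n_samples - 1, len(sent)):
        raise ValueError(f"k={k} exceeds min(n_samples-1, n_sentinel)")
    x = profiles.to_numpy(dtype=float)
    means = x.mean(axis=1)
    xc = x - means[:, None]
    const = np.ptp(x, axis=1) == 0
    if const.any():
        logger.warning("%d constant genes in training corpus", int(const.sum()))
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # contiguous copies so a serialization round trip is bit-identical
    loadings = np.ascontiguousarray(u[:, :k])  # genes x k, orthonormal columns
    scores = (s[:k, None] * vt[:k])  # k x samples
    sent_idx = profiles.index.get_indexer(sent)
    xs = xc[sent_idx]  # n_sentinel x samples
    coef, *_ = np.linalg.lstsq(xs.T, scores.T, rcond=None)  # n_sentinel x k
    return ExtrapolationModel(
        genes=list(profiles.index),
        sentinel_genes=list(sent),
        gene_means=means,
        loadings=loadings,
        coef=np.ascontiguousarray(coef.T),
        k=k,
        n_training_samples=n_samples,
        metadata={"explained_variance": [float(v) for v in (s[:k] ** 2 / max(n_samples - 1, 1))]},
    )


def predict(
    model: ExtrapolationModel,
    sentinel_profiles: pd.DataFrame,
    passthrough_sentinel: bool = True,
    min_coverage: float = 0.95,
) -> pd.DataFrame:
    """Extrapolate whole-transcriptome profiles from sentinel measurements.

    ``sentinel_profiles`` is genes x samples; sentinel genes absent from the
    input are mean-imputed provided coverage is at least ``min_coverage``
    (otherwise an error).  With ``passthrough_sentinel`` the measured sentinel
    values overwrite their predicted rows.
    """
    sent = model.sentinel_genes
    present = [g for g in sent if g in sentinel_profiles.index]
    coverage = len(present) / len(sent)
    if coverage < min_coverage:
        raise ValueError(f"sentinel coverage {coverage:.2%} below floor {min_coverage:.2%}")
    sent_means = pd.Series(model.gene_means, index=model.genes).loc[sent]
    xs = sentinel_profiles.reindex(sent)
    xs = xs.apply(lambda col: col.fillna(sent_means), axis=0) if xs.isna().any().any() else xs
    xsc = xs.to_numpy(dtype=float) - sent_means.to_numpy()[:, None]
    scores = model.coef @ xsc  # k x samples
    pred = model.gene_means[:, None] + model.loadings @ scores
    out = pd.DataFrame(pred, index=model.genes, columns=sentinel_profiles.columns)
    if passthrough_sentinel:
        out.loc[present] = sentinel_profiles.loc[present].to_numpy(dtype=float)
    return out


def choose_k(
    profiles: pd.DataFrame,
    sentinel_genes: list[str],
    k_grid: list[int] | None = None,
    n_folds: int = 5,
    max_k: int = 50,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Pick k by cross-validated held-out prediction RMSE on the corpus."""
    n = profiles.shape[1]
    if k_grid is None:
        cap = min(max_k, n - max(2, n // n_folds) - 1, len(sentinel_genes))
        k_grid = sorted({k for k in (1, 2, 3, 5, 10, 20, 30, 50) if 1 <= k <= cap})
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    rows = []
    for k in k_grid:
        errs = []
        for fold in folds:
            test_cols = profiles.columns[fold]
            train_cols = profiles.columns.difference(test_cols)
            model = train(profiles[train_cols], sentinel_genes, k)
            pred = predict(model, profiles.loc[sentinel_genes, test_cols],
                           passthrough_sentinel=False)
            truth = profiles[test_cols]
            errs.append(float(np.sqrt(((pred - truth) ** 2).to_numpy().mean())))
        rows.append({"k": k, "cv_rmse": float(np.mean(errs))})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["cv_rmse"].idxmin(), "k"])
    return best, table
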