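"""Plain-text I/O for the pipeline's tabular formats.

Counts travel as TSV (probes x samples, integer) or MatrixMarket with sidecar
row/column files; manifests and sample sheets as TSV; gene sets as GMT
(see :mod:`httox.geneset_scoring`).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .qc_normalize import ProbeCounts

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_manifest",
    "write_manifest",
    "read_sample_sheet",
    "write_sample_sheet",
    "load_probe_counts",
]

MANIFEST_COLUMNS = ["probe_id", "gene_id", "attenuation_factor"]


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe_id"
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("probe_id").to_csv(path, sep="\t")


def read_counts_mtx(path) -> pd.DataFrame:
    """Read MatrixMarket counts with ``<stem>.rows`` / ``<stem>.cols``
    sidecar label files."""
    path = Path(path)
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    rows = path.with_suffix(".rows").read_text().split()
    cols = path.with_suffix(".cols").read_text().split()
    return pd.DataFrame(np.asarray(mat), index=pd.Index(rows, name="probe_id"), columns=cols)


def write_counts_mtx(counts: pd.DataFrame, path) -> None:
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(counts.to_numpy()))
    path.with_suffix(".rows").write_text("\n".join(map(str, counts.index)) + "\n")
    path.with_suffix(".cols").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df.set_index("probe_id")


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.rename_axis("probe_id").to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def load_probe_counts(counts_path, manifest_path, unattenuated: bool = False) -> ProbeCounts:
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        counts = read_counts_mtx(counts_path)
    else:
        counts = read_counts_tsv(counts_path)
    return ProbeCounts(counts=counts, manifest=read_manifest(manifest_path),
                       unattenuated=unattenuated)
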