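"""Per-chemical, per-dose differential expression.

log2 fold-changes are differences of group means on the log2-RPM scale
(treated minus matched vehicle control within the same chemical); per-gene
significance by one-way ANOVA with Benjamini-Hochberg FDR.  The default scope
tests each dose group against its control separately (two-group ANOVA, one BH
family per chemical x dose), which is what per-dose significant-gene counts
require; an across-dose joint ANOVA is available.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "FoldChangeProfile",
    "differential_expression",
    "fold_change_matrix",
    "deg_counts",
]


@dataclass
class FoldChangeProfile:
    """Gene-level log2FC / p / q for one chemical at one dose level.

    ``table`` is indexed by gene with columns ``log2fc``, ``p``, ``q``.
    """

    chemical: str
    dose_level: int
    dose_value: float
    n_treated: int
    n_control: int
    table: pd.DataFrame


def _anova_two_group(treated: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA p-values for two groups, one test per row.

    Equivalent to the pooled-variance two-sided t-test (F(1, n-2) = t^2).
    Zero-variance conventions: all values identical -> p = 1; zero
    within-group variance with differing means -> p = 0.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.f_oneway(treated, control, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
    allvals = np.concatenate([treated, control], axis=1)
    total_const = np.ptp(allvals, axis=1) == 0
    within_const = (np.ptp(treated, axis=1) == 0) & (np.ptp(control, axis=1) == 0)
    p[within_const & ~total_const] = 0.0
    p[total_const] = 1.0
    return p


def differential_expression(
    norm,
    sheet: pd.DataFrame,
    scope: str = "per_dose",
) -> list[FoldChangeProfile]:
    """Fold changes and ANOVA/FDR for every chemical x dose level.

    ``norm`` is a :class:`~httox.qc_normalize.NormalizedExpression` (or any
    object with a gene x sample ``values`` DataFrame).  Each chemical's
    dose-0 group (its vehicle control) is the fold-change baseline.  With
    ``scope="per_dose"`` each dose is tested against control in a two-group
    ANOVA and BH is applied across genes within that chemical x dose; with
    ``scope="across_doses"`` a joint one-way ANOVA over all dose groups plus
    control yields one p per gene per chemical, shared by its dose levels, and
    one BH family per chemical.
    """
    if scope not in {"per_dose", "across_doses"}:
        raise ValueError(f"unknown scope: {scope}")
    values = norm.values if hasattr(norm, "values") and isinstance(norm.values, pd.DataFrame) else norm
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    sheet = sheet.loc[sheet.index.intersection(values.columns)]

    profiles: list[FoldChangeProfile] = []
    for chem, chem_sheet in sheet.groupby("chemical", sort=True):
        ctrl_ids = list(chem_sheet.index[chem_sheet["dose_level"] == 0])
        if not ctrl_ids:
            raise ValueError(f"{chem}: no dose-0 control group")
        ctrl = values[ctrl_ids].to_numpy(dtype=float)
        ctrl_mean = ctrl.mean(axis=1)
        dose_levels = sorted(chem_sheet.loc[chem_sheet["dose_level"] > 0, "dose_level"].unique())

        joint_q = None
        if scope == "across_doses":
            groups = [ctrl] + [
                values[list(chem_sheet.index[chem_sheet["dose_level"] == d])].to_numpy(dtype=float)
                for d in dose_levels
            ]
            small = [g for g in groups if g.shape[1] < 2]
            if small:
                logger.warning("%s: group(s) with <2 replicates in joint ANOVA", chem)
            with np.errstate(divide="ignore", invalid="ignore"):
                p_joint = np.asarray(stats.f_oneway(*groups, axis=1).pvalue, dtype=float)
            allvals = np.concatenate(groups, axis=1)
            p_joint[np.ptp(allvals, axis=1) == 0] = 1.0
            p_joint = np.clip(np.nan_to_num(p_joint, nan=1.0), 0.0, 1.0)
            joint_q = multipletests(p_joint, method="fdr_bh")[1]

        for d in dose_levels:
            trt_ids = list(chem_sheet.index[chem_sheet["dose_level"] == d])
            trt = values[trt_ids].to_numpy(dtype=float)
            log2fc = trt.mean(axis=1) - ctrl_mean
            if scope == "per_dose":
                if trt.shape[1] < 2 or ctrl.shape[1] < 2:
                    logger.warning("%s dose %s: <2 replicates, p set missing", chem, d)
                    p = np.full(values.shape[0], np.nan)
                    q = np.full(values.shape[0], np.nan)
                else:
                    p = _anova_two_group(trt, ctrl)
                    q = multipletests(p, method="fdr_bh")[1]
            else:
                p, q = p_joint, joint_q
            table = pd.DataFrame(
                {"log2fc": log2fc, "p": p, "q": q}, index=values.index.copy()
            )
            dose_value = float(chem_sheet.loc[trt_ids[0], "dose_value"])
            profiles.append(
                FoldChangeProfile(
                    chemical=chem,
                    dose_level=int(d),
                    dose_value=dose_value,
                    n_treated=trt.shape[1],
                    n_control=ctrl.shape[1],
                    table=table,
                )
            )
    return profiles


def fold_change_matrix(profiles: list[FoldChangeProfile]) -> pd.DataFrame:
    """Genes x (chemical, dose_level) matrix of log2FC values."""
    cols = {}
    for prof in sorted(profiles, key=lambda p: (p.chemical, p.dose_level)):
        cols[(prof.chemical, prof.dose_level)] = prof.table["log2fc"]
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["chemical", "dose_level"])
    return out


def deg_counts(profiles: list[FoldChangeProfile], q_threshold: float = 0.1) -> pd.DataFrame:
    """Significant-gene counts (q < threshold) per chemical x dose level."""
    if not (0 < q_threshold <= 1):
        raise ValueError("q_threshold must be in (0, 1]")
    rows = [
        {
            "chemical": prof.chemical,
            "dose_level": prof.dose_level,
            "dose_value": prof.dose_value,
            "n_deg": int((prof.table["q"] < q_threshold).sum()),
            "q_threshold": q_threshold,
        }
        for prof in sorted(profiles, key=lambda p: (p.chemical, p.dose_level))
    ]
    return pd.DataFrame(rows)
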