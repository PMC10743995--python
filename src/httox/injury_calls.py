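"""Liver injury-module activation calls from per-dose z/p series.

A module is *activated (consistent)* for a chemical when its permutation
z-score exceeds 2 with empirical p < 0.05 at two or more consecutive dose
levels.  When some dose clears the z threshold but no such run exists and the
highest z-clearing dose is not significant (magnitude without significance at
the high end), the call is *activated (inconsistent)* — the striped-bar
pattern.  Everything else is *not activated*.  Modules are grouped into three
overarching cellular processes (inflammation, proliferation, degeneration); a
group is active for a chemical when at least one member module is consistently
activated.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleActivationCall",
    "call_activation",
    "call_all",
    "summarize_phenotypes",
]

STATUSES = ("activated_consistent", "activated_inconsistent", "not_activated")


@dataclass
class ModuleActivationCall:
    """Per chemical x module verdict over an ordered dose series."""

    chemical: str
    module_id: str
    phenotype_group: str
    dose_levels: list[int]
    z: list[float]
    p: list[float]
    status: str
    supporting_doses: list[int]


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal runs of True."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def call_activation(
    z: list[float],
    p: list[float],
    dose_levels: list[int] | None = None,
    chemical: str = "",
    module_id: str = "",
    phenotype_group: str = "none",
    z_min: float = 2.0,
    p_max: float = 0.05,
    k_consecutive: int = 2,
    require_consecutive: bool = True,
) -> ModuleActivationCall:
    """Apply the activation rule to one module's dose series.

    ``z`` and ``p`` are ordered by dose rank; missing values (NaN) fail both
    criteria.  ``require_consecutive=False`` relaxes the run requirement to
    "at least ``k_consecutive`` dose levels anywhere"; ``k_consecutive=1``
    reduces to the single-dose criterion.
    """
    z = np.asarray(z, dtype=float)
    p = np.asarray(p, dtype=float)
    if z.size == 0 or z.shape != p.shape:
        raise ValueError("z and p must be non-empty and the same length")
    if dose_levels is None:
        dose_levels = list(range(1, z.size + 1))
    dose_levels = list(dose_levels)

    with np.errstate(invalid="ignore"):
        big = np.nan_to_num(z, nan=-np.inf) > z_min
        sig = np.nan_to_num(p, nan=1.0) < p_max
    qualifying = big & sig

    supporting: list[int] = []
    if require_consecutive:
        consistent = False
        for start, length in _runs_of_true(qualifying):
            if length >= k_consecutive:
                consistent = True
                supporting.extend(dose_levels[start:start + length])
    else:
        consistent = int(qualifying.sum()) >= k_consecutive
        if consistent:
            supporting = [d for d, q in zip(dose_levels, qualifying) if q]

    if consistent:
        status = "activated_consistent"
    elif big.any() and not sig[np.flatnonzero(big)[-1]]:
        # magnitude present, but the highest z-clearing dose is not
        # significant: low-dose-significant / high-dose-not striped pattern
        status = "activated_inconsistent"
        supporting = [d for d, b in zip(dose_levels, big) if b]
    else:
        status = "not_activated"
        supporting = []
    return ModuleActivationCall(
        chemical=chemical,
        module_id=module_id,
        phenotype_group=phenotype_group,
        dose_levels=dose_levels,
        z=[float(v) for v in z],
        p=[float(v) for v in p],
        status=status,
        supporting_doses=sorted(set(supporting)),
    )


def call_all(
    score_table: pd.DataFrame,
    z_min: float = 2.0,
    p_max: float = 0.05,
    k_consecutive: int = 2,
    require_consecutive: bool = True,
) -> list[ModuleActivationCall]:
    """Activation calls for every (chemical, module) in a score table
    (as produced by :func:`httox.geneset_scoring.score_all`)."""
    calls = []
    for (chem, set_id), grp in score_table.groupby(["chemical", "set_id"], sort=True):
        grp = grp.sort_values("dose_level")
        group = grp["phenotype_group"].iloc[0] if "phenotype_group" in grp else "none"
        calls.append(
            call_activation(
                z=grp["z"].to_list(),
                p=grp["p"].to_list(),
                dose_levels=grp["dose_level"].to_list(),
                chemical=chem,
                module_id=set_id,
                phenotype_group=group,
                z_min=z_min,
                p_max=p_max,
                k_consecutive=k_consecutive,
                require_consecutive=require_consecutive,
            )
        )
    return calls


def summarize_phenotypes(calls: list[ModuleActivationCall]) -> pd.DataFrame:
    """Chemical x phenotype-group activity matrix.

    A group is active for a chemical when any member module is
    activated_consistent; modules without a known group are bucketed under
    ``none`` with a warning.
    """
    known = {"inflammation", "proliferation", "degeneration"}
    rows: dict[str, dict[str, bool]] = {}
    columns = sorted(known)
    for call in calls:
        group = call.phenotype_group
        if group not in known:
            if group != "none":
                logger.warning("module %s has unknown phenotype group %r", call.module_id, group)
            group = "none"
            if group not in columns:
                columns = columns + ["none"]
        row = rows.setdefault(call.chemical, {})
        row[group] = row.get(group, False) or call.status == "activated_consistent"
    out = pd.DataFrame(False, index=sorted(rows), columns=columns, dtype=bool)
    for chem, row in rows.items():
        for group, active in row.items():
            out.loc[chem, group] = bool(active)
    out.index.name = "chemical"
    return out
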