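"""Aggregated fold-change gene-set scoring with an empirical permutation null.

Two statistics over a per-gene log2 fold-change vector:

* **AFC** (aggregated fold change): the signed sum of member-gene log2FCs;
  positive scores mean net upregulation of the set.
* **AAFC** (aggregate absolute fold change): the sum of |log2FC| over members;
  the magnitude of disruption regardless of direction.

Significance comes from a gene-label permutation null: random same-size gene
subsets are drawn from the measured universe (without replacement within each
draw, 10,000 draws by default), scored with the same statistic, and the actual
score is located on that null as a z-score and an empirical p-value with
add-one correction (so p is never 0).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "GeneSetScore",
    "read_gmt",
    "write_gmt",
    "afc_score",
    "aafc_score",
    "permutation_null",
    "score_all",
]

PHENOTYPE_GROUPS = ("inflammation", "proliferation", "degeneration")


@dataclass(frozen=True)
class GeneSet:
    """A gene set: KEGG-like pathway or liver injury (histopathology) module.

    ``phenotype_group`` tags injury modules with the overarching cellular
    process (inflammation / proliferation / degeneration); pathways carry
    ``none``.  Members are de-duplicated and order-stable.
    """

    set_id: str
    description: str
    genes: tuple[str, ...]
    category: str = "pathway"
    phenotype_group: str = "none"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"{self.set_id}: gene set must have >= 1 member")
        if len(set(self.genes)) != len(self.genes):
            object.__setattr__(self, "genes", tuple(dict.fromkeys(self.genes)))


@dataclass
class GeneSetScore:
    """A scored set under one (chemical, dose) fold-change profile."""

    set_id: str
    method: str
    score: float
    null_mean: float
    null_sd: float
    z: float  # NaN when null_sd == 0
    p: float
    n_permutations: int
    seed: int
    n_members_used: int
    chemical: str | None = None
    dose_level: int | None = None
    phenotype_group: str = "none"


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file (set_id, description, tab-separated gene ids).

    A ``group=<inflammation|proliferation|degeneration>`` token in the
    description marks an injury module and sets its phenotype group.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            set_id, desc, genes = fields[0], fields[1], fields[2:]
            group = "none"
            for token in desc.split():
                if token.startswith("group="):
                    value = token.split("=", 1)[1]
                    if value in PHENOTYPE_GROUPS:
                        group = value
            category = "injury_module" if group != "none" else "pathway"
            sets.append(
                GeneSet(
                    set_id=set_id,
                    description=desc,
                    genes=tuple(g for g in genes if g),
                    category=category,
                    phenotype_group=group,
                )
            )
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *s.genes]) + "\n")


def _member_values(fc: pd.Series, gene_set: GeneSet) -> np.ndarray:
    members = [g for g in dict.fromkeys(gene_set.genes) if g in fc.index]
    if not members:
        raise ValueError(f"{gene_set.set_id}: no member gene present in the fold-change vector")
    return fc.loc[members].to_numpy(dtype=float)


def afc_score(fc: pd.Series, gene_set: GeneSet) -> float:
    """Signed sum of member log2 fold-changes (absent members are skipped)."""
    return float(_member_values(fc, gene_set).sum())


def aafc_score(fc: pd.Series, gene_set: GeneSet) -> float:
    """Sum of absolute member log2 fold-changes; always >= 0."""
    return float(np.abs(_member_values(fc, gene_set)).sum())


def _null_sums(values: np.ndarray, m: int, n_perm: int, rng: np.random.Generator,
               chunk: int = 2000) -> np.ndarray:
    """Sums of ``n_perm`` random m-subsets of ``values`` (without replacement
    within a draw), chunked to bound memory."""
    n = values.size
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        out[done:done + b] = values[idx].sum(axis=1)
        done += b
    return out


def permutation_null(
    fc: pd.Series,
    gene_set: GeneSet,
    method: str = "aafc",
    n_perm: int = 10_000,
    seed: int = 0,
    tail: str | None = None,
    rng: np.random.Generator | None = None,
) -> GeneSetScore:
    """Score a set and locate it on a random-gene-set null.

    The universe is every gene with a fold-change value, in canonical (sorted)
    gene order so results do not depend on input ordering.  ``tail`` defaults
    to two-sided for AFC (both directions of pathway regulation are of
    interest) and upper for AAFC (pure disruption magnitude).  p uses the
    add-one correction (1 + #{null >= actual}) / (n_perm + 1); when the null
    is degenerate (sd 0, e.g. set == universe) z is NaN but p is still defined.
    """
    if method not in {"afc", "aafc"}:
        raise ValueError(f"unknown method: {method}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail is None:
        tail = "two_sided" if method == "afc" else "upper"
    if tail not in {"upper", "two_sided"}:
        raise ValueError(f"unknown tail: {tail}")

    fc = fc[~fc.isna()]
    fc = fc.loc[sorted(fc.index)]
    members = [g for g in dict.fromkeys(gene_set.genes) if g in fc.index]
    m = len(members)
    if m == 0:
        raise ValueError(f"{gene_set.set_id}: no member gene present in the fold-change vector")
    if m > fc.size:
        raise ValueError("set larger than the measured universe")

    universe = fc.to_numpy(dtype=float)
    if method == "aafc":
        universe = np.abs(universe)
        actual = float(np.abs(fc.loc[members]).sum())
    else:
        actual = float(fc.loc[members].sum())

    if rng is None:
        rng = np.random.default_rng(seed)
    null = _null_sums(universe, m, n_perm, rng)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    z = (actual - null_mean) / null_sd if null_sd > 0 else math.nan
    if tail == "upper":
        exceed = int(np.count_nonzero(null >= actual))
    else:
        exceed = int(np.count_nonzero(np.abs(null - null_mean) >= abs(actual - null_mean)))
    p = (1 + exceed) / (n_perm + 1)
    return GeneSetScore(
        set_id=gene_set.set_id,
        method=method,
        score=actual,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p=p,
        n_permutations=n_perm,
        seed=seed,
        n_members_used=m,
        phenotype_group=gene_set.phenotype_group,
    )


def score_all(
    profiles,
    sets: list[GeneSet],
    method: str = "aafc",
    n_perm: int = 10_000,
    seed: int = 0,
    tail: str | None = None,
) -> pd.DataFrame:
    """Score every set under every (chemical, dose) fold-change profile.

    ``profiles`` is an iterable of objects with ``chemical``, ``dose_level``
    and a ``table`` DataFrame carrying a ``log2fc`` column (see
    :mod:`httox.differential`).  Null draws are shared across sets of equal
    size within one (chemical, dose) profile — statistically indistinguishable
    from independent draws since draws never depend on set identity — and the
    generator stream for each (profile, set size) is derived deterministically
    from ``seed``, so identical sets get identical scores and reruns are
    reproducible.
    """
    rows = []
    profiles = list(profiles)
    for prof_i, prof in enumerate(sorted(profiles, key=lambda p: (p.chemical, p.dose_level))):
        fc = prof.table["log2fc"]
        fc = fc[~fc.isna()].loc[sorted(fc.dropna().index)]
        for s in sorted(sets, key=lambda s: s.set_id):
            m = len([g for g in dict.fromkeys(s.genes) if g in fc.index])
            if m == 0:
                raise ValueError(f"{s.set_id}: no member gene present for {prof.chemical} dose {prof.dose_level}")
            # one stream per (profile, set size): equal-size sets share draws
            child_seed = np.random.SeedSequence([seed, prof_i, m])
            score = permutation_null(
                fc, s, method=method, n_perm=n_perm, seed=seed, tail=tail,
                rng=np.random.default_rng(child_seed),
            )
            score.chemical = prof.chemical
            score.dose_level = prof.dose_level
            rows.append(score)
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in rows],
            "method": [r.method for r in rows],
            "chemical": [r.chemical for r in rows],
            "dose_level": [r.dose_level for r in rows],
            "phenotype_group": [r.phenotype_group for r in rows],
            "score": [r.score for r in rows],
            "null_mean": [r.null_mean for r in rows],
            "null_sd": [r.null_sd for r in rows],
            "z": [r.z for r in rows],
            "p": [r.p for r in rows],
            "n_perm": [r.n_permutations for r in rows],
            "seed": [r.seed for r in rows],
            "n_members_used": [r.n_members_used for r in rows],
        }
    )
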