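"""Synthetic study-data generator.

Emulates a 5-day oral-gavage rat study measured on a targeted probe panel
(TempO-Seq style): 18 chemicals x 8-9 dose levels + vehicle control x 4
replicates, with planted monotone (Hill-in-dose-rank) expression signatures
for toxic chemicals, negative-binomial count noise, per-sample library-size
variation, per-probe attenuation factors, and a low-rank cross-gene
covariance training corpus so sentinel-to-transcriptome extrapolation is
learnable.  Every downstream stage of the pipeline is testable against data
from this module without external downloads.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geneset_scoring import GeneSet
from .qc_normalize import ProbeCounts

__all__ = [
    "StudyDesign",
    "SignatureSpec",
    "SynthCorpus",
    "default_design",
    "make_signatures",
    "generate_counts",
    "generate_corpus",
    "generate_genesets",
]

TOXICITY_CLASSES = ("non_toxic", "non_hepatotoxic", "hepatotoxic")

#: QC thresholds used when seeding deliberate QC failures (mirrors qc_normalize).
_QC_FAIL_VALUES = {
    "total_reads": 400_000.0,
    "aligned_reads": 400_000.0,
    "total_alignment_rate": 30.0,
    "unique_alignment_rate": 20.0,
}


@dataclass
class StudyDesign:
    """Chemicals, dose grids, toxicity classes and replication of a study.

    ``dose_values`` holds the non-zero dose grid (mg/kg) per chemical, strictly
    increasing; a dose-0 vehicle-control group is implicit for every chemical.
    """

    chemicals: list[str]
    dose_values: dict[str, list[float]]
    toxicity_class: dict[str, str]
    vehicle: dict[str, str]
    n_replicates: int = 4

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for chem in self.chemicals:
            doses = np.asarray(self.dose_values[chem], dtype=float)
            if doses.size < 2:
                raise ValueError(f"{chem}: need >= 2 dose levels plus control")
            if np.any(doses <= 0):
                raise ValueError(f"{chem}: dose values must be positive")
            if np.any(np.diff(doses) <= 0):
                raise ValueError(f"{chem}: dose values must be strictly increasing")
            if self.toxicity_class[chem] not in TOXICITY_CLASSES:
                raise ValueError(f"{chem}: unknown toxicity class {self.toxicity_class[chem]}")

    def n_dose_levels(self, chemical: str) -> int:
        return len(self.dose_values[chemical])


@dataclass
class SignatureSpec:
    """Planted dose-responsive signatures.

    ``effect_direction`` maps chemical -> {gene: +1/-1}; the expected log2
    expression of a signature gene g at dose rank d (1..D, 0 = control) is

        baseline_g + direction_g * effect_g * d^h / (d^h + ed50_g^h)

    a Hill curve in dose *rank*, so chemicals with different absolute mg/kg
    grids produce comparable planted effects.  Per-gene saturation effects
    ``effect_size`` (<= ``max_effect``) and per-gene ``gene_ed50`` emulate the
    heterogeneous potencies of real dose-response signatures (genes recruit
    gradually as dose rises, rather than all at once); genes without an entry
    fall back to ``max_effect`` and ``ed50_rank``.  ``shared_core`` is a gene
    set common to the signature of every hepatotoxic chemical, emulating the
    common-gene structure seen across strongly perturbing hepatotoxicants.
    """

    effect_direction: dict[str, dict[str, int]]
    max_effect: float = 2.0
    hill_coefficient: float = 4.0
    ed50_rank: float | None = None  # default: mid-rank per chemical
    shared_core: set[str] = field(default_factory=set)
    effect_size: dict[str, dict[str, float]] = field(default_factory=dict)
    gene_ed50: dict[str, dict[str, float]] = field(default_factory=dict)

    def signature_genes(self, chemical: str) -> set[str]:
        return set(self.effect_direction.get(chemical, {}))

    def validate(self, design: StudyDesign) -> None:
        for chem in design.chemicals:
            genes = self.signature_genes(chem)
            cls = design.toxicity_class[chem]
            if cls == "non_toxic" and genes:
                raise ValueError(f"{chem}: non_toxic chemicals must have empty signatures")
            if cls == "hepatotoxic" and not self.shared_core <= genes:
                raise ValueError(f"{chem}: shared_core must be a subset of every hepatotoxic signature")


@dataclass
class SynthCorpus:
    """Low-rank training corpus for the extrapolation model.

    Whole-transcriptome profiles are ``means + loadings @ scores + noise``;
    the sentinel view is the row subset used as the measured panel.
    """

    genes: list[str]
    sentinel_genes: list[str]
    loadings: np.ndarray  # genes x k
    scores: np.ndarray  # k x samples
    gene_means: np.ndarray
    noise_sd: float


def default_design(n_replicates: int = 4) -> StudyDesign:
    """The 18-chemical study design: dose grids in mg/kg (EE2 in ug/kg),
    gavage vehicles, and the chronic-study toxicity classification."""
    doses = {
        "ACR": [0.078, 0.156, 0.3125, 0.625, 1.25, 2.5, 5, 10],
        "BDCA": [1.25, 2.5, 5, 10, 20, 40, 80, 160],
        "COU": [3.125, 6.25, 12.5, 25, 50, 100, 200, 400],
        "DEHP": [8, 16, 31.25, 62.5, 125, 250, 500, 1000],
        "DE71": [0.38, 0.75, 1.5, 3, 15, 50, 100, 200, 500],
        "EE2": [0.02, 0.067, 0.2, 0.6, 1.8, 5.4, 16.2, 48.6],
        "FEN": [8, 16, 31.25, 62.5, 125, 250, 500, 1000],
        "FUR": [0.125, 0.25, 0.5, 1, 2, 4, 8, 16],
        "GIN": [39.1, 78.125, 156.25, 312.5, 625, 1250, 2500, 5000],
        "HCB": [0.004, 0.015, 0.0625, 0.25, 1, 4, 16, 64],
        "MET": [4.625, 9.25, 18.5, 37, 75, 150, 300, 600],
        "MTE": [39.1, 78.125, 156.25, 312.5, 625, 937.5, 1250, 1750],
        "PFOA": [0.156, 0.3125, 0.625, 1.25, 2.5, 5, 10, 20],
        "PUL": [2.4, 4.7, 9.4, 18.75, 37.5, 75, 150, 300],
        "TBBPA": [4, 8, 16, 125, 250, 500, 1000, 2000],
        "TCAB": [0.1, 0.3, 1, 3, 10, 30, 100, 200, 400],
        "TCPP": [18.75, 37.5, 75, 150, 300, 600, 1000, 2000],
        "THU": [1.5, 3, 6.25, 12.5, 25, 50, 100, 200],
    }
    vehicles = {
        "ACR": "water", "BDCA": "water", "GIN": "water",
        "COU": "corn_oil", "DEHP": "corn_oil", "DE71": "corn_oil",
        "EE2": "corn_oil", "FUR": "corn_oil", "HCB": "corn_oil",
        "MTE": "corn_oil", "PUL": "corn_oil", "TBBPA": "corn_oil",
        "TCAB": "corn_oil_acetone",
        "FEN": "methylcellulose", "MET": "methylcellulose",
        "TCPP": "methylcellulose", "THU": "methylcellulose",
        "PFOA": "tween80",
    }
    hepatotoxic = {"COU", "DE71", "DEHP", "FEN", "FUR", "HCB", "MET",
                   "PFOA", "PUL", "TCAB", "TCPP"}
    non_hepatotoxic = {"EE2", "TBBPA", "MTE"}
    tox = {
        c: ("hepatotoxic" if c in hepatotoxic
            else "non_hepatotoxic" if c in non_hepatotoxic
            else "non_toxic")
        for c in doses
    }
    return StudyDesign(
        chemicals=sorted(doses),
        dose_values={c: list(map(float, v)) for c, v in doses.items()},
        toxicity_class=tox,
        vehicle=vehicles,
        n_replicates=n_replicates,
    )


def make_signatures(
    design: StudyDesign,
    genes: list[str],
    n_signature: int = 120,
    core_size: int = 50,
    frac_up: float = 0.7,
    max_effect: float = 2.0,
    hill_coefficient: float = 4.0,
    ed50_rank: float | None = None,
    seed: int = 0,
) -> SignatureSpec:
    """Draw per-chemical signature gene sets with a shared hepatotoxic core.

    Hepatotoxic chemicals get ``n_signature`` genes including the shared core
    (all core genes share the same direction across chemicals, predominantly
    up, so top-dose profiles of different hepatotoxicants correlate);
    non-hepatotoxic chemicals get a half-size private signature; non-toxic
    chemicals get none.

    Core genes are strong responders (full ``max_effect``, half-maximal at
    mid-rank); private genes draw heterogeneous saturation effects
    (0.3-1 x ``max_effect``) and half-maximal ranks spread over the upper
    dose range, so significant-gene counts keep climbing with dose instead of
    saturating — the dose-dependent recruitment seen in real exposure studies.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    if core_size > n_signature:
        raise ValueError("core_size cannot exceed n_signature")
    core = list(rng.choice(genes, size=core_size, replace=False))
    core_dir = {g: (1 if rng.random() < frac_up else -1) for g in core}
    effect_direction: dict[str, dict[str, int]] = {}
    effect_size: dict[str, dict[str, float]] = {}
    gene_ed50: dict[str, dict[str, float]] = {}
    non_core = [g for g in genes if g not in core_dir]
    for chem in design.chemicals:
        cls = design.toxicity_class[chem]
        if cls == "non_toxic":
            effect_direction[chem] = {}
            effect_size[chem] = {}
            gene_ed50[chem] = {}
            continue
        n_levels = design.n_dose_levels(chem)
        mid = ed50_rank if ed50_rank is not None else n_levels / 2.0
        if cls == "hepatotoxic":
            n_private = n_signature - core_size
            private = rng.choice(non_core, size=n_private, replace=False)
            dirs = dict(core_dir)
            sizes = {g: max_effect for g in core_dir}
            ed50s = {g: mid for g in core_dir}
        else:  # non_hepatotoxic: private-only signature, no shared core
            private = rng.choice(non_core, size=max(n_signature // 2, 1), replace=False)
            dirs, sizes, ed50s = {}, {}, {}
        for g in private:
            g = str(g)
            dirs[g] = 1 if rng.random() < frac_up else -1
            sizes[g] = float(rng.uniform(0.3, 1.0)) * max_effect
            ed50s[g] = float(rng.uniform(0.45, 1.05)) * n_levels
        effect_direction[chem] = dirs
        effect_size[chem] = sizes
        gene_ed50[chem] = ed50s
    sig = SignatureSpec(
        effect_direction=effect_direction,
        max_effect=max_effect,
        hill_coefficient=hill_coefficient,
        ed50_rank=ed50_rank,
        shared_core=set(core),
        effect_size=effect_size,
        gene_ed50=gene_ed50,
    )
    sig.validate(design)
    return sig


def _hill(rank: np.ndarray, h: float, ed50: float) -> np.ndarray:
    rank = np.asarray(rank, dtype=float)
    out = np.zeros_like(rank)
    pos = rank > 0
    out[pos] = rank[pos] ** h / (rank[pos] ** h + ed50**h)
    return out


def generate_counts(
    design: StudyDesign,
    sig: SignatureSpec,
    genes: list[str] | None = None,
    n_genes: int = 2000,
    seed: int = 0,
    dispersion: float = 0.1,
    baseline_log2_mean: float = 9.0,
    baseline_log2_sd: float = 2.0,
    library_size_sd: float = 0.2,
    attenuated_fraction: float = 0.1,
    attenuation_range: tuple[float, float] = (1.0, 50.0),
    n_probes_per_gene: int = 1,
    qc_fail_fraction: float = 0.0,
) -> tuple[ProbeCounts, pd.DataFrame]:
    """Simulate measured probe counts and the sample sheet for a study design.

    Counts are negative-binomial around ``2**expected_log2 * library_factor``
    with ``var = mu * (1 + dispersion * mu)``; the top ``attenuated_fraction``
    of probes by baseline expression carry log-uniform attenuation factors in
    ``attenuation_range`` and their *measured* counts are the unattenuated
    draws divided by the factor (rounded), as a targeted-sequencing assay
    reports them.  ``qc_fail_fraction`` of samples are seeded to fail each
    sample-QC criterion (depth, alignment rates, aligned reads, probe
    expression breadth) so QC flagging is exercisable.

    Returns the measured :class:`~httox.qc_normalize.ProbeCounts` (attenuated,
    integer) and the sample sheet with synthetic alignment statistics.
    """
    sig.validate(design)
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"g{i:05d}" for i in range(n_genes)]
    genes = list(genes)
    for chem in design.chemicals:
        missing = sig.signature_genes(chem) - set(genes)
        if missing:
            raise ValueError(f"signature genes absent from gene list: {sorted(missing)[:5]}")

    # sample sheet
    rows = []
    for chem in design.chemicals:
        dose_grid = [0.0] + list(design.dose_values[chem])
        for level, dose in enumerate(dose_grid):
            for rep in range(1, design.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{chem}_d{level}_r{rep}",
                        "chemical": chem,
                        "dose_level": level,
                        "dose_value": dose,
                        "vehicle": design.vehicle[chem],
                        "replicate": rep,
                    }
                )
    sheet = pd.DataFrame(rows)
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in design")
    n_samples = len(sheet)
    n_g = len(genes)

    baseline = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_g)

    # expected log2 expression per gene x sample
    expected = np.tile(baseline[:, None], (1, n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}
    for chem in design.chemicals:
        dirs = sig.effect_direction.get(chem, {})
        if not dirs:
            continue
        n_levels = design.n_dose_levels(chem)
        default_ed50 = sig.ed50_rank if sig.ed50_rank is not None else n_levels / 2.0
        cols = sheet.index[sheet["chemical"] == chem].to_numpy()
        ranks = sheet.loc[cols, "dose_level"].to_numpy(dtype=float)
        sig_genes = list(dirs)
        gi = np.array([gene_index[g] for g in sig_genes])
        dvec = np.array([dirs[g] for g in sig_genes], dtype=float)
        sizes = np.array(
            [sig.effect_size.get(chem, {}).get(g, sig.max_effect) for g in sig_genes]
        )
        ed50s = np.array(
            [sig.gene_ed50.get(chem, {}).get(g, default_ed50) for g in sig_genes]
        )
        h = sig.hill_coefficient
        with np.errstate(divide="ignore"):
            rk = ranks[None, :] ** h
            hill = rk / (rk + ed50s[:, None] ** h)
        hill[:, ranks == 0] = 0.0
        expected[np.ix_(gi, cols)] += (dvec * sizes)[:, None] * hill

    lib_factor = np.exp(rng.normal(0.0, library_size_sd, size=n_samples))
    mu = (2.0**expected) * lib_factor[None, :]
    if dispersion > 0:
        n_nb = 1.0 / dispersion
        p_nb = n_nb / (n_nb + mu)
        true_counts = rng.negative_binomial(n_nb, p_nb)
    else:
        true_counts = rng.poisson(mu)

    # probes: replicate each gene's expectation per probe, attenuate the top
    # expressed fraction
    probe_ids, probe_gene = [], []
    for g in genes:
        for j in range(1, n_probes_per_gene + 1):
            probe_ids.append(f"{g}_pr{j}")
            probe_gene.append(g)
    if n_probes_per_gene > 1:
        rep_idx = np.repeat(np.arange(n_g), n_probes_per_gene)
        mu_p = mu[rep_idx]
        if dispersion > 0:
            p_nb = (1.0 / dispersion) / (1.0 / dispersion + mu_p)
            true_counts = rng.negative_binomial(1.0 / dispersion, p_nb)
        else:
            true_counts = rng.poisson(mu_p)
        base_p = baseline[rep_idx]
    else:
        base_p = baseline
    n_probes = len(probe_ids)

    factors = np.ones(n_probes)
    n_att = int(round(attenuated_fraction * n_probes))
    if n_att > 0:
        top = np.argsort(base_p)[-n_att:]
        lo, hi = attenuation_range
        factors[top] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_att))
    measured = np.rint(true_counts / factors[:, None]).astype(np.int64)

    manifest = pd.DataFrame(
        {"gene_id": probe_gene, "attenuation_factor": factors},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    counts = pd.DataFrame(measured, index=manifest.index, columns=sheet["sample_id"].to_numpy())

    # synthetic alignment statistics: comfortably passing by default
    total = rng.uniform(2.0e6, 4.0e6, size=n_samples)
    t_rate = rng.uniform(70.0, 95.0, size=n_samples)
    u_rate = rng.uniform(55.0, 85.0, size=n_samples)
    aligned = total * t_rate / 100.0
    expressed = (counts.to_numpy() >= 5).mean(axis=0) * 100.0

    if qc_fail_fraction > 0:
        for col, bad in _QC_FAIL_VALUES.items():
            idx = rng.choice(n_samples, size=max(1, int(round(qc_fail_fraction * n_samples))), replace=False)
            if col == "total_reads":
                total[idx] = bad
            elif col == "aligned_reads":
                aligned[idx] = bad
            elif col == "total_alignment_rate":
                t_rate[idx] = bad
            else:
                u_rate[idx] = bad
        # probe-breadth failures are seeded in the matrix itself
        idx = rng.choice(n_samples, size=max(1, int(round(qc_fail_fraction * n_samples))), replace=False)
        for j in idx:
            kill = rng.choice(n_probes, size=int(0.6 * n_probes), replace=False)
            counts.iloc[kill, j] = 0
        expressed = (counts.to_numpy() >= 5).mean(axis=0) * 100.0

    sheet["total_reads"] = np.floor(total).astype(np.int64)
    sheet["aligned_reads"] = np.floor(aligned).astype(np.int64)
    sheet["total_alignment_rate"] = t_rate
    sheet["unique_alignment_rate"] = u_rate
    sheet["pct_probes_expressed"] = expressed
    return ProbeCounts(counts=counts, manifest=manifest), sheet


def generate_corpus(
    n_samples: int,
    n_genes: int,
    n_sentinel: int,
    k: int,
    noise_sd: float,
    seed: int = 0,
) -> tuple[SynthCorpus, pd.DataFrame]:
    """Low-rank whole-transcriptome training corpus.

    Profiles (genes x samples, log2-expression scale) are
    ``gene_means + loadings @ scores + N(0, noise_sd)``; the sentinel list is a
    seeded subset of the gene list.  With ``noise_sd = 0`` the centered matrix
    has numerical rank exactly ``k``.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    if n_sentinel >= n_genes:
        raise ValueError("n_sentinel must be < n_genes")
    if k > n_sentinel:
        raise ValueError("k must be <= n_sentinel")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    sentinel = sorted(rng.choice(genes, size=n_sentinel, replace=False))
    loadings = rng.normal(0.0, 1.0, size=(n_genes, k))
    scores = rng.normal(0.0, 1.0, size=(k, n_samples))
    gene_means = rng.normal(7.0, 1.0, size=n_genes)
    profiles = gene_means[:, None] + loadings @ scores
    if noise_sd > 0:
        profiles = profiles + rng.normal(0.0, noise_sd, size=profiles.shape)
    prof = pd.DataFrame(profiles, index=genes, columns=[f"s{j:05d}" for j in range(n_samples)])
    corpus = SynthCorpus(
        genes=genes,
        sentinel_genes=list(sentinel),
        loadings=loadings,
        scores=scores,
        gene_means=gene_means,
        noise_sd=noise_sd,
    )
    return corpus, prof


def generate_genesets(
    sig: SignatureSpec,
    universe: list[str],
    n_decoy_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
    planted_size: int = 30,
    phenotype_groups: tuple[str, ...] = ("inflammation", "proliferation", "degeneration"),
) -> list[GeneSet]:
    """Planted injury-module-like sets plus random decoy sets.

    Planted sets are subsets of the shared hepatotoxic core (falling back to
    the union of signature genes when the core is small), one per phenotype
    group, so injury-call tests have a known ground truth; decoys are uniform
    draws from the universe tagged ``group=pathway``.
    """
    universe = list(universe)
    uset = set(universe)
    all_sig = set().union(*(sig.signature_genes(c) for c in sig.effect_direction)) if sig.effect_direction else set()
    if not all_sig <= uset:
        raise ValueError("universe must cover all signature genes")
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set size exceeds universe")
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    pool = sorted(sig.shared_core) if sig.shared_core else sorted(all_sig)
    if pool:
        for i, group in enumerate(phenotype_groups):
            size = min(planted_size, len(pool))
            members = sorted(rng.choice(pool, size=size, replace=False))
            sets.append(
                GeneSet(
                    set_id=f"planted_{group}",
                    description=f"group={group}",
                    genes=tuple(members),
                    category="injury_module",
                    phenotype_group=group,
                )
            )
    for i in range(n_decoy_sets):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(universe, size=size, replace=False))
        sets.append(
            GeneSet(
                set_id=f"decoy_{i:03d}",
                description="group=pathway",
                genes=tuple(members),
                category="pathway",
                phenotype_group="none",
            )
        )
    return sets
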