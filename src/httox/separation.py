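"""The toxic/non-toxic separation study on synthetic data.

One simulated study = several hepatotoxic chemicals with planted Hill
signatures (a strong 50-gene shared core plus heterogeneous private
responders) and null chemicals with no signature, run through the full
pipeline: normalization, per-dose differential expression, highest-dose
common-gene consensus, condition correlation, AAFC injury-module scoring and
activation calls.  The summary rates quantify how reliably the pipeline
separates the two classes:

* monotone (non-decreasing) significant-gene counts over the top half of the
  dose range for hepatotoxic chemicals;
* recovery of the planted shared core by the cross-chemical consensus, and
  the off-core fraction among consensus genes;
* pairwise Pearson correlation of top-dose fold-change profiles over the
  consensus genes;
* consistent activation of planted injury modules for hepatotoxic chemicals,
  and the absence of consistent activation for null chemicals.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synth
from .cluster_corr import common_genes
from .differential import deg_counts, differential_expression, fold_change_matrix
from .geneset_scoring import score_all
from .injury_calls import call_all
from .qc_normalize import collapse_probes, normalize, unattenuate

__all__ = ["SeparationConditions", "simulate_study", "run_separation_sim", "separation_summary"]


@dataclass(frozen=True)
class SeparationConditions:
    """Study conditions for the separation benchmark.

    2,000 genes with a 300-gene hepatotoxic signature (15 % of the
    transcriptome perturbed at top dose, the scale seen for strongly
    perturbing hepatotoxicants) including a 50-gene shared core at the full
    2-log2-unit saturation effect; 8 dose levels + vehicle control with 4
    replicates; negative-binomial counts at dispersion 0.1.
    """

    n_hepatotoxic: int = 4
    n_null: int = 2
    n_dose_levels: int = 8
    n_replicates: int = 4
    n_genes: int = 2000
    n_signature: int = 300
    core_size: int = 50
    max_effect: float = 2.0
    module_size: int = 30
    n_perm: int = 1000
    q_deg: float = 0.1
    q_consensus: float = 0.1


def _make_design(cond: SeparationConditions) -> synth.StudyDesign:
    chems = [f"HEP{i}" for i in range(cond.n_hepatotoxic)] + [
        f"NULL{i}" for i in range(cond.n_null)
    ]
    doses = {c: [float(2**i) for i in range(cond.n_dose_levels)] for c in chems}
    tox = {c: ("hepatotoxic" if c.startswith("HEP") else "non_toxic") for c in chems}
    return synth.StudyDesign(
        chemicals=chems,
        dose_values=doses,
        toxicity_class=tox,
        vehicle={c: "corn_oil" for c in chems},
        n_replicates=cond.n_replicates,
    )


def simulate_study(seed: int, cond: SeparationConditions = SeparationConditions()):
    """One synthetic study: (design, signatures, counts, sheet, gene sets)."""
    design = _make_design(cond)
    genes = [f"g{i:05d}" for i in range(cond.n_genes)]
    ss = np.random.SeedSequence([int(seed), 0])
    s_sig, s_counts, s_sets = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    sig = synth.make_signatures(
        design, genes, n_signature=cond.n_signature, core_size=cond.core_size,
        max_effect=cond.max_effect, seed=s_sig,
    )
    counts, sheet = synth.generate_counts(design, sig, genes=genes, seed=s_counts)
    sets = synth.generate_genesets(
        sig, genes, n_decoy_sets=0, planted_size=cond.module_size, seed=s_sets
    )
    return design, sig, counts, sheet, sets


def run_separation_sim(seed: int, cond: SeparationConditions = SeparationConditions()) -> dict:
    """Run one simulated study through the pipeline and collect the per-series
    outcomes (booleans/fractions, one entry per chemical or module series)."""
    design, sig, counts, sheet, sets = simulate_study(seed, cond)
    hep = [c for c in design.chemicals if design.toxicity_class[c] == "hepatotoxic"]
    nulls = [c for c in design.chemicals if design.toxicity_class[c] != "hepatotoxic"]

    gene_norm = collapse_probes(normalize(unattenuate(counts)), counts.manifest)
    profiles = differential_expression(gene_norm.values, sheet, scope="per_dose")
    profiles_joint = differential_expression(gene_norm.values, sheet, scope="across_doses")

    # (a) monotone DEG counts over the top half of dose ranks
    degs = deg_counts(profiles, q_threshold=cond.q_deg)
    half = cond.n_dose_levels // 2
    monotone = []
    for chem in hep:
        n = degs[degs["chemical"] == chem].sort_values("dose_level")["n_deg"].to_list()
        top = n[half:]
        monotone.append(all(top[i] <= top[i + 1] for i in range(len(top) - 1)))

    # (b) shared-core recovery by the highest-dose consensus (joint dose-response
    # ANOVA per chemical supplies the per-gene significance)
    consensus = common_genes(profiles_joint, hep, q_threshold=cond.q_consensus)
    members = set(consensus.members)
    core = sig.shared_core
    recovery = len(members & core) / len(core)
    off_core_frac = len(members - core) / max(len(members), 1)

    # (c) top-dose inter-chemical Pearson r over the consensus genes
    fcmat = fold_change_matrix(profiles)
    tops = fcmat[[(c, cond.n_dose_levels) for c in hep]]
    idx = np.triu_indices(len(hep), 1)
    r_all_genes = tops.corr().to_numpy()[idx]
    cg = sorted(members & set(tops.index))
    r_common = tops.loc[cg].corr().to_numpy()[idx] if len(cg) > 3 else np.array([np.nan])

    # (d/e) injury-module activation calls (AAFC, per-dose profiles)
    scores = score_all(profiles, sets, method="aafc", n_perm=cond.n_perm, seed=seed)
    calls = call_all(scores)
    activated = [
        c.status == "activated_consistent" for c in calls if c.chemical in hep
    ]
    null_clean = [
        c.status != "activated_consistent" for c in calls if c.chemical in nulls
    ]
    return {
        "monotone": monotone,
        "recovery": recovery,
        "off_core_frac": off_core_frac,
        "r_common": [float(v) for v in r_common],
        "r_all_genes": [float(v) for v in r_all_genes],
        "activated": activated,
        "null_clean": null_clean,
    }


def separation_summary(n_sims: int, seed: int,
                       cond: SeparationConditions = SeparationConditions()) -> dict:
    """Aggregate separation rates over ``n_sims`` independent studies.

    Rates are per series: each hepatotoxic chemical contributes one monotone
    series and one value per planted module to the activation rate; each null
    chemical contributes one series per module to the clean-null rate.
    """
    ss = np.random.SeedSequence(int(seed))
    sims = [run_separation_sim(int(c.generate_state(1)[0] % (2**31)), cond)
            for c in ss.spawn(n_sims)]
    cat = lambda key: [v for s in sims for v in np.atleast_1d(s[key])]
    return {
        "n_sims": n_sims,
        "monotone_deg_fraction": float(np.mean(cat("monotone"))),
        "core_recovery_mean": float(np.mean([s["recovery"] for s in sims])),
        "core_recovery_min": float(np.min([s["recovery"] for s in sims])),
        "off_core_fraction_max": float(np.max([s["off_core_frac"] for s in sims])),
        "r_common_gt_0.6_fraction": float(np.mean(np.array(cat("r_common")) > 0.6)),
        "r_common_median": float(np.nanmedian(cat("r_common"))),
        "r_all_genes_median": float(np.nanmedian(cat("r_all_genes"))),
        "activation_fraction": float(np.mean(cat("activated"))),
        "null_clean_fraction": float(np.mean(cat("null_clean"))),
    }
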