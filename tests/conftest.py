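import numpy as np
import pandas as pd
import pytest

from httox import synth
from httox.qc_normalize import ProbeCounts


@pytest.fixture(scope="session")
def small_design() -> synth.StudyDesign:
    """Two hepatotoxic + one null chemical, 8 dose levels, 4 replicates."""
    chems = ["HEPA", "HEPB", "NULLA"]
    return synth.StudyDesign(
        chemicals=chems,
        dose_values={c: [float(2**i) for i in range(8)] for c in chems},
        toxicity_class={"HEPA": "hepatotoxic", "HEPB": "hepatotoxic", "NULLA": "non_toxic"},
        vehicle={c: "corn_oil" for c in chems},
    )


@pytest.fixture(scope="session")
def genes() -> list[str]:
    return [f"g{i:05d}" for i in range(600)]


@pytest.fixture(scope="session")
def small_signatures(small_design, genes) -> synth.SignatureSpec:
    return synth.make_signatures(small_design, genes, n_signature=80, core_size=40, seed=7)


@pytest.fixture(scope="session")
def small_study(small_design, small_signatures, genes):
    """Counts + sheet for the small design (no seeded QC failures)."""
    counts, sheet = synth.generate_counts(
        small_design, small_signatures, genes=genes, seed=7
    )
    return counts, sheet


def make_probe_counts(values: np.ndarray, factors=None, samples=None,
                      unattenuated: bool = False) -> ProbeCounts:
    """Hand-built ProbeCounts with one probe per gene."""
    n_probes, n_samples = values.shape
    probes = [f"p{i:03d}" for i in range(n_probes)]
    manifest = pd.DataFrame(
        {
            "gene_id": [f"g{i:03d}" for i in range(n_probes)],
            "attenuation_factor": np.ones(n_probes) if factors is None else np.asarray(factors, dtype=float),
        },
        index=pd.Index(probes, name="probe_id"),
    )
    counts = pd.DataFrame(
        values,
        index=manifest.index,
        columns=[f"s{j}" for j in range(n_samples)] if samples is None else samples,
    )
    return ProbeCounts(counts=counts, manifest=manifest, unattenuated=unattenuated)


def make_sheet(samples, chemical="CHEM", dose_levels=None, total_reads=2_000_000,
               aligned_reads=1_500_000, total_rate=80.0, unique_rate=60.0):
    n = len(samples)
    dose_levels = [0] * n if dose_levels is None else dose_levels
    return pd.DataFrame(
        {
            "sample_id": samples,
            "chemical": chemical,
            "dose_level": dose_levels,
            "dose_value": [float(d) for d in dose_levels],
            "vehicle": "corn_oil",
            "replicate": list(range(1, n + 1)),
            "total_reads": total_reads,
            "aligned_reads": aligned_reads,
            "total_alignment_rate": total_rate,
            "unique_alignment_rate": unique_rate,
            "pct_probes_expressed": 100.0,
        }
    )
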