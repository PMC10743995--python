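"""Pipeline configuration: one YAML/JSON document drives every stage."""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Paths, thresholds, seeds and mode flags for a full pipeline run.

    ``counts``/``manifest``/``samples`` may be omitted when ``synthetic`` is
    true, in which case the study is simulated with ``seed``.
    """

    out_dir: str = "results/run"
    counts: str | None = None
    manifest: str | None = None
    samples: str | None = None
    gene_sets: str | None = None
    model: str | None = None  # trained extrapolation model (.npz); optional

    synthetic: bool = True
    synth_n_genes: int = 2000
    synth_n_chemicals: int = 6

    seed: int = 17
    n_perm: int = 10_000
    q_threshold: float = 0.1
    deg_q_threshold: float = 0.05
    z_min: float = 2.0
    p_max: float = 0.05
    k_consecutive: int = 2
    r_min: float = 0.8
    scope: str = "per_dose"
    collapse_policy: str = "mean"
    score_method: str = "aafc"
    keep_flagged: bool = False
    passthrough_sentinel: bool = True
    consensus_chemicals: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not (0 < self.q_threshold <= 1 and 0 < self.deg_q_threshold <= 1):
            raise ValueError("q thresholds must be in (0, 1]")
        if not (0 < self.p_max <= 1):
            raise ValueError("p_max must be in (0, 1]")
        if self.n_perm < 1 or self.k_consecutive < 1:
            raise ValueError("n_perm and k_consecutive must be >= 1")
        if self.scope not in {"per_dose", "across_doses"}:
            raise ValueError(f"unknown scope: {self.scope}")
        if self.score_method not in {"afc", "aafc"}:
            raise ValueError(f"unknown score method: {self.score_method}")
        if self.seed is None:
            raise ValueError("a seed is mandatory (stochastic stages)")
        if not self.synthetic:
            for name in ("counts", "manifest", "samples", "gene_sets"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"{name} path required when synthetic=false")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")
        elif self.gene_sets is not None and not Path(self.gene_sets).exists():
            raise FileNotFoundError(f"gene_sets file not found: {self.gene_sets}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        data = asdict(self)
        text = (json.dumps(data, indent=2) if str(path).endswith(".json")
                else yaml.safe_dump(data, sort_keys=False))
        Path(path).write_text(text)
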