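"""Run configuration: one YAML/JSON document drives a full pipeline run."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import ConfigError, SimulationConfig

__all__ = ["RunConfig", "ConfigError"]


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs.

    ``query_from`` selects the drug-query genes: 'planted' (the simulated
    target genes), 'finemap' (candidate genes recovered by the fine-mapping
    stage) or 'file' (one gene ID per line at ``query_genes_path``).
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    window_r2: float = 0.6
    eqtl_r2: float = 0.8
    fdr: float = 0.01
    pseudocount: float = 1.0
    n_permutations: int = 2000
    weighted_es: bool = False
    query_from: str = "planted"
    query_genes_path: str | None = None
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        for name, v in (("window_r2", self.window_r2), ("eqtl_r2", self.eqtl_r2)):
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if not 0 < self.fdr <= 1:
            raise ConfigError(f"fdr must lie in (0, 1], got {self.fdr}")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.query_from not in {"planted", "finemap", "file"}:
            raise ConfigError(f"unknown query_from {self.query_from!r}")
        if self.query_from == "file" and not self.query_genes_path:
            raise ConfigError("query_from='file' requires query_genes_path")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        cfg = cls(simulation=SimulationConfig.from_dict(sim), **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
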