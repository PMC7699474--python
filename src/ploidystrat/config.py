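"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ValidationError
from .synthetic import SimulationParams


@dataclass
class InputPaths:
    """File inputs for a run on real (non-simulated) data."""

    expression_a: Path
    meta_a: Path
    expression_b: Path
    meta_b: Path
    orthology: Path
    annotation: Path
    ontology_edges: Path | None = None
    gene2term: Path | None = None
    term_labels: Path | None = None
    network: Path | None = None

    def __post_init__(self):
        for f in fields(self):
            value = getattr(self, f.name)
            if value is None:
                continue
            path = Path(value)
            setattr(self, f.name, path)
            if not path.exists():
                raise ValidationError(f"input path for {f.name} does not exist: {path}")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: Path = Path("results")
    fold_thresholds: list = field(default_factory=lambda: [2.0, 1.3])
    pca_sd: float = 2.0
    hub_degree: int = 10
    log2_pseudocount: float = 1.0
    simulate: SimulationParams | None = None
    inputs: InputPaths | None = None

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if not self.fold_thresholds:
            raise ValidationError("fold_thresholds must not be empty")
        for fold in self.fold_thresholds:
            if fold <= 1:
                raise ValidationError(f"fold thresholds must be > 1, got {fold}")
        if self.pca_sd <= 0:
            raise ValidationError(f"pca_sd must be > 0, got {self.pca_sd}")
        if (self.simulate is None) == (self.inputs is None):
            raise ValidationError("exactly one of 'simulate' or 'inputs' must be configured")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if kwargs.get("simulate") is not None:
            sim = kwargs["simulate"]
            if isinstance(sim, dict):
                sim_known = {f.name for f in fields(SimulationParams)}
                sim_unknown = set(sim) - sim_known
                if sim_unknown:
                    raise ValidationError(f"unknown simulate keys: {sorted(sim_unknown)}")
                kwargs["simulate"] = SimulationParams(**sim)
        if kwargs.get("inputs") is not None and isinstance(kwargs["inputs"], dict):
            kwargs["inputs"] = InputPaths(**kwargs["inputs"])
        return cls(**kwargs)
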