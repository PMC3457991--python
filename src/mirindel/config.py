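"""Run configuration: one YAML file drives every pipeline command.

All analysis thresholds live here with their defaults: seed-scan window
half-width 50 nt (a ~100 bp window around each variant), seed span 2-8,
LD confidence bounds (strong LD: cl >= 0.7 and cu >= 0.98; strong
recombination: cu < 0.9), MAF floor 0.05, 95% informative-pair fraction,
100 kb GWAS linking window, and the >=10-gene pathway reporting floor.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

from .ld import GabrielParams


@dataclass
class RunConfig:
    inputs: Dict[str, str] = field(default_factory=dict)
    half_width: int = 50
    seed_span: Tuple[int, int] = (2, 8)
    variant_subset: str = "both"        # all | indels_only | both
    ld: GabrielParams = field(default_factory=GabrielParams)
    ld_window: int = 100_000
    min_genes: int = 10
    output_dir: str = "out"
    simulate: Dict = field(default_factory=dict)   # GeneratorConfig overrides

    def __post_init__(self) -> None:
        for name in ("ci_lower", "ci_upper", "recomb_upper", "maf_min",
                     "strong_fraction"):
            v = getattr(self.ld, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"ld.{name}={v} outside [0, 1]")
        if self.ld_window <= 0:
            raise ValueError("ld_window must be positive")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.variant_subset not in ("all", "indels_only", "both"):
            raise ValueError(f"bad variant_subset {self.variant_subset!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        ld = d.pop("ld", {})
        window = ld.pop("window", d.pop("ld_window", 100_000)) if isinstance(ld, dict) else 100_000
        seed_span = tuple(d.pop("seed_span", (2, 8)))
        known = {"inputs", "half_width", "variant_subset", "min_genes",
                 "output_dir", "simulate"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(ld=GabrielParams(**ld), ld_window=int(window),
                   seed_span=seed_span, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seed_span"] = list(self.seed_span)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output location
        does not influence results and is excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def input_path(self, key: str) -> Path:
        if key not in self.inputs:
            raise KeyError(f"config is missing required input {key!r}")
        return Path(self.inputs[key])
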