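"""Run configuration: YAML round-trip of all rule/spec objects and the
reproducibility manifest written by every CLI run."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import BinSpec, ErrorModel, LibrarySpec
from .targets import DesignRules


@dataclass
class RunConfig:
    """Everything a pipeline stage needs, serializable losslessly to YAML."""

    seed: int = 0
    design_rules: DesignRules = field(default_factory=DesignRules)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    library_spec: LibrarySpec = field(default_factory=LibrarySpec)
    bin_spec: BinSpec = field(default_factory=BinSpec)
    cassette_seed: int = 7
    n_molecules: int = 10_000
    n_clones: int = 1_000
    read_len: int = 150
    umi_len: int = 8
    barcodes: dict = field(default_factory=lambda: {"s1": "ACGTAC"})
    seq_error_rate: float = 0.0
    pcr_duplication: int = 5
    matcher_max_mismatches: int = 4

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("design_rules", "error_model", "library_spec", "bin_spec"):
            d[key] = dataclasses.asdict(getattr(self, key))
        d["design_rules"]["pam_patterns"] = list(self.design_rules.pam_patterns)
        d["design_rules"]["favorable_dinucs"] = list(self.design_rules.favorable_dinucs)
        d["bin_spec"]["fractions"] = list(self.bin_spec.fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design_rules" in d:
            dr = dict(d["design_rules"])
            for k in ("pam_patterns", "favorable_dinucs"):
                if k in dr:
                    dr[k] = tuple(dr[k])
            d["design_rules"] = DesignRules(**dr)
        if "error_model" in d:
            d["error_model"] = ErrorModel(**d["error_model"])
        if "library_spec" in d:
            d["library_spec"] = LibrarySpec(**d["library_spec"])
        if "bin_spec" in d:
            bs = dict(d["bin_spec"])
            if "fractions" in bs:
                bs["fractions"] = tuple(bs["fractions"])
            d["bin_spec"] = BinSpec(**bs)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_manifest(path: str | Path, stage: str, config: RunConfig, extra: dict | None = None):
    """Machine-readable record sufficient to reproduce a CLI run."""
    from . import __version__

    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
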