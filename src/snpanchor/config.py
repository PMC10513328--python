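"""Pipeline configuration: defaults in code, YAML file, CLI flag overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .ibs_qc import QCConfig


@dataclass
class PipelineConfig:
    """Every stage parameter with its default.

    Precedence: command-line flags > configuration file > these defaults.
    The effective configuration is echoed to the log and written beside the
    outputs of every run.
    """

    k: int = 21
    min_identity: float = 0.95
    max_gap: int = 10_000_000
    keep_mismatch: bool = False
    min_sites: int = 50
    replicates: int = 1000
    seed: int = 0
    allele_aware: bool = False
    pca_scale: bool = True
    qc: QCConfig = field(default_factory=QCConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        qc_raw = raw.pop("qc", {})
        known = {f.name for f in fields(cls)} - {"qc"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw, qc=QCConfig(**qc_raw))

    def override(self, **kwargs) -> "PipelineConfig":
        """New config with non-None kwargs applied (flags beat file values)."""
        d = asdict(self)
        qc = d.pop("qc")
        for key, value in kwargs.items():
            if value is None:
                continue
            if key in qc:
                qc[key] = value
            elif key in d:
                d[key] = value
            else:
                raise KeyError(key)
        return PipelineConfig(**d, qc=QCConfig(**qc))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
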