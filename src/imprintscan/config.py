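"""Pipeline-wide configuration: scan thresholds, PofO rule, QC thresholds.

A flat key=value mapping (YAML) whose keys are exactly the
:class:`~imprintscan.classify.ScanParameters` field names, plus
``pofo_min_obs`` / ``pofo_high_meth`` / ``pofo_low_meth``,
``qc_depth_thresholds`` and ``seed``.  Unknown keys are rejected so typos
never silently fall back to defaults.  Precedence: command-line flags over
config file over defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import yaml

from .classify import ScanParameters
from .errors import ConfigError
from .phasing import PofOThresholds
from .qc import DEFAULT_DEPTH_THRESHOLDS

__all__ = ["PipelineConfig"]

_SCAN_KEYS = set(ScanParameters.__dataclass_fields__)
_POFO_KEYS = {"pofo_min_obs", "pofo_high_meth", "pofo_low_meth"}
_OTHER_KEYS = {"qc_depth_thresholds", "seed"}


@dataclass(frozen=True)
class PipelineConfig:
    scan: ScanParameters = field(default_factory=ScanParameters)
    pofo: PofOThresholds = field(default_factory=PofOThresholds)
    qc_depth_thresholds: tuple[int, ...] = DEFAULT_DEPTH_THRESHOLDS
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "PipelineConfig":
        unknown = set(mapping) - _SCAN_KEYS - _POFO_KEYS - _OTHER_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        scan = ScanParameters.from_mapping({k: v for k, v in mapping.items() if k in _SCAN_KEYS})
        pofo = PofOThresholds(
            min_obs=int(mapping.get("pofo_min_obs", 10)),
            high_meth=float(mapping.get("pofo_high_meth", 0.7)),
            low_meth=float(mapping.get("pofo_low_meth", 0.3)),
        )
        return cls(
            scan=scan,
            pofo=pofo,
            qc_depth_thresholds=tuple(mapping.get("qc_depth_thresholds", DEFAULT_DEPTH_THRESHOLDS)),
            seed=int(mapping.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_mapping(data)

    def to_flat_dict(self) -> dict[str, object]:
        out: dict[str, object] = {f.name: getattr(self.scan, f.name) for f in fields(self.scan)}
        out["pofo_min_obs"] = self.pofo.min_obs
        out["pofo_high_meth"] = self.pofo.high_meth
        out["pofo_low_meth"] = self.pofo.low_meth
        out["qc_depth_thresholds"] = list(self.qc_depth_thresholds)
        out["seed"] = self.seed
        return out

    def write_template(self, path: str | Path) -> None:
        """Write a config template with every default explicit."""
        with open(path, "wt") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)
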