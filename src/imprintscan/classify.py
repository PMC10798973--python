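"""Per-CpG depth filtering and methylation-level classification.

Aggregate methylation near 50% at a CpG is the expected signature of a
parental DMR: one allele methylated, the other not.  Each depth-passing CpG
is placed in exactly one class by its methylation level:

* ``HYPO``          level < 0.3 (strict)
* ``HYPER``         level > 0.7 (strict)
* ``HEMI``          0.4 <= level <= 0.6 (inclusive)
* ``INTERMEDIATE``  the residue (0.3, 0.4) and (0.6, 0.7)
* ``LOW_DEPTH``     fewer than 20 reads, before any level comparison

The three published ranges do not tile [0, 1]; the residue is kept as an
explicit class so the partition is testable.  All threshold comparisons live
in :func:`classify_cpg` so a different inclusivity convention is a one-line
change.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigError, ValidationError
from .io import CpGCall

__all__ = [
    "MethylationClass",
    "ScanParameters",
    "ClassifiedCpG",
    "classify_cpg",
    "classify_all",
    "write_class_summary",
]


class MethylationClass(str, Enum):
    HYPO = "HYPO"
    HYPER = "HYPER"
    HEMI = "HEMI"
    INTERMEDIATE = "INTERMEDIATE"
    LOW_DEPTH = "LOW_DEPTH"


@dataclass(frozen=True)
class ScanParameters:
    """All thresholds and window sizes of the region-calling procedure.

    Defaults are the published stringent criteria: depth >= 20X; hypo/hyper
    at <0.3/>0.7; hemi at [0.4, 0.6]; >=5 hemi CpGs within a 100-bp window
    (hemiR100) or 5 consecutive hemi CpGs (hemiR5); neighbouring regions
    closer than the defining criterion (100 bp resp. 5 bp) are merged.
    """

    min_depth: int = 20
    hypo_max: float = 0.3
    hyper_min: float = 0.7
    hemi_low: float = 0.4
    hemi_high: float = 0.6
    min_cpgs: int = 5
    window_bp: int = 100
    merge_gap_r100: int = 100
    merge_gap_r5: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.hypo_max < self.hemi_low < self.hemi_high < self.hyper_min <= 1):
            raise ConfigError(
                "require 0 <= hypo_max < hemi_low < hemi_high < hyper_min <= 1, got "
                f"{self.hypo_max}, {self.hemi_low}, {self.hemi_high}, {self.hyper_min}"
            )
        if self.min_depth < 1:
            raise ConfigError(f"min_depth must be >= 1, got {self.min_depth}")
        if self.min_cpgs < 2:
            raise ConfigError(f"min_cpgs must be >= 2, got {self.min_cpgs}")
        if self.window_bp < 1:
            raise ConfigError(f"window_bp must be >= 1, got {self.window_bp}")
        if self.merge_gap_r100 < 0 or self.merge_gap_r5 < 0:
            raise ConfigError("merge gaps must be non-negative")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "ScanParameters":
        """Build from a config mapping, rejecting unknown keys."""
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown scan parameter(s): {sorted(unknown)}")
        return cls(**{k: v for k, v in mapping.items()})  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScanParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"scan-parameter file {path} must hold a mapping")
        return cls.from_mapping(data)

    def replace(self, **kw) -> "ScanParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class ClassifiedCpG:
    call: CpGCall
    klass: MethylationClass


def _effective_level(call: CpGCall) -> float:
    # counts are authoritative over the file's printed fraction
    return call.n_meth / call.n_total if call.n_total > 0 else call.meth_level


def classify_cpg(call: CpGCall, params: ScanParameters) -> MethylationClass:
    """Classify one CpG call; order of checks is fixed (depth first)."""
    if call.context != "CpG":
        raise ValidationError(
            f"classify_cpg requires CpG context, got {call.context} at {call.chrom}:{call.pos}"
        )
    if call.n_total < params.min_depth:
        return MethylationClass.LOW_DEPTH
    meth = _effective_level(call)
    if meth < params.hypo_max:
        return MethylationClass.HYPO
    if meth > params.hyper_min:
        return MethylationClass.HYPER
    if params.hemi_low <= meth <= params.hemi_high:
        return MethylationClass.HEMI
    return MethylationClass.INTERMEDIATE


def classify_all(
    calls: Sequence[CpGCall], params: ScanParameters
) -> tuple[list[ClassifiedCpG], dict[MethylationClass, int]]:
    """Classify every CpG-context call; non-CpG contexts are passed over.

    Returns the classified calls in input order and a summary mapping every
    class to its count (classes with zero occurrences included); the counts
    sum to the number of CpG-context calls.  Input must be sorted by
    (chrom, pos).
    """
    _check_sorted(calls)
    classified: list[ClassifiedCpG] = []
    summary: dict[MethylationClass, int] = {k: 0 for k in MethylationClass}
    for call in calls:
        if call.context != "CpG":
            continue
        klass = classify_cpg(call, params)
        classified.append(ClassifiedCpG(call, klass))
        summary[klass] += 1
    return classified, summary


def _check_sorted(calls: Sequence[CpGCall]) -> None:
    for a, b in zip(calls, calls[1:]):
        if a.chrom == b.chrom and b.pos < a.pos:
            raise ValidationError(
                f"calls not sorted by (chrom, pos): {a.chrom}:{a.pos} precedes {b.chrom}:{b.pos}"
            )


def write_classified(classified: Iterable[ClassifiedCpG], path: str | Path) -> None:
    """TSV of per-CpG calls with their class (pipeline intermediate)."""
    with open(path, "wt") as fh:
        fh.write("chrom\tpos\tstrand\tcontext\tmeth_level\tn_meth\tn_total\tclass\n")
        for c in classified:
            call = c.call
            fh.write(
                f"{call.chrom}\t{call.pos}\t{call.strand}\t{call.context}\t"
                f"{call.meth_level:.6f}\t{call.n_meth}\t{call.n_total}\t{c.klass.value}\n"
            )


def read_classified(path: str | Path) -> list[ClassifiedCpG]:
    """Inverse of :func:`write_classified`."""
    from .io import _open_text

    out: list[ClassifiedCpG] = []
    with _open_text(path) as fh:
        header = fh.readline()
        for line in fh:
            chrom, pos, strand, context, meth, n_meth, n_total, klass = line.rstrip("\n").split("\t")
            nm, nt = int(n_meth), int(n_total)
            out.append(
                ClassifiedCpG(
                    CpGCall(
                        chrom=chrom,
                        pos=int(pos),
                        strand=strand,
                        context=context,
                        meth_level=nm / nt if nt else float(meth),
                        n_meth=nm,
                        n_total=nt,
                    ),
                    MethylationClass(klass),
                )
            )
    return out


def write_class_summary(summary: Mapping[MethylationClass, int], path: str | Path) -> None:
    """TSV with one row per class: class, count, fraction of all CpGs."""
    total = sum(summary.values())
    with open(path, "wt") as fh:
        fh.write("class\tcount\tfraction\n")
        for klass in MethylationClass:
            n = summary.get(klass, 0)
            frac = n / total if total else 0.0
            fh.write(f"{klass.value}\t{n}\t{frac:.6f}\n")
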