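"""Hemi-methylated region calling.

Two region definitions are implemented over the set of hemi-methylated CpGs
of one sample:

* **hemiR100** — density criterion: at least ``min_cpgs`` hemi CpGs fitting
  inside a window of ``window_bp`` bases (span between first and last CpG of
  the qualifying subset <= window_bp - 1).
* **hemiR5** — consecutiveness criterion: at least ``min_cpgs`` hemi CpGs
  that are consecutive among the assayed, depth-passing CpGs of the
  chromosome, additionally required to fall inside a hemiR100 region so the
  subset relation between the two definitions holds by construction.

Neighbouring regions of one kind closer than the defining distance (100 bp
for hemiR100, 5 bp for hemiR5; strict inequality) are merged transitively.
Region boundaries are reported as the tight span of the supporting CpGs
(0-based half-open: ``min_pos - 1`` to ``max_pos``).

``brute_force_hemi_regions`` re-derives hemiR100 calls by exhaustive window
enumeration and serves as the reference the fast scanner is tested against.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .classify import ClassifiedCpG, MethylationClass, ScanParameters
from .errors import ValidationError

__all__ = [
    "HemiRegion",
    "scan_hemi_r100",
    "scan_hemi_r5",
    "merge_regions",
    "brute_force_hemi_regions",
    "call_hemi_regions",
    "write_region_table",
]

KINDS = ("hemiR100", "hemiR5")


@dataclass(frozen=True)
class HemiRegion:
    """A called hemi-methylated interval with its supporting CpGs."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    kind: str
    n_hemi: int
    cpg_positions: tuple[int, ...]  # 1-based, strictly increasing
    mean_meth: float

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown region kind {self.kind!r}")
        if self.n_hemi != len(self.cpg_positions):
            raise ValidationError("n_hemi must equal the number of supporting CpGs")
        if any(b <= a for a, b in zip(self.cpg_positions, self.cpg_positions[1:])):
            raise ValidationError("cpg_positions must be strictly increasing")
        if self.start != self.cpg_positions[0] - 1 or self.end != self.cpg_positions[-1]:
            raise ValidationError("region bounds must tightly span the supporting CpGs")

    @property
    def midpoint(self) -> int:
        """0-based midpoint, used for candidate assignment."""
        return (self.start + self.end) // 2

    @classmethod
    def from_positions(
        cls,
        chrom: str,
        positions: Sequence[int],
        kind: str,
        meth_by_pos: Mapping[int, float] | None = None,
    ) -> "HemiRegion":
        positions = tuple(sorted(positions))
        if meth_by_pos is not None and all(p in meth_by_pos for p in positions):
            mean_meth = sum(meth_by_pos[p] for p in positions) / len(positions)
        else:
            mean_meth = math.nan
        return cls(
            chrom=chrom,
            start=positions[0] - 1,
            end=positions[-1],
            kind=kind,
            n_hemi=len(positions),
            cpg_positions=positions,
            mean_meth=mean_meth,
        )


def _check_positions(positions: Sequence[int]) -> None:
    for a, b in zip(positions, positions[1:]):
        if b <= a:
            raise ValidationError(
                f"positions must be sorted and unique, found {a} before {b}"
            )


def scan_hemi_r100(
    chrom: str,
    hemi_positions: Sequence[int],
    params: ScanParameters,
    meth_by_pos: Mapping[int, float] | None = None,
) -> list[HemiRegion]:
    """Call hemiR100 regions on one chromosome's hemi-CpG positions.

    A window of ``window_bp`` bases is anchored at every hemi CpG; windows
    holding >= ``min_cpgs`` CpGs qualify, and CpG sets of overlapping
    qualifying windows are unioned into regions.  Output is unmerged (apply
    :func:`merge_regions`), sorted by start, non-overlapping.
    """
    _check_positions(hemi_positions)
    n = len(hemi_positions)
    qualifying: list[tuple[int, int]] = []  # inclusive index intervals
    for i in range(n):
        j = bisect_right(hemi_positions, hemi_positions[i] + params.window_bp - 1) - 1
        if j - i + 1 >= params.min_cpgs:
            qualifying.append((i, j))
    # union index intervals that share at least one CpG
    unioned: list[list[int]] = []
    for i, j in qualifying:
        if unioned and i <= unioned[-1][1]:
            unioned[-1][1] = max(unioned[-1][1], j)
        else:
            unioned.append([i, j])
    return [
        HemiRegion.from_positions(chrom, hemi_positions[i : j + 1], "hemiR100", meth_by_pos)
        for i, j in unioned
    ]


def merge_regions(regions: Sequence[HemiRegion], gap: int) -> list[HemiRegion]:
    """Merge same-kind regions closer than ``gap`` bp, transitively.

    Distance is ``next.start - prev.end``; merging is strict ("less than").
    The result is a fixed point: re-applying changes nothing, and all
    remaining inter-region distances are >= gap.
    """
    if not regions:
        return []
    kinds = {r.kind for r in regions}
    if len(kinds) > 1:
        raise ValidationError(f"merge_regions requires a single kind, got {sorted(kinds)}")
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    merged: list[HemiRegion] = []
    for r in regions:
        prev = merged[-1] if merged else None
        if prev is not None and r.chrom == prev.chrom and r.start - prev.end < gap:
            positions = sorted(set(prev.cpg_positions) | set(r.cpg_positions))
            if math.isnan(prev.mean_meth) or math.isnan(r.mean_meth):
                mean = math.nan
            else:
                tot = prev.n_hemi + r.n_hemi
                mean = (prev.mean_meth * prev.n_hemi + r.mean_meth * r.n_hemi) / tot
            merged[-1] = HemiRegion(
                chrom=prev.chrom,
                start=positions[0] - 1,
                end=positions[-1],
                kind=prev.kind,
                n_hemi=len(positions),
                cpg_positions=tuple(positions),
                mean_meth=mean,
            )
        else:
            merged.append(r)
    return merged


def brute_force_hemi_regions(
    hemi_positions: Sequence[int],
    params: ScanParameters,
    chrom: str = "chr",
) -> list[HemiRegion]:
    """Reference hemiR100 caller by exhaustive window enumeration.

    Enumerates the window anchored at every position, collects the CpG sets
    of qualifying windows, unions intersecting sets to a fixed point, builds
    regions and applies the merge rule.  Intended for small inputs
    (hundreds of positions); quadratic.
    """
    _check_positions(hemi_positions)
    sets: list[set[int]] = []
    for p in hemi_positions:
        window = {q for q in hemi_positions if p <= q <= p + params.window_bp - 1}
        if len(window) >= params.min_cpgs:
            sets.append(window)
    # union to fixed point
    changed = True
    while changed:
        changed = False
        out: list[set[int]] = []
        for s in sets:
            for t in out:
                if t & s:
                    t |= s
                    changed = True
                    break
            else:
                out.append(s)
        sets = out
    regions = [
        HemiRegion.from_positions(chrom, sorted(s), "hemiR100") for s in sets
    ]
    regions.sort(key=lambda r: r.start)
    return merge_regions(regions, params.merge_gap_r100)


def scan_hemi_r5(
    classified: Sequence[ClassifiedCpG],
    params: ScanParameters,
) -> list[HemiRegion]:
    """Call hemiR5 regions on one chromosome's classified CpGs.

    ``classified`` must be the positionally ordered depth-passing CpGs of a
    single chromosome (consecutiveness is judged over assayed CpGs, not
    genomic coordinates).  Maximal runs of HEMI CpGs are intersected with the
    merged hemiR100 regions of the same input; every sub-run of length
    >= ``min_cpgs`` is reported.  Output is unmerged.
    """
    if not classified:
        return []
    chroms = {c.call.chrom for c in classified}
    if len(chroms) > 1:
        raise ValidationError("scan_hemi_r5 operates on one chromosome at a time")
    chrom = chroms.pop()
    positions = [c.call.pos for c in classified]
    _check_positions(positions)
    if any(c.klass is MethylationClass.LOW_DEPTH for c in classified):
        raise ValidationError("scan_hemi_r5 input must exclude LOW_DEPTH CpGs")

    hemi_positions = [c.call.pos for c in classified if c.klass is MethylationClass.HEMI]
    meth_by_pos = {
        c.call.pos: (c.call.n_meth / c.call.n_total if c.call.n_total else c.call.meth_level)
        for c in classified
    }
    r100 = merge_regions(
        scan_hemi_r100(chrom, hemi_positions, params, meth_by_pos), params.merge_gap_r100
    )
    if not r100:
        return []

    # maximal runs of consecutive HEMI among assayed CpGs
    runs: list[list[int]] = []
    current: list[int] = []
    for c in classified:
        if c.klass is MethylationClass.HEMI:
            current.append(c.call.pos)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)

    out: list[HemiRegion] = []
    for run in runs:
        if len(run) < params.min_cpgs:
            continue
        for region in r100:
            inside = [p for p in run if region.start < p <= region.end]
            if len(inside) >= params.min_cpgs:
                out.append(HemiRegion.from_positions(chrom, inside, "hemiR5", meth_by_pos))
    out.sort(key=lambda r: r.start)
    return out


def call_hemi_regions(
    classified: Sequence[ClassifiedCpG],
    params: ScanParameters,
) -> dict[str, list[HemiRegion]]:
    """Run both scans plus merging over a multi-chromosome classified set.

    Returns ``{"hemiR100": [...], "hemiR5": [...]}`` sorted by
    (chrom, start).  LOW_DEPTH CpGs are removed here (they are not assayed
    for the purpose of either criterion).
    """
    by_chrom: dict[str, list[ClassifiedCpG]] = {}
    for c in classified:
        if c.klass is MethylationClass.LOW_DEPTH:
            continue
        by_chrom.setdefault(c.call.chrom, []).append(c)
    result: dict[str, list[HemiRegion]] = {"hemiR100": [], "hemiR5": []}
    for chrom in sorted(by_chrom):
        cs = by_chrom[chrom]
        hemi_positions = [c.call.pos for c in cs if c.klass is MethylationClass.HEMI]
        meth_by_pos = {
            c.call.pos: (
                c.call.n_meth / c.call.n_total if c.call.n_total else c.call.meth_level
            )
            for c in cs
        }
        r100 = merge_regions(
            scan_hemi_r100(chrom, hemi_positions, params, meth_by_pos),
            params.merge_gap_r100,
        )
        r5 = merge_regions(scan_hemi_r5(cs, params), params.merge_gap_r5)
        result["hemiR100"].extend(r100)
        result["hemiR5"].extend(r5)
    return result


def read_region_table(path: str | Path) -> list[HemiRegion]:
    """Inverse of :func:`write_region_table`."""
    out: list[HemiRegion] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            chrom, start, end, kind, n_hemi, mean_meth, positions = line.rstrip("\n").split("\t")
            out.append(
                HemiRegion(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    kind=kind,
                    n_hemi=int(n_hemi),
                    cpg_positions=tuple(int(p) for p in positions.split(",")),
                    mean_meth=math.nan if mean_meth == "NA" else float(mean_meth),
                )
            )
    return out


def write_region_table(regions: Iterable[HemiRegion], path: str | Path) -> None:
    """TSV region table: chrom, start, end, kind, n_hemi, mean_meth, positions."""
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.kind))
    with open(path, "wt") as fh:
        fh.write("chrom\tstart\tend\tkind\tn_hemi\tmean_meth\tcpg_positions\n")
        for r in regions:
            mean = "NA" if math.isnan(r.mean_meth) else f"{r.mean_meth:.6f}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.kind}\t{r.n_hemi}\t{mean}\t"
                + ",".join(map(str, r.cpg_positions))
                + "\n"
            )
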