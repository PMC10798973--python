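"""Capture-panel performance metrics.

Quantifies how well a targeted methyl-seq capture performed on its panel:

* **efficiency** — per-target fraction of bases covered at each depth
  threshold (default thresholds 1, 10, 20, 30, 50, 100);
* **homogeneity** — per-target mean and population SD of per-base depth;
* **specificity** — percentage of reads mapping outside every target
  (>= 1 bp overlap counts as on-target);
* **GC / size bias** — Pearson correlation of per-target mean coverage with
  GC fraction and with target size;
* **conversion QC** — residual methylation in non-CpG (CHH/CHG) contexts;
  mammalian non-CpG methylation is near zero, so the CHH rate estimates
  the cytosine-conversion failure rate and ``1 - rate_chh`` the conversion
  efficiency.

Depth is consumed as a run-length encoded track (bedGraph); all per-target
statistics are accumulated from integer base counts, so results are exact.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree
from scipy import stats

from .errors import InputError, ParseError, ValidationError
from .io import CpGCall, GenomicInterval, _open_text

__all__ = [
    "DepthTrack",
    "TargetQC",
    "NonCpGMethylation",
    "read_bedgraph",
    "target_efficiency",
    "coverage_homogeneity",
    "compute_target_qc",
    "off_target_fraction",
    "gc_coverage_correlation",
    "non_cpg_methylation_rate",
    "gc_fraction_from_fasta",
    "write_qc_table",
]

DEFAULT_DEPTH_THRESHOLDS = (1, 10, 20, 30, 50, 100)


class DepthTrack:
    """Per-base depth as sorted non-overlapping runs per chromosome.

    Bases not covered by any run have *unknown* depth (distinct from zero):
    per-target statistics are computed over covered bases only and flagged
    when a target is not fully covered.
    """

    def __init__(self, runs: Mapping[str, Sequence[tuple[int, int, int]]]):
        self._runs: dict[str, list[tuple[int, int, int]]] = {}
        self._starts: dict[str, list[int]] = {}
        for chrom, rs in runs.items():
            rs = sorted(rs)
            for (s, e, d) in rs:
                if not (0 <= s < e) or d < 0:
                    raise ValidationError(f"bad depth run {chrom}:{s}-{e} depth {d}")
            for (s1, e1, _), (s2, _, _) in zip(rs, rs[1:]):
                if s2 < e1:
                    raise ValidationError(f"overlapping depth runs on {chrom}")
            self._runs[chrom] = list(rs)
            self._starts[chrom] = [s for s, _, _ in rs]

    def runs_in(self, target: GenomicInterval):
        """Yield (n_bases, depth) for track runs clipped to the target."""
        rs = self._runs.get(target.chrom, [])
        starts = self._starts.get(target.chrom, [])
        i = max(bisect_right(starts, target.start) - 1, 0)
        for s, e, d in rs[i:]:
            if s >= target.end:
                break
            lo, hi = max(s, target.start), min(e, target.end)
            if hi > lo:
                yield hi - lo, d

    def covered_bases(self, target: GenomicInterval) -> int:
        return sum(n for n, _ in self.runs_in(target))

    def total_depth_sum(self) -> int:
        return sum((e - s) * d for rs in self._runs.values() for s, e, d in rs)


def read_bedgraph(path: str | Path) -> DepthTrack:
    """Read a bedGraph depth track (chrom, start, end, depth; 0-based)."""
    runs: dict[str, list[tuple[int, int, int]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError("bedGraph line needs 4 columns", lineno)
            try:
                chrom, s, e, d = parts[0], int(parts[1]), int(parts[2]), int(float(parts[3]))
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
            runs.setdefault(chrom, []).append((s, e, d))
    return DepthTrack(runs)


@dataclass
class TargetQC:
    """Per-target capture metrics (one row of the QC report)."""

    target: GenomicInterval
    mean_depth: float
    sd_depth: float
    frac_at_depth: dict[int, float]
    gc_fraction: float | None = None
    fully_covered: bool = True


def target_efficiency(
    track: DepthTrack,
    targets: Sequence[GenomicInterval],
    depths: Sequence[int] = DEFAULT_DEPTH_THRESHOLDS,
) -> list[dict[int, float]]:
    """Per-target fraction of bases covered at each depth threshold.

    Fractions are computed over covered bases from integer counts, so they
    are non-increasing in the threshold by construction.
    """
    if any(d <= 0 for d in depths):
        raise ValidationError("depth thresholds must be positive")
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValidationError("depth thresholds must be strictly increasing")
    out = []
    for target in targets:
        total = 0
        at = {d: 0 for d in depths}
        for n, depth in track.runs_in(target):
            total += n
            for d in depths:
                if depth >= d:
                    at[d] += n
        out.append({d: (at[d] / total if total else 0.0) for d in depths})
    return out


def coverage_homogeneity(
    track: DepthTrack, targets: Sequence[GenomicInterval]
) -> list[tuple[float, float]]:
    """Per-target (mean, population SD) of per-base depth over covered bases."""
    out = []
    for target in targets:
        n = s1 = s2 = 0
        for w, d in track.runs_in(target):
            n += w
            s1 += w * d
            s2 += w * d * d
        if n == 0:
            raise ValidationError(f"target {target.label} has no covered bases")
        mean = s1 / n
        var = s2 / n - mean * mean
        out.append((mean, math.sqrt(max(var, 0.0))))
    return out


def compute_target_qc(
    track: DepthTrack,
    targets: Sequence[GenomicInterval],
    depths: Sequence[int] = DEFAULT_DEPTH_THRESHOLDS,
    gc_by_target: Mapping[str, float] | None = None,
) -> list[TargetQC]:
    """Assemble the full per-target QC record set."""
    eff = target_efficiency(track, targets, depths)
    homog = coverage_homogeneity(track, targets)
    out = []
    for target, fr, (mean, sd) in zip(targets, eff, homog):
        out.append(
            TargetQC(
                target=target,
                mean_depth=mean,
                sd_depth=sd,
                frac_at_depth=fr,
                gc_fraction=(gc_by_target or {}).get(target.label),
                fully_covered=track.covered_bases(target) == len(target),
            )
        )
    return out


def off_target_fraction(
    read_intervals: Sequence[GenomicInterval], targets: Sequence[GenomicInterval]
) -> float:
    """Percentage of reads mapping outside every target (>=1 bp overlap rule)."""
    if not read_intervals:
        raise ValidationError("off_target_fraction requires at least one read")
    trees: dict[str, IntervalTree] = {}
    for t in targets:
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end)
    off = 0
    for read in read_intervals:
        tree = trees.get(read.chrom)
        if tree is None or not tree.overlap(read.start, read.end):
            off += 1
    return 100.0 * off / len(read_intervals)


@dataclass(frozen=True)
class CorrelationResult:
    r_gc: float | None
    r_size: float | None
    n: int


def gc_coverage_correlation(targets_qc: Sequence[TargetQC]) -> CorrelationResult:
    """Pearson correlation of mean depth with GC fraction (and target size).

    Requires >= 3 targets with finite values; a zero-variance variable
    yields None for that coefficient.
    """
    with_gc = [t for t in targets_qc if t.gc_fraction is not None]
    if len(targets_qc) < 3:
        raise ValidationError("need at least 3 targets for a correlation")

    def _pearson(x, y):
        if len(x) < 3 or len(set(x)) == 1 or len(set(y)) == 1:
            return None
        return float(stats.pearsonr(x, y).statistic)

    r_gc = (
        _pearson([t.gc_fraction for t in with_gc], [t.mean_depth for t in with_gc])
        if len(with_gc) >= 3
        else None
    )
    r_size = _pearson([len(t.target) for t in targets_qc], [t.mean_depth for t in targets_qc])
    return CorrelationResult(r_gc=r_gc, r_size=r_size, n=len(targets_qc))


@dataclass(frozen=True)
class NonCpGMethylation:
    """Residual non-CpG methylation and the implied conversion efficiency."""

    rate_chh: float | None
    rate_chg: float | None
    conversion_estimate: float | None
    n_chh: int = 0
    n_chg: int = 0

    @property
    def no_data(self) -> bool:
        return self.rate_chh is None and self.rate_chg is None


def non_cpg_methylation_rate(calls: Iterable[CpGCall]) -> NonCpGMethylation:
    """Aggregate methylated/total read counts per non-CpG context."""
    sums = {"CHH": [0, 0], "CHG": [0, 0]}  # [methylated, total]
    for c in calls:
        if c.context in sums:
            sums[c.context][0] += c.n_meth
            sums[c.context][1] += c.n_total
    rate_chh = sums["CHH"][0] / sums["CHH"][1] if sums["CHH"][1] else None
    rate_chg = sums["CHG"][0] / sums["CHG"][1] if sums["CHG"][1] else None
    return NonCpGMethylation(
        rate_chh=rate_chh,
        rate_chg=rate_chg,
        conversion_estimate=1.0 - rate_chh if rate_chh is not None else None,
        n_chh=sums["CHH"][1],
        n_chg=sums["CHG"][1],
    )


def gc_fraction_from_fasta(path: str | Path) -> dict[str, float]:
    """GC fraction per FASTA record (record id -> fraction)."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA not found: {path}")
    out: dict[str, float] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            continue
        out[rec.id] = (seq.count("G") + seq.count("C")) / len(seq)
    return out


def write_qc_table(targets_qc: Sequence[TargetQC], path: str | Path) -> None:
    depths = sorted({d for t in targets_qc for d in t.frac_at_depth})
    with open(path, "wt") as fh:
        header = ["target", "chrom", "start", "end", "mean_depth", "sd_depth", "gc_fraction"]
        header += [f"frac_ge_{d}x" for d in depths]
        fh.write("\t".join(header) + "\n")
        for t in targets_qc:
            iv = t.target
            gc = "NA" if t.gc_fraction is None else f"{t.gc_fraction:.4f}"
            row = [
                iv.label, iv.chrom, str(iv.start), str(iv.end),
                f"{t.mean_depth:.4f}", f"{t.sd_depth:.4f}", gc,
            ]
            row += [f"{t.frac_at_depth.get(d, 0.0):.6f}" for d in depths]
            fh.write("\t".join(row) + "\n")
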