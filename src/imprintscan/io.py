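"""Readers and writers for the text formats the pipeline touches.

Coordinate conventions are converted at this boundary and nowhere else:
per-cytosine calls keep the 1-based positions of the CGmap dialect, while
genomic intervals use 0-based half-open BED coordinates.  All readers
transparently accept gzip-compressed input (detected by magic bytes, not
file extension).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from .errors import InputError, ParseError, ValidationError

__all__ = [
    "GenomicInterval",
    "CpGCall",
    "read_cgmap",
    "read_bismark_cov",
    "read_bed",
    "write_cgmap",
    "write_bed",
    "merge_symmetric_cpgs",
    "write_regions_bed",
]

#: CGmap context-class column values mapped onto the internal vocabulary.
_CGMAP_CONTEXTS = {"CG": "CpG", "CHG": "CHG", "CHH": "CHH"}
_CONTEXTS = frozenset(_CGMAP_CONTEXTS.values())


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, as in BED.

    ``start`` is inclusive, ``end`` exclusive; ``name`` is an optional label
    (e.g. a candidate-region identifier such as ``IGF2-H19``).
    """

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos_1based: int) -> bool:
        """Whether a 1-based point position falls inside the interval."""
        return self.start < pos_1based <= self.end

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def label(self) -> str:
        return self.name or f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class CpGCall:
    """One cytosine observation from a methylation caller.

    ``pos`` is the 1-based coordinate of the cytosine; ``meth_level`` is the
    fraction of methylated reads and must agree with ``n_meth / n_total``
    whenever reads were observed.  ``strand_known`` is False for dialects
    that do not record strand (Bismark coverage).
    """

    chrom: str
    pos: int
    strand: str
    context: str
    meth_level: float
    n_meth: int
    n_total: int
    strand_known: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if self.context not in _CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        if not (0 <= self.n_meth <= self.n_total):
            raise ValidationError(
                f"require 0 <= n_meth <= n_total, got {self.n_meth}/{self.n_total}"
            )
        if not (0.0 <= self.meth_level <= 1.0):
            raise ValidationError(f"meth_level outside [0,1]: {self.meth_level}")
        if self.n_total > 0 and abs(self.meth_level - self.n_meth / self.n_total) > 1e-6:
            raise ValidationError(
                f"meth_level {self.meth_level} inconsistent with counts "
                f"{self.n_meth}/{self.n_total}"
            )


def _open_text(path: str | Path) -> IO[str]:
    """Open plain or gzip text, sniffing the gzip magic bytes."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _fields(line: str, n_expected: int, lineno: int) -> list[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < n_expected:
        raise ParseError(
            f"expected at least {n_expected} tab-separated columns, got {len(parts)}",
            lineno,
        )
    return parts


def read_cgmap(path: str | Path) -> list[CpGCall]:
    """Read a CGmap file (8 columns, per-cytosine) into ``CpGCall`` records.

    Columns: chrom, nucleotide (C on +, G on -), 1-based position, context
    class (CG/CHG/CHH), dinucleotide context, methylation level, methylated
    count, total count.  The methylation level is recomputed from the counts
    when depth is non-zero, so rounding in the file never propagates.
    """
    calls: list[CpGCall] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 8:
                raise ParseError(f"CGmap line must have 8 columns, got {len(parts)}", lineno)
            chrom, nuc, pos_s, ctx, _dinuc, meth_s, nm_s, nt_s = parts
            if nuc not in ("C", "G"):
                raise ParseError(f"nucleotide column must be C or G, got {nuc!r}", lineno)
            if ctx not in _CGMAP_CONTEXTS:
                raise ParseError(f"unknown context class {ctx!r}", lineno)
            try:
                pos = int(pos_s)
                meth = float(meth_s)
                n_meth = int(nm_s)
                n_total = int(nt_s)
            except ValueError as exc:
                raise ParseError(f"non-numeric field ({exc})", lineno) from None
            if n_total > 0:
                meth = n_meth / n_total
            try:
                calls.append(
                    CpGCall(
                        chrom=chrom,
                        pos=pos,
                        strand="+" if nuc == "C" else "-",
                        context=_CGMAP_CONTEXTS[ctx],
                        meth_level=meth,
                        n_meth=n_meth,
                        n_total=n_total,
                    )
                )
            except ValidationError as exc:
                raise ParseError(str(exc), lineno) from None
    return calls


def read_bismark_cov(path: str | Path) -> list[CpGCall]:
    """Read a Bismark coverage file into ``CpGCall`` records.

    Columns: chrom, start, end (1-based inclusive), methylation percentage,
    methylated count, unmethylated count.  The dialect carries neither strand
    nor context: strand is recorded as "+" with ``strand_known=False`` and
    context is assumed CpG.
    """
    calls: list[CpGCall] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = _fields(line, 6, lineno)
            chrom, start_s, _end_s, pct_s, nm_s, nu_s = parts[:6]
            try:
                pos = int(start_s)
                pct = float(pct_s)
                n_meth = int(nm_s)
                n_unmeth = int(nu_s)
            except ValueError as exc:
                raise ParseError(f"non-numeric field ({exc})", lineno) from None
            if not (0.0 <= pct <= 100.0):
                raise ParseError(f"methylation percentage outside [0,100]: {pct}", lineno)
            n_total = n_meth + n_unmeth
            meth = n_meth / n_total if n_total > 0 else pct / 100.0
            try:
                calls.append(
                    CpGCall(
                        chrom=chrom,
                        pos=pos,
                        strand="+",
                        context="CpG",
                        meth_level=meth,
                        n_meth=n_meth,
                        n_total=n_total,
                        strand_known=False,
                    )
                )
            except ValidationError as exc:
                raise ParseError(str(exc), lineno) from None
    return calls


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 (extra columns ignored) preserving record order."""
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = _fields(line, 3, lineno)
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate ({exc})", lineno) from None
            name = parts[3] if len(parts) > 3 else ""
            try:
                intervals.append(GenomicInterval(chrom, start, end, name))
            except ValidationError as exc:
                raise ParseError(str(exc), lineno) from None
    return intervals


def write_cgmap(calls: Iterable[CpGCall], path: str | Path, *, compress: bool = False) -> None:
    """Write calls in CGmap layout (inverse of :func:`read_cgmap`)."""
    ctx_back = {v: k for k, v in _CGMAP_CONTEXTS.items()}
    dinuc = {"CpG": "CG", "CHG": "CC", "CHH": "CA"}
    if compress:
        # mtime=0 keeps output bytes a pure function of the input
        import io as _stdio

        raw = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
        fh_ctx = _stdio.TextIOWrapper(raw)
    else:
        fh_ctx = open(path, "wt")
    with fh_ctx as fh:
        for c in calls:
            meth = c.n_meth / c.n_total if c.n_total > 0 else c.meth_level
            fh.write(
                f"{c.chrom}\t{'C' if c.strand == '+' else 'G'}\t{c.pos}\t"
                f"{ctx_back[c.context]}\t{dinuc[c.context]}\t{meth:.6f}\t"
                f"{c.n_meth}\t{c.n_total}\n"
            )


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def merge_symmetric_cpgs(calls: Sequence[CpGCall]) -> list[CpGCall]:
    """Combine the two strand-symmetric cytosines of a CpG dyad.

    A "+"-strand CpG at position p followed by a "-"-strand CpG at p+1 on the
    same chromosome is replaced by a single call at p with summed counts;
    unpaired calls pass through unchanged.  Input must be sorted by
    (chrom, pos).  Idempotent, and conserves total n_meth and n_total.
    """
    _check_sorted(calls)
    merged: list[CpGCall] = []
    i = 0
    while i < len(calls):
        cur = calls[i]
        nxt = calls[i + 1] if i + 1 < len(calls) else None
        if (
            nxt is not None
            and cur.context == "CpG"
            and nxt.context == "CpG"
            and cur.strand == "+"
            and nxt.strand == "-"
            and nxt.chrom == cur.chrom
            and nxt.pos == cur.pos + 1
        ):
            n_meth = cur.n_meth + nxt.n_meth
            n_total = cur.n_total + nxt.n_total
            merged.append(
                CpGCall(
                    chrom=cur.chrom,
                    pos=cur.pos,
                    strand="+",
                    context="CpG",
                    meth_level=n_meth / n_total if n_total > 0 else 0.0,
                    n_meth=n_meth,
                    n_total=n_total,
                    strand_known=cur.strand_known and nxt.strand_known,
                )
            )
            i += 2
        else:
            merged.append(cur)
            i += 1
    return merged


def _check_sorted(calls: Sequence[CpGCall]) -> None:
    for a, b in zip(calls, calls[1:]):
        if a.chrom == b.chrom and b.pos < a.pos:
            raise ValidationError(
                f"calls not sorted by (chrom, pos): {a.chrom}:{a.pos} precedes {b.chrom}:{b.pos}"
            )


def write_regions_bed(regions, path: str | Path) -> None:
    """Write hemi-methylated regions as BED6.

    Name is ``<kind>_<i>`` with a per-kind 1-based index in coordinate order,
    score is the supporting hemi-CpG count, strand ".".  Output bytes are a
    deterministic function of the input.
    """
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    counters: dict[str, int] = {}
    with open(path, "wt") as fh:
        for r in regions:
            counters[r.kind] = counters.get(r.kind, 0) + 1
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.kind}_{counters[r.kind]}\t{r.n_hemi}\t.\n"
            )
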