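"""Intersection of classified CpGs and hemi regions with the candidate panel.

Every CpG is assigned to the candidate interval containing its position;
called regions are assigned by their midpoint (candidates are orders of
magnitude larger than regions, so midpoint assignment avoids double
counting at edges).  Items outside every candidate are tallied as
off-panel.  Candidates are then ranked by the size of their largest
hemi-CpG cluster, the read-out used to nominate the top imprinted locus.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .classify import ClassifiedCpG, MethylationClass
from .errors import ValidationError
from .io import GenomicInterval
from .regions import HemiRegion

__all__ = ["CandidateSummary", "AnnotationResult", "annotate", "rank_candidates", "write_candidate_table"]


@dataclass
class CandidateSummary:
    """Per-candidate CpG-class and region tallies.

    The five class counts partition ``n_cpg_total``; ``max_cluster_hemi`` is
    the largest supporting-CpG count of any region assigned to the
    candidate (either kind).
    """

    candidate: GenomicInterval
    n_cpg_total: int = 0
    n_hypo: int = 0
    n_hyper: int = 0
    n_hemi: int = 0
    n_intermediate: int = 0
    n_low_depth: int = 0
    n_hemiR100: int = 0
    n_hemiR5: int = 0
    max_cluster_hemi: int = 0

    @property
    def name(self) -> str:
        return self.candidate.label


@dataclass
class AnnotationResult:
    summaries: list[CandidateSummary]
    off_panel: CandidateSummary  # tallies for items outside every candidate

    @property
    def n_candidates_with_regions(self) -> int:
        return sum(1 for s in self.summaries if s.n_hemiR100 + s.n_hemiR5 > 0)


class _PanelIndex:
    """Point-containment lookup over validated non-overlapping intervals."""

    def __init__(self, panel: Sequence[GenomicInterval]):
        if not panel:
            raise ValidationError("candidate panel must be non-empty")
        self._by_chrom: dict[str, tuple[list[int], list[tuple[int, int]]]] = {}
        by_chrom: dict[str, list[tuple[GenomicInterval, int]]] = {}
        for idx, iv in enumerate(panel):
            by_chrom.setdefault(iv.chrom, []).append((iv, idx))
        for chrom, items in by_chrom.items():
            items.sort(key=lambda t: t[0].start)
            for (a, _), (b, _) in zip(items, items[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"overlapping panel intervals: {a.label} and {b.label}"
                    )
            self._by_chrom[chrom] = (
                [iv.start for iv, _ in items],
                [(iv.end, idx) for iv, idx in items],
            )

    def find(self, chrom: str, pos_0based: int) -> int | None:
        """Index of the panel interval containing a 0-based position."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends = entry
        i = bisect_right(starts, pos_0based) - 1
        if i >= 0 and pos_0based < ends[i][0]:
            return ends[i][1]
        return None


_CLASS_FIELD = {
    MethylationClass.HYPO: "n_hypo",
    MethylationClass.HYPER: "n_hyper",
    MethylationClass.HEMI: "n_hemi",
    MethylationClass.INTERMEDIATE: "n_intermediate",
    MethylationClass.LOW_DEPTH: "n_low_depth",
}


def annotate(
    classified: Sequence[ClassifiedCpG],
    regions: Iterable[HemiRegion],
    panel: Sequence[GenomicInterval],
) -> AnnotationResult:
    """Tally classified CpGs and called regions per candidate interval.

    The panel must be non-overlapping (validated).  Every candidate gets a
    summary, including empty ones; off-panel items are tallied separately so
    the total is conserved.
    """
    index = _PanelIndex(panel)
    summaries = [CandidateSummary(candidate=iv) for iv in panel]
    off = CandidateSummary(candidate=GenomicInterval("off_panel", 0, 1, "off_panel"))

    for c in classified:
        i = index.find(c.call.chrom, c.call.pos - 1)
        target = summaries[i] if i is not None else off
        target.n_cpg_total += 1
        setattr(target, _CLASS_FIELD[c.klass], getattr(target, _CLASS_FIELD[c.klass]) + 1)

    for region in regions:
        i = index.find(region.chrom, region.midpoint)
        target = summaries[i] if i is not None else off
        if region.kind == "hemiR100":
            target.n_hemiR100 += 1
        else:
            target.n_hemiR5 += 1
        target.max_cluster_hemi = max(target.max_cluster_hemi, region.n_hemi)

    return AnnotationResult(summaries=summaries, off_panel=off)


def rank_candidates(summaries: Sequence[CandidateSummary]) -> list[CandidateSummary]:
    """Rank candidates by largest hemi cluster, then total hemi CpGs, then name.

    Deterministic and invariant to input order.
    """
    return sorted(
        summaries,
        key=lambda s: (-s.max_cluster_hemi, -s.n_hemi, s.name),
    )


def write_candidate_table(result: AnnotationResult, path: str | Path, ranked: bool = True) -> None:
    rows = rank_candidates(result.summaries) if ranked else list(result.summaries)
    with open(path, "wt") as fh:
        fh.write(
            "candidate\tchrom\tstart\tend\tn_cpg_total\tn_hypo\tn_hyper\tn_hemi\t"
            "n_intermediate\tn_low_depth\tn_hemiR100\tn_hemiR5\tmax_cluster_hemi\n"
        )
        for s in rows + [result.off_panel]:
            iv = s.candidate
            fh.write(
                f"{s.name}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{s.n_cpg_total}\t{s.n_hypo}\t"
                f"{s.n_hyper}\t{s.n_hemi}\t{s.n_intermediate}\t{s.n_low_depth}\t"
                f"{s.n_hemiR100}\t{s.n_hemiR5}\t{s.max_cluster_hemi}\n"
            )
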