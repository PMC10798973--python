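"""Parent-of-origin assignment of hemi-methylated regions.

In a reciprocal cross between two divergent lines, a SNP at which the
offspring is heterozygous and only one assignment of its alleles to
(sire, dam) is Mendelian-consistent tells unambiguously which chromosome
each sequencing read came from.  Reads that co-observe such a SNP allele and
the methylation state of CpGs inside a hemi-methylated region therefore
split the region's methylation by parental allele; a region whose paternal
allele is methylated while the maternal allele is not (or vice versa) is
called paternally (maternally) methylated.  A gamete sample closes the loop:
sperm carries the paternal germline state, so a paternally methylated
germline DMR must be fully methylated in sperm and a maternally methylated
one fully unmethylated.

The classical read-out of this evidence is manual genome-browser
inspection; this module makes it an explicit, configurable decision rule
(minimum observations per allele, per-allele methylation thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, ParseError, ValidationError
from .io import CpGCall
from .regions import HemiRegion

__all__ = [
    "TrioGenotypes",
    "PhasedObservation",
    "PofOThresholds",
    "AlleleMethylation",
    "PofOCall",
    "SNPPhasing",
    "informative_snps",
    "allele_methylation",
    "call_pofo",
    "germline_check",
    "phase_regions",
    "read_trio_table",
    "read_observation_table",
    "write_pofo_table",
]

_BASES = frozenset("ACGT")

PATERNAL = "paternal"
MATERNAL = "maternal"
AMBIGUOUS = "ambiguous"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class TrioGenotypes:
    """Genotypes of one SNP in a sire/dam/offspring trio (unordered pairs)."""

    snp_id: str
    chrom: str
    pos: int
    sire_gt: tuple[str, str]
    dam_gt: tuple[str, str]
    offspring_gt: tuple[str, str]

    def __post_init__(self) -> None:
        for gt in (self.sire_gt, self.dam_gt, self.offspring_gt):
            if len(gt) != 2 or any(a not in _BASES for a in gt):
                raise ValidationError(f"{self.snp_id}: genotype must be a pair of ACGT, got {gt}")


@dataclass(frozen=True)
class PhasedObservation:
    """One read's joint observation of a SNP allele and a CpG state."""

    read_id: str
    chrom: str
    snp_pos: int
    allele: str
    cpg_pos: int
    meth_state: str  # "methylated" | "unmethylated"

    def __post_init__(self) -> None:
        if self.allele not in _BASES:
            raise ValidationError(f"allele must be one of ACGT, got {self.allele!r}")
        if self.meth_state not in ("methylated", "unmethylated"):
            raise ValidationError(f"bad meth_state {self.meth_state!r}")


@dataclass(frozen=True)
class PofOThresholds:
    """Decision rule for the parent-of-origin call.

    A region is called only when both alleles carry at least ``min_obs``
    observations and the methylated allele is >= ``high_meth`` while the
    other is <= ``low_meth`` (mirroring the hypo/hyper CpG thresholds).
    """

    min_obs: int = 10
    high_meth: float = 0.7
    low_meth: float = 0.3

    def __post_init__(self) -> None:
        if self.min_obs < 1:
            raise ConfigError("min_obs must be >= 1")
        if not (0 <= self.low_meth < self.high_meth <= 1):
            raise ConfigError("require 0 <= low_meth < high_meth <= 1")


@dataclass(frozen=True)
class AlleleMethylation:
    pat_meth: float | None
    mat_meth: float | None
    n_obs_pat: int
    n_obs_mat: int
    n_excluded: int = 0


@dataclass(frozen=True)
class PofOCall:
    region: HemiRegion
    origin: str  # paternal | maternal | ambiguous | uninformative
    pat_meth: float | None
    mat_meth: float | None
    n_obs_pat: int
    n_obs_mat: int


@dataclass(frozen=True)
class SNPPhasing:
    """Result of trio phasing: allele->parent maps plus exclusions."""

    allele_maps: dict[str, dict[str, str]]  # snp_id -> {allele: parent}
    by_position: dict[tuple[str, int], dict[str, str]]
    excluded: dict[str, str]  # snp_id -> reason

    @property
    def n_inconsistent(self) -> int:
        return sum(1 for r in self.excluded.values() if r == "mendelian_inconsistent")


def informative_snps(trios: Sequence[TrioGenotypes]) -> SNPPhasing:
    """Select cross-informative SNPs and map offspring alleles to parents.

    A SNP is informative iff the offspring is heterozygous and exactly one
    assignment of its two alleles to (sire, dam) is Mendelian-consistent.
    Uninformative and Mendelian-inconsistent SNPs are excluded with a
    recorded reason; an inconsistent trio never contributes to calls.
    """
    allele_maps: dict[str, dict[str, str]] = {}
    by_position: dict[tuple[str, int], dict[str, str]] = {}
    excluded: dict[str, str] = {}
    for trio in trios:
        x, y = trio.offspring_gt
        if x == y:
            excluded[trio.snp_id] = "offspring_homozygous"
            continue
        assignments = []
        for pat, mat in ((x, y), (y, x)):
            if pat in trio.sire_gt and mat in trio.dam_gt:
                assignments.append((pat, mat))
        if not assignments:
            excluded[trio.snp_id] = "mendelian_inconsistent"
        elif len(assignments) > 1:
            excluded[trio.snp_id] = "ambiguous_assignment"
        else:
            pat, mat = assignments[0]
            amap = {pat: PATERNAL, mat: MATERNAL}
            allele_maps[trio.snp_id] = amap
            by_position[(trio.chrom, trio.pos)] = amap
    return SNPPhasing(allele_maps, by_position, excluded)


def allele_methylation(
    region: HemiRegion,
    observations: Iterable[PhasedObservation],
    snp_map: SNPPhasing | Mapping[tuple[str, int], Mapping[str, str]],
) -> AlleleMethylation:
    """Split a region's CpG observations by parental allele.

    Observations outside the region, at SNPs without an informative map, or
    carrying an allele absent from the map are excluded (counted).
    """
    lookup = snp_map.by_position if isinstance(snp_map, SNPPhasing) else snp_map
    counts = {PATERNAL: [0, 0], MATERNAL: [0, 0]}  # [methylated, total]
    n_excluded = 0
    for obs in observations:
        if obs.chrom != region.chrom or not (region.start < obs.cpg_pos <= region.end):
            continue
        amap = lookup.get((obs.chrom, obs.snp_pos))
        if amap is None or obs.allele not in amap:
            n_excluded += 1
            continue
        parent = amap[obs.allele]
        counts[parent][1] += 1
        if obs.meth_state == "methylated":
            counts[parent][0] += 1
    pat_m, pat_t = counts[PATERNAL]
    mat_m, mat_t = counts[MATERNAL]
    return AlleleMethylation(
        pat_meth=pat_m / pat_t if pat_t else None,
        mat_meth=mat_m / mat_t if mat_t else None,
        n_obs_pat=pat_t,
        n_obs_mat=mat_t,
        n_excluded=n_excluded,
    )


def call_pofo(
    region: HemiRegion,
    allele_meth: AlleleMethylation,
    thresholds: PofOThresholds = PofOThresholds(),
) -> PofOCall:
    """Turn per-allele methylation into a parent-of-origin verdict."""
    am = allele_meth
    if am.n_obs_pat < thresholds.min_obs or am.n_obs_mat < thresholds.min_obs:
        origin = UNINFORMATIVE
    elif am.pat_meth >= thresholds.high_meth and am.mat_meth <= thresholds.low_meth:
        origin = PATERNAL
    elif am.mat_meth >= thresholds.high_meth and am.pat_meth <= thresholds.low_meth:
        origin = MATERNAL
    else:
        origin = AMBIGUOUS
    return PofOCall(
        region=region,
        origin=origin,
        pat_meth=am.pat_meth,
        mat_meth=am.mat_meth,
        n_obs_pat=am.n_obs_pat,
        n_obs_mat=am.n_obs_mat,
    )


def germline_check(
    region: HemiRegion,
    gamete_calls: Sequence[CpGCall],
    expected_origin: str,
    thresholds: PofOThresholds = PofOThresholds(),
    min_depth: int = 20,
) -> str:
    """Check a called region against the paternal germline (sperm) state.

    Sperm carries the paternal chromosome complement, so a paternally
    methylated germline DMR should be near-fully methylated in sperm, a
    maternally methylated one near-fully unmethylated.  Returns
    "consistent", "inconsistent" or "no_data".
    """
    if expected_origin not in (PATERNAL, MATERNAL):
        raise ValidationError(f"expected_origin must be paternal/maternal, got {expected_origin!r}")
    levels = [
        c.n_meth / c.n_total
        for c in gamete_calls
        if c.chrom == region.chrom
        and region.start < c.pos <= region.end
        and c.context == "CpG"
        and c.n_total >= min_depth
    ]
    if not levels:
        return "no_data"
    mean = sum(levels) / len(levels)
    if expected_origin == PATERNAL:
        return "consistent" if mean >= thresholds.high_meth else "inconsistent"
    return "consistent" if mean <= thresholds.low_meth else "inconsistent"


def phase_regions(
    regions: Sequence[HemiRegion],
    trios: Sequence[TrioGenotypes],
    observations: Sequence[PhasedObservation],
    thresholds: PofOThresholds = PofOThresholds(),
) -> list[PofOCall]:
    """End-to-end: informative SNPs -> per-region allele split -> verdicts."""
    phasing = informative_snps(trios)
    return [
        call_pofo(region, allele_methylation(region, observations, phasing), thresholds)
        for region in regions
    ]


# ---------------------------------------------------------------------------
# TSV interchange


def _parse_gt(text: str, where: str) -> tuple[str, str]:
    alleles = text.replace("|", "/").split("/") if "/" in text or "|" in text else list(text)
    if len(alleles) != 2:
        raise ParseError(f"{where}: genotype must have two alleles, got {text!r}")
    return (alleles[0], alleles[1])


def read_trio_table(path: str | Path) -> list[TrioGenotypes]:
    """Trio genotype TSV: snp_id, chrom, pos, sire_gt, dam_gt, offspring_gt."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "chrom", "pos", "sire_gt", "dam_gt", "offspring_gt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"trio table {path} missing column(s): {missing}")
    trios = []
    for row in df.itertuples(index=False):
        trios.append(
            TrioGenotypes(
                snp_id=row.snp_id,
                chrom=row.chrom,
                pos=int(row.pos),
                sire_gt=_parse_gt(row.sire_gt, row.snp_id),
                dam_gt=_parse_gt(row.dam_gt, row.snp_id),
                offspring_gt=_parse_gt(row.offspring_gt, row.snp_id),
            )
        )
    return trios


def read_observation_table(path: str | Path) -> list[PhasedObservation]:
    """Observation TSV: read_id, chrom, snp_pos, allele, cpg_pos, meth_state."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["read_id", "chrom", "snp_pos", "allele", "cpg_pos", "meth_state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"observation table {path} missing column(s): {missing}")
    return [
        PhasedObservation(
            read_id=row.read_id,
            chrom=row.chrom,
            snp_pos=int(row.snp_pos),
            allele=row.allele,
            cpg_pos=int(row.cpg_pos),
            meth_state=row.meth_state,
        )
        for row in df.itertuples(index=False)
    ]


def write_pofo_table(calls: Sequence[PofOCall], path: str | Path) -> None:
    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.6f}"

    with open(path, "wt") as fh:
        fh.write(
            "chrom\tstart\tend\tkind\tn_hemi\torigin\tpat_meth\tmat_meth\tn_obs_pat\tn_obs_mat\n"
        )
        for c in calls:
            r = c.region
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.kind}\t{r.n_hemi}\t{c.origin}\t"
                f"{fmt(c.pat_meth)}\t{fmt(c.mat_meth)}\t{c.n_obs_pat}\t{c.n_obs_mat}\n"
            )
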