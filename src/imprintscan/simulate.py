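"""Synthetic methyl-seq study generator with known ground truth.

Emulates, from a single seed, the full data structure of a reciprocal-cross
targeted methyl-seq experiment: a candidate-region panel with clustered CpG
positions, germline DMRs of known parental origin planted inside candidates,
per-individual CGmap methylation calls (offspring and parent blood, plus a
sperm sample carrying the paternal germline state), fixed-difference SNPs
between the two founder lines with read-level SNP–CpG co-observations, and
depth/read/GC tracks for capture QC.  A :class:`TruthManifest` records every
planted feature so each pipeline stage can be scored exactly.

Noise model
-----------
Background (non-DMR) CpGs draw a true level from a beta distribution centred
on a hypo- (~0.03) or hyper-methylated (~0.97) state with SD
``meth_noise_sd``, then binomial read sampling given a negative-binomial
depth.  DMR CpGs in blood are emitted **per allele**: the two parental
alleles contribute balanced read counts (``ceil(d/2)`` / ``floor(d/2)``) and
each read reports its allele's methylation state with a flip probability of
``meth_noise_sd``; at zero noise the aggregate level is exactly
``ceil(d/2)/d`` and every planted DMR CpG is hemi-methylated by
construction.  Allelic depth imbalance is deliberately not modelled (see the
methods note).  Sperm DMR CpGs use the beta-binomial path around the
germline state (~0.98 methylated for paternal-origin DMRs, ~0.02 for
maternal).  Non-CpG cytosines (CHH/CHG) are emitted with methylation equal
to the configured conversion-failure rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .io import CpGCall, GenomicInterval, write_bed, write_cgmap
from .phasing import PhasedObservation, TrioGenotypes
from .qc import DepthTrack

__all__ = [
    "SimulationConfig",
    "DMRTruth",
    "SNPTruth",
    "TruthManifest",
    "CrossData",
    "QCInputs",
    "simulate_panel",
    "simulate_individual",
    "simulate_cross",
    "simulate_qc_inputs",
    "simulate_all",
]

ROLES = ("offspring_blood", "parent_blood", "sperm")
DIRECTIONS = ("LWxMS", "MSxLW")  # sire line first
_MIN_REGION_CPGS = 5  # detectability floor for planted DMRs


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length_bp: int | None = None  # None: sized to fit the panel
    n_candidates: int = 12
    candidate_size_bp: tuple[int, int] = (5_000, 50_000)
    cpg_spacing_bp: int = 25
    n_dmrs: int = 6  # half paternal-, half maternal-methylated
    dmr_n_cpgs: tuple[int, int] = (8, 120)
    dmr_cpg_spacing_bp: tuple[int, int] = (12, 20)
    depth_mean: float = 40.0
    depth_dispersion: float = 5.0
    depth_floor: int = 1
    meth_noise_sd: float = 0.03
    background_hemi_rate: float = 0.01
    background_hypo_fraction: float = 0.3
    hypo_level: float = 0.03
    hyper_level: float = 0.97
    sperm_meth_high: float = 0.98
    sperm_meth_low: float = 0.02
    snp_density: int = 2  # informative SNPs per DMR
    failure_conversion_rate: float = 0.005
    noncpg_per_cpg: float = 1.0  # non-CpG cytosines emitted per CpG
    obs_reads_per_snp: int = 30
    obs_cpgs_per_read: int = 5
    n_offspring_per_direction: int = 1
    # capture-QC inputs
    n_qc_reads: int = 10_000
    read_length_bp: int = 150
    off_target_rate: float = 0.2
    gc_range: tuple[float, float] = (0.35, 0.65)
    gc_bias: float = 2.0  # log-linear weight of (gc - 0.5) on target coverage

    def __post_init__(self) -> None:
        for name in (
            "meth_noise_sd", "background_hemi_rate", "background_hypo_fraction",
            "hypo_level", "hyper_level", "sperm_meth_high", "sperm_meth_low",
            "failure_conversion_rate", "off_target_rate",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        for name in ("candidate_size_bp", "dmr_n_cpgs", "dmr_cpg_spacing_bp", "gc_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} range must be non-degenerate, got ({lo}, {hi})")
        if self.n_dmrs > self.n_candidates:
            raise ConfigError("n_dmrs cannot exceed n_candidates")
        if self.n_dmrs and self.dmr_n_cpgs[0] < _MIN_REGION_CPGS:
            raise ConfigError(
                f"dmr_n_cpgs minimum must be >= {_MIN_REGION_CPGS} so every planted "
                "DMR is detectable"
            )
        max_dmr_len = self.dmr_n_cpgs[1] * self.dmr_cpg_spacing_bp[1]
        if self.n_dmrs and self.candidate_size_bp[0] < max_dmr_len + 600:
            raise ConfigError("candidate_size_bp minimum too small to host the largest DMR")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ConfigError("depth model parameters must be positive")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class DMRTruth:
    name: str
    interval: GenomicInterval
    origin: str  # paternal | maternal (methylated allele)
    cpg_positions: tuple[int, ...]
    candidate: str


@dataclass(frozen=True)
class SNPTruth:
    snp_id: str
    chrom: str
    pos: int
    lw_allele: str
    ms_allele: str
    dmr_name: str


@dataclass
class TruthManifest:
    """Ground truth of one simulated study."""

    chrom_lengths: dict[str, int]
    candidates: list[GenomicInterval]
    cpg_positions: dict[str, tuple[int, ...]]
    dmrs: list[DMRTruth]
    snps: list[SNPTruth]

    def dmr_origin_by_pos(self) -> dict[tuple[str, int], str]:
        out: dict[tuple[str, int], str] = {}
        for dmr in self.dmrs:
            for p in dmr.cpg_positions:
                out[(dmr.interval.chrom, p)] = dmr.origin
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "chrom_lengths": self.chrom_lengths,
            "candidates": [asdict(c) for c in self.candidates],
            "cpg_positions": {k: list(v) for k, v in self.cpg_positions.items()},
            "dmrs": [
                {**asdict(d), "interval": asdict(d.interval), "cpg_positions": list(d.cpg_positions)}
                for d in self.dmrs
            ],
            "snps": [asdict(s) for s in self.snps],
        }
        with open(path, "wt") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            chrom_lengths=p["chrom_lengths"],
            candidates=[GenomicInterval(**c) for c in p["candidates"]],
            cpg_positions={k: tuple(v) for k, v in p["cpg_positions"].items()},
            dmrs=[
                DMRTruth(
                    name=d["name"],
                    interval=GenomicInterval(**d["interval"]),
                    origin=d["origin"],
                    cpg_positions=tuple(d["cpg_positions"]),
                    candidate=d["candidate"],
                )
                for d in p["dmrs"]
            ],
            snps=[SNPTruth(**s) for s in p["snps"]],
        )


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), *stream])


def _fill_cpg_positions(rng: np.random.Generator, lo: int, hi: int, mean_spacing: int) -> list[int]:
    """CpG positions in [lo, hi] with exponential-ish spacing (min 2 bp)."""
    out: list[int] = []
    pos = lo + int(rng.exponential(mean_spacing))
    while pos <= hi:
        out.append(pos)
        pos += 2 + int(rng.exponential(max(mean_spacing - 2, 1)))
    return out


def simulate_panel(config: SimulationConfig) -> TruthManifest:
    """Lay out candidates, CpG maps, planted DMRs and line-fixed SNPs."""
    rng = _rng(config, 0)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    # place candidates round-robin across chromosomes
    cursors = {c: 10_000 for c in chroms}
    candidates: list[GenomicInterval] = []
    for i in range(config.n_candidates):
        chrom = chroms[i % len(chroms)]
        size = int(rng.integers(config.candidate_size_bp[0], config.candidate_size_bp[1] + 1))
        start = cursors[chrom] + int(rng.integers(20_000, 50_000))
        candidates.append(GenomicInterval(chrom, start, start + size, f"cand{i + 1:03d}"))
        cursors[chrom] = start + size
    chrom_lengths = {c: cursors[c] + 10_000 for c in chroms}
    if config.chromosome_length_bp is not None:
        if any(length > config.chromosome_length_bp for length in chrom_lengths.values()):
            raise ConfigError(
                f"candidates do not fit on chromosomes of {config.chromosome_length_bp} bp"
            )
        chrom_lengths = {c: config.chromosome_length_bp for c in chroms}

    dmr_host_idx = sorted(rng.choice(config.n_candidates, size=config.n_dmrs, replace=False))
    origins = ["paternal" if i % 2 == 0 else "maternal" for i in range(config.n_dmrs)]

    cpgs_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    dmrs: list[DMRTruth] = []
    snps: list[SNPTruth] = []
    margin = 300

    for ci, cand in enumerate(candidates):
        if ci in dmr_host_idx:
            d_i = dmr_host_idx.index(ci)
            k = int(rng.integers(config.dmr_n_cpgs[0], config.dmr_n_cpgs[1] + 1))
            spacings = rng.integers(
                config.dmr_cpg_spacing_bp[0], config.dmr_cpg_spacing_bp[1] + 1, size=k - 1
            )
            dmr_len = int(spacings.sum()) + 1
            d_start = int(rng.integers(cand.start + 1 + margin, cand.end - dmr_len - margin))
            positions = [d_start]
            for s in spacings:
                positions.append(positions[-1] + int(s))
            name = f"DMR{d_i + 1:02d}"
            dmrs.append(
                DMRTruth(
                    name=name,
                    interval=GenomicInterval(cand.chrom, positions[0] - 1, positions[-1], name),
                    origin=origins[d_i],
                    cpg_positions=tuple(positions),
                    candidate=cand.name,
                )
            )
            # line-fixed SNPs between DMR CpGs
            gap_idx = rng.choice(k - 1, size=min(config.snp_density, k - 1), replace=False)
            for j, g in enumerate(sorted(int(x) for x in gap_idx)):
                offset = int(rng.integers(3, max(4, int(spacings[g]) - 2)))
                snp_pos = positions[g] + offset
                snps.append(
                    SNPTruth(
                        snp_id=f"{name}_snp{j + 1}",
                        chrom=cand.chrom,
                        pos=snp_pos,
                        lw_allele="A",
                        ms_allele="G",
                        dmr_name=name,
                    )
                )
            # background CpGs flanking the DMR (50-bp buffer)
            bg = _fill_cpg_positions(rng, cand.start + 1, positions[0] - 50, config.cpg_spacing_bp)
            bg += _fill_cpg_positions(rng, positions[-1] + 50, cand.end, config.cpg_spacing_bp)
            cpgs_by_chrom[cand.chrom].extend(sorted(bg + positions))
        else:
            cpgs_by_chrom[cand.chrom].extend(
                _fill_cpg_positions(rng, cand.start + 1, cand.end, config.cpg_spacing_bp)
            )

    return TruthManifest(
        chrom_lengths=chrom_lengths,
        candidates=candidates,
        cpg_positions={c: tuple(sorted(set(ps))) for c, ps in cpgs_by_chrom.items()},
        dmrs=dmrs,
        snps=snps,
    )


def _beta_around(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Beta draw with the given per-element mean and common SD (clipped)."""
    if sd <= 0:
        return np.asarray(mean, dtype=float)
    m = np.clip(np.asarray(mean, dtype=float), 1e-3, 1 - 1e-3)
    v = np.minimum(sd * sd, m * (1 - m) * 0.95)
    nu = m * (1 - m) / v - 1
    return rng.beta(m * nu, (1 - m) * nu)


def _nb_depth(rng: np.random.Generator, config: SimulationConfig, size: int) -> np.ndarray:
    r = config.depth_dispersion
    p = r / (r + config.depth_mean)
    d = rng.negative_binomial(r, p, size=size)
    return np.maximum(d, max(config.depth_floor, 1))


def simulate_individual(
    manifest: TruthManifest,
    role: str,
    cross_direction: str,
    config: SimulationConfig,
    stream: int = 0,
) -> list[CpGCall]:
    """Emit one individual's per-cytosine calls (CpG plus CHH/CHG rows)."""
    if role not in ROLES:
        raise ValidationError(f"unknown role {role!r}; expected one of {ROLES}")
    if cross_direction not in DIRECTIONS:
        raise ValidationError(f"unknown cross direction {cross_direction!r}")
    rng = _rng(config, 1, ROLES.index(role), DIRECTIONS.index(cross_direction), stream)
    eps = config.meth_noise_sd
    origin_by_pos = manifest.dmr_origin_by_pos()

    calls: list[CpGCall] = []
    for chrom in sorted(manifest.cpg_positions):
        pos = np.asarray(manifest.cpg_positions[chrom], dtype=np.int64)
        n = len(pos)
        if n == 0:
            continue
        depth = _nb_depth(rng, config, n)
        origins = np.array(
            [origin_by_pos.get((chrom, int(p)), "") for p in pos], dtype=object
        )
        in_dmr = origins != ""

        n_meth = np.zeros(n, dtype=np.int64)

        # background CpGs: beta-binomial around a hypo/hyper (rarely hemi) state
        bg = ~in_dmr
        n_bg = int(bg.sum())
        if n_bg:
            true = np.where(
                rng.random(n_bg) < config.background_hypo_fraction,
                config.hypo_level,
                config.hyper_level,
            )
            hemi_like = rng.random(n_bg) < config.background_hemi_rate
            true = np.where(hemi_like, 0.5, true)
            level = _beta_around(rng, true, eps)
            n_meth[bg] = rng.binomial(depth[bg], level)

        n_dmr = int(in_dmr.sum())
        if n_dmr:
            d = depth[in_dmr]
            if role in ("offspring_blood", "parent_blood"):
                # balanced allelic sampling: one methylated, one unmethylated allele
                n_hi = (d + 1) // 2
                n_meth[in_dmr] = rng.binomial(n_hi, 1 - eps) + rng.binomial(d - n_hi, eps)
            else:  # sperm: paternal germline state
                true = np.where(
                    origins[in_dmr] == "paternal", config.sperm_meth_high, config.sperm_meth_low
                )
                level = _beta_around(rng, true, eps)
                n_meth[in_dmr] = rng.binomial(d, level)

        for i in range(n):
            calls.append(
                CpGCall(
                    chrom=chrom,
                    pos=int(pos[i]),
                    strand="+",
                    context="CpG",
                    meth_level=int(n_meth[i]) / int(depth[i]),
                    n_meth=int(n_meth[i]),
                    n_total=int(depth[i]),
                )
            )

        # non-CpG cytosines for conversion QC, spread over this chromosome's candidates
        n_noncpg = int(round(config.noncpg_per_cpg * n))
        if n_noncpg:
            cands = [c for c in manifest.candidates if c.chrom == chrom]
            spans = np.array([len(c) for c in cands], dtype=float)
            pick = rng.choice(len(cands), size=n_noncpg, p=spans / spans.sum())
            taken = set(int(p) for p in pos)
            nc_rows = []
            for ci in pick:
                c = cands[int(ci)]
                p = int(rng.integers(c.start + 1, c.end + 1))
                if p in taken:
                    continue
                taken.add(p)
                nc_rows.append(p)
            nc_rows.sort()
            d_nc = _nb_depth(rng, config, len(nc_rows))
            m_nc = rng.binomial(d_nc, config.failure_conversion_rate)
            ctx_nc = np.where(rng.random(len(nc_rows)) < 0.75, "CHH", "CHG")
            for p, d, m, ctx in zip(nc_rows, d_nc, m_nc, ctx_nc):
                calls.append(
                    CpGCall(
                        chrom=chrom,
                        pos=int(p),
                        strand="+",
                        context=str(ctx),
                        meth_level=int(m) / int(d),
                        n_meth=int(m),
                        n_total=int(d),
                    )
                )

    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


@dataclass
class CrossData:
    """Genotypes and read-level observations for every simulated offspring."""

    trios: dict[str, list[TrioGenotypes]]  # offspring_id -> per-SNP trios
    observations: dict[str, list[PhasedObservation]]
    direction: dict[str, str]

    def reciprocal_pairs(self) -> list[tuple[str, str]]:
        a = sorted(k for k, d in self.direction.items() if d == "LWxMS")
        b = sorted(k for k, d in self.direction.items() if d == "MSxLW")
        return list(zip(a, b))


def simulate_cross(manifest: TruthManifest, config: SimulationConfig) -> CrossData:
    """Generate both cross directions with line-fixed (fully informative) SNPs."""
    if not manifest.snps:
        raise ConfigError("manifest has no SNPs; cannot simulate the cross")
    eps = config.meth_noise_sd
    dmr_by_name = {d.name: d for d in manifest.dmrs}
    trios: dict[str, list[TrioGenotypes]] = {}
    observations: dict[str, list[PhasedObservation]] = {}
    direction_of: dict[str, str] = {}

    for d_i, direction in enumerate(DIRECTIONS):
        for o_i in range(config.n_offspring_per_direction):
            rng = _rng(config, 2, d_i, o_i)
            offspring = f"offspring_{direction}_{o_i + 1}"
            direction_of[offspring] = direction
            trio_rows: list[TrioGenotypes] = []
            obs_rows: list[PhasedObservation] = []
            for snp in manifest.snps:
                lw, ms = snp.lw_allele, snp.ms_allele
                sire_allele = lw if direction == "LWxMS" else ms
                dam_allele = ms if direction == "LWxMS" else lw
                trio_rows.append(
                    TrioGenotypes(
                        snp_id=snp.snp_id,
                        chrom=snp.chrom,
                        pos=snp.pos,
                        sire_gt=(sire_allele, sire_allele),
                        dam_gt=(dam_allele, dam_allele),
                        offspring_gt=(sire_allele, dam_allele),
                    )
                )
                dmr = dmr_by_name[snp.dmr_name]
                k = len(dmr.cpg_positions)
                span = min(config.obs_cpgs_per_read, k)
                half = config.obs_reads_per_snp // 2
                for r in range(config.obs_reads_per_snp):
                    parent = "paternal" if r < half else "maternal"
                    allele = sire_allele if parent == "paternal" else dam_allele
                    start_idx = int(rng.integers(0, k - span + 1))
                    for cpg in dmr.cpg_positions[start_idx : start_idx + span]:
                        methylated = parent == dmr.origin
                        if rng.random() < eps:
                            methylated = not methylated
                        obs_rows.append(
                            PhasedObservation(
                                read_id=f"{offspring}_{snp.snp_id}_r{r + 1}",
                                chrom=snp.chrom,
                                snp_pos=snp.pos,
                                allele=allele,
                                cpg_pos=int(cpg),
                                meth_state="methylated" if methylated else "unmethylated",
                            )
                        )
            trios[offspring] = trio_rows
            observations[offspring] = obs_rows
    return CrossData(trios=trios, observations=observations, direction=direction_of)


@dataclass
class QCInputs:
    """Simulated inputs for the capture-QC stage."""

    reads: list[GenomicInterval]
    track: DepthTrack
    gc_by_target: dict[str, float]


def simulate_qc_inputs(manifest: TruthManifest, config: SimulationConfig) -> QCInputs:
    """Reads with a configured off-target rate, their pileup, and target GC.

    On-target reads are allocated to candidates with probability
    proportional to ``size * exp(gc_bias * (gc - 0.5))`` so mean per-target
    coverage correlates with GC with a known sign; off-target reads fall
    entirely inside inter-candidate gaps.  The depth track is the exact
    pileup of the emitted reads.
    """
    rng = _rng(config, 3)
    targets = manifest.candidates
    gc = rng.uniform(config.gc_range[0], config.gc_range[1], size=len(targets))
    gc_by_target = {t.name: float(g) for t, g in zip(targets, gc)}

    # off-target placement gaps (clear of every target by construction)
    rl = config.read_length_bp
    gaps: list[GenomicInterval] = []
    for chrom, length in sorted(manifest.chrom_lengths.items()):
        bounds = sorted((t.start, t.end) for t in targets if t.chrom == chrom)
        prev = 0
        for s, e in bounds + [(length, length)]:
            if s - prev > rl + 400:
                gaps.append(GenomicInterval(chrom, prev + 200, s - 200 - rl))
            prev = max(prev, e)
    gap_w = np.array([len(g) for g in gaps], dtype=float)

    w = np.array([len(t) for t in targets], dtype=float) * np.exp(
        config.gc_bias * (gc - 0.5)
    )
    w /= w.sum()

    n_off = int(rng.binomial(config.n_qc_reads, config.off_target_rate))
    reads: list[GenomicInterval] = []
    for _ in range(n_off):
        g = gaps[int(rng.choice(len(gaps), p=gap_w / gap_w.sum()))]
        s = int(rng.integers(g.start, g.end + 1))
        reads.append(GenomicInterval(g.chrom, s, s + rl, "off"))
    for _ in range(config.n_qc_reads - n_off):
        t = targets[int(rng.choice(len(targets), p=w))]
        s = int(rng.integers(t.start, t.end - rl + 1))
        reads.append(GenomicInterval(t.chrom, s, s + rl, "on"))

    # exact pileup -> run-length depth track
    runs: dict[str, list[tuple[int, int, int]]] = {}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        events: dict[int, int] = {}
        for r in rs:
            events[r.start] = events.get(r.start, 0) + 1
            events[r.end] = events.get(r.end, 0) - 1
        depth = 0
        prev_pos = None
        chrom_runs: list[tuple[int, int, int]] = []
        for p in sorted(events):
            if prev_pos is not None and depth > 0 and p > prev_pos:
                chrom_runs.append((prev_pos, p, depth))
            depth += events[p]
            prev_pos = p
        runs[chrom] = chrom_runs
    return QCInputs(reads=reads, track=DepthTrack(runs), gc_by_target=gc_by_target)


def write_bedgraph(track: DepthTrack, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for chrom in sorted(track._runs):
            for s, e, d in track._runs[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")


def write_fasta_targets(
    manifest: TruthManifest, gc_by_target: dict[str, float], config: SimulationConfig, path: str | Path
) -> None:
    """One record per candidate with the requested GC composition."""
    rng = _rng(config, 4)
    bases = np.array(list("GCAT"))
    with open(path, "wt") as fh:
        for t in manifest.candidates:
            g = gc_by_target[t.name]
            p = np.array([g / 2, g / 2, (1 - g) / 2, (1 - g) / 2])
            seq = "".join(rng.choice(bases, size=len(t), p=p))
            fh.write(f">{t.name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_trio_table(trios: Sequence[TrioGenotypes], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("snp_id\tchrom\tpos\tsire_gt\tdam_gt\toffspring_gt\n")
        for t in trios:
            fh.write(
                f"{t.snp_id}\t{t.chrom}\t{t.pos}\t{t.sire_gt[0]}/{t.sire_gt[1]}\t"
                f"{t.dam_gt[0]}/{t.dam_gt[1]}\t{t.offspring_gt[0]}/{t.offspring_gt[1]}\n"
            )


def write_observation_table(obs: Sequence[PhasedObservation], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("read_id\tchrom\tsnp_pos\tallele\tcpg_pos\tmeth_state\n")
        for o in obs:
            fh.write(
                f"{o.read_id}\t{o.chrom}\t{o.snp_pos}\t{o.allele}\t{o.cpg_pos}\t{o.meth_state}\n"
            )


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input; returns the file map.

    Emits the candidate panel, one blood CGmap per offspring (both cross
    directions), a sperm CGmap, trio/observation tables, QC inputs and the
    ground-truth manifest.  Byte-identical for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = simulate_panel(config)
    files: dict[str, Path] = {}

    files["panel"] = outdir / "panel.bed"
    write_bed(manifest.candidates, files["panel"])
    files["truth"] = outdir / "truth.json"
    manifest.to_json(files["truth"])

    cross = simulate_cross(manifest, config)
    for o_i, (offspring, direction) in enumerate(sorted(cross.direction.items())):
        calls = simulate_individual(manifest, "offspring_blood", direction, config, stream=o_i)
        files[f"cgmap_{offspring}"] = outdir / f"{offspring}.cgmap.gz"
        write_cgmap(calls, files[f"cgmap_{offspring}"], compress=True)
        files[f"trios_{offspring}"] = outdir / f"trios_{offspring}.tsv"
        write_trio_table(cross.trios[offspring], files[f"trios_{offspring}"])
        files[f"observations_{offspring}"] = outdir / f"observations_{offspring}.tsv"
        write_observation_table(cross.observations[offspring], files[f"observations_{offspring}"])

    sperm = simulate_individual(manifest, "sperm", "LWxMS", config)
    files["cgmap_sperm"] = outdir / "sperm.cgmap.gz"
    write_cgmap(sperm, files["cgmap_sperm"], compress=True)

    qc_in = simulate_qc_inputs(manifest, config)
    files["depth"] = outdir / "depth.bedgraph"
    write_bedgraph(qc_in.track, files["depth"])
    files["reads"] = outdir / "reads.bed"
    write_bed(qc_in.reads, files["reads"])
    files["fasta"] = outdir / "targets.fasta"
    write_fasta_targets(manifest, qc_in.gc_by_target, config, files["fasta"])
    return files
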