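# Methods

## The signal being detected

A germline DMR at an imprinted locus is methylated on exactly one parental
allele. In bulk methyl-seq of a diploid somatic tissue the two alleles are
sampled together, so such a region appears as a cluster of CpGs with
aggregate methylation near 0.5 ("hemi-methylated"), flanked by the ordinary
bimodal background (CpG islands near 0, gene bodies and intergenic DNA near
1). The pipeline turns that observation into calls in three steps —
classify CpGs, cluster hemi CpGs into regions, split each region's
methylation by parental allele — and closes the loop with a gamete sample.

## Classification

Each CpG with depth `n_total >= min_depth` (default 20 reads) is classified
by its level β = n_meth / n_total (counts are authoritative; printed
fractions in input files are ignored when counts exist, which removes
rounding differences between CGmap and Bismark dialects):

| class | rule | default |
|---|---|---|
| HYPO | β < hypo_max | 0.3, strict |
| HYPER | β > hyper_min | 0.7, strict |
| HEMI | hemi_low ≤ β ≤ hemi_high | [0.4, 0.6], inclusive |
| INTERMEDIATE | the residue (0.3, 0.4) ∪ (0.6, 0.7) | |
| LOW_DEPTH | depth below min_depth, checked first | |

The three named bands deliberately do not tile [0, 1]; CpGs in the residue
are kept as an explicit class rather than dropped so the partition is
testable (class counts always sum to the number of CpG-context calls).
Strictness conventions are centralized in `classify_cpg`, so changing an
inclusivity decision is a one-line edit.

## Region calling

**hemiR100** (density): a window of `window_bp` = 100 bases is anchored at
every hemi CpG; a window holding ≥ `min_cpgs` = 5 hemi CpGs qualifies
(equivalently, a 5-CpG subset with span ≤ 99 bp — "within 100 bp" read as
fitting inside a 100-base window). CpG sets of overlapping qualifying
windows are unioned. The reported interval is the tight span of the
supporting CpGs (first CpG − 1 to last CpG, 0-based half-open), not the
window edges, because tight spans are reproducible and conservative.

**hemiR5** (consecutiveness): maximal runs of ≥ 5 hemi CpGs uninterrupted
by any other assayed, depth-passing CpG. Consecutiveness is judged over the
sample's own call set — without the reference genome there is no other
defensible notion of "consecutive CpGs". Each run is intersected with the
merged hemiR100 regions of the same input and sub-runs of ≥ 5 CpGs are
reported; this enforces the subset relation between the two definitions by
construction (a run of widely spaced hemi CpGs can satisfy consecutiveness
while failing the density criterion).

**Merging**: regions of one kind closer than the defining distance
(100 bp for hemiR100, 5 bp for hemiR5; strict inequality, distance =
next.start − prev.end) are merged transitively. The result is a fixed
point, and all surviving gaps are ≥ the threshold.

`brute_force_hemi_regions` re-derives hemiR100 calls by enumerating every
anchored window and unioning intersecting CpG sets to a fixed point; the
production scanner is required to match it exactly (boundaries and CpG
membership) on randomized inputs. A window anchored between two CpGs can
never hold more CpGs than one anchored at its first CpG, so per-CpG
anchoring loses nothing.

## Parent-of-origin phasing

The classical read-out of allele-specific methylation is manual
genome-browser inspection of reads that cover both an informative SNP and
the DMR. This package makes the decision rule explicit:

- **Informative SNPs.** A trio SNP is used iff the offspring is
  heterozygous and exactly one assignment of its two alleles to (sire, dam)
  is Mendelian-consistent. Double-heterozygous trios are excluded as
  ambiguous; Mendelian-inconsistent trios are flagged, counted, and never
  contribute. In a reciprocal cross between divergent lines most fixed
  differences qualify.
- **Allele routing.** Each read-level (SNP allele, CpG state) observation
  inside a region is routed to its parental allele; per-allele methylation
  is the methylated fraction of routed observations.
- **Verdict.** `paternal` if paternal-allele methylation ≥ 0.7 and
  maternal ≤ 0.3 (mirroring the CpG class thresholds); `maternal` for the
  mirror; `ambiguous` when both alleles are well observed but not
  separated; `uninformative` when either allele has < 10 observations.
  All three numbers are configurable (`PofOThresholds`); they are this
  package's formalization of a previously visual judgement, declared
  rather than fitted.

Swapping the sire and dam genotype columns flips every paternal↔maternal
verdict and swaps the per-allele summaries, changing nothing else — the
core symmetry of the reciprocal-cross design, enforced by test.

**Germline check.** Sperm carries the paternal complement: a paternally
methylated germline DMR must show mean sperm methylation ≥ 0.7
(`consistent`), a maternally methylated one ≤ 0.3. CpGs below the depth
filter are excluded; a region with no depth-passing sperm CpGs returns
`no_data`. Only sperm semantics are implemented (one gamete type suffices
to separate germline from somatic DMRs on the paternal side).

## Candidate annotation

CpGs are assigned to the candidate containing their position; regions by
their midpoint (candidates are kb–Mb scale, regions ~10²–10³ bp, so
midpoint assignment avoids edge double-counting). The panel must be
non-overlapping; off-panel items are tallied separately so totals are
conserved. Ranking: largest single hemi cluster, then total hemi CpGs,
then name — deterministic and order-invariant.

## Capture QC

Per-target efficiency (fraction of bases at depth ≥ d for configurable d,
default {1, 10, 20, 30, 50, 100}), homogeneity (mean and population SD of
per-base depth), off-target percentage (a read is on-target with ≥ 1 bp
overlap, the common capture convention; configurable in principle via the
interval index), Pearson GC–coverage and size–coverage correlations, and
conversion efficiency estimated as 1 − (CHH methylation rate), valid
because mammalian non-CpG methylation is near zero outside specific cell
types. All depth statistics are accumulated from integer base counts over
run-length-encoded tracks, so they are exact; bases absent from the track
are treated as *unobserved* rather than zero and flagged, not guessed.

## Synthetic studies

The generator emulates the structure of a reciprocal-cross capture
experiment at desk scale: 12 candidates of 5–50 kb on 2 chromosomes,
CpGs at ~25 bp mean spacing, 6 planted germline DMRs (half paternal, half
maternal) of 8–120 CpGs at 12–20 bp spacing (so ≥ 5 CpGs always fit one
100-bp window — every planted DMR is detectable at zero noise), 2
line-fixed SNPs per DMR, negative-binomial depth (mean 40, dispersion 5),
and a 20% off-target read fraction with a GC-biased on-target allocation.
Scale was chosen so a full study simulates in well under a second while
preserving every structural feature the pipeline exercises; a production
capture panel (a hundred-plus candidates, some Mb-sized) differs only in
count and length.

Noise model: background CpGs draw a true level from a beta distribution
centred on 0.03 (hypo, 30%) or 0.97 (hyper, 70%) with SD `meth_noise_sd`
(default 0.03), then binomial sampling given depth; a small fraction
(`background_hemi_rate`, default 1%) is hemi-like, emulating allele- and
strand-specific or stochastic intermediate methylation. DMR CpGs in blood
are emitted **per allele with balanced allele depths** (⌈d/2⌉ reads from
the methylated allele, ⌊d/2⌋ from the other, each read flipped with
probability `meth_noise_sd`): at zero noise the aggregate is exactly
⌈d/2⌉/d ∈ [0.4, 0.6], making zero-noise recovery a deterministic guarantee
rather than a high-probability event. The deliberate simplification is
that allelic sampling imbalance is not modelled — a Binomial(d, ½) allele
split would put ~15–25% of DMR CpGs outside the hemi band at depth 20–40
regardless of noise settings, conflating sampling depth with the noise
knob. Consequences: passing the clean-condition tests demonstrates
correctness of the calling logic, not robustness to allelic imbalance;
real data will show lower per-CpG hemi rates inside true DMRs than the
simulation at equal depth, mitigated by the region criteria needing only
5 of the cluster's CpGs.

Phased observations are generated balanced (half the reads per SNP from
each allele) with per-observation flip probability `meth_noise_sd`; founder
lines are fixed for alternate alleles, the maximally informative design.
Sperm DMR CpGs use the beta-binomial path around 0.98 / 0.02.

What the generator does *not* emulate: read sequences and alignment error,
bisulfite/enzymatic conversion chemistry differences, strand-split CpG
dyads (all calls are emitted on the + strand; the symmetric-dyad merger is
exercised on constructed inputs), copy-number variation, cell-type
heterogeneity, and somatic (non-germline) DMRs. Tests passing on synthetic
data therefore validate the algorithmic contracts, not performance on
tissue data.

Determinism: every stream derives from `(seed, stage-tag…)` via numpy's
seed-sequence spawning; gzip members are written with mtime 0; manifests
contain no timestamps or absolute paths. Identical seed and configuration
give byte-identical outputs, which the end-to-end test asserts.

## Numerical and degenerate-input choices

- Interval coordinates are 0-based half-open (BED); per-cytosine positions
  1-based (CGmap). Conversions happen only in the I/O layer.
- Bismark coverage carries no strand; it is recorded "+" with
  `strand_known=False`. No downstream stage uses strand.
- Symmetric-dyad merging is available but **off by default**: per-cytosine
  records are processed as-is, matching the standard CGmap workflow.
- Empty inputs: empty call files parse to empty lists; an empty read set or
  an uncovered target in QC is an error (a silent 0 or NaN would be read as
  a measurement); a region with no phased observations is `uninformative`,
  not an error.
- Merged-region mean methylation is the support-count-weighted mean;
  regions built from bare positions carry NaN and propagate it.
- Correlations require ≥ 3 targets; zero variance yields None, flagged
  rather than raised.

## Known limitations

- PofO thresholds (≥ 10 observations per allele, 0.7/0.3 separation) are
  declared defaults, not estimates from data; sensitivity to them is not
  profiled.
- hemiR100 boundaries and the span ≤ 99 bp window reading are one of two
  defensible conventions ("within 100 bp" could also mean span ≤ 100);
  the constant lives in one place and the oracle shares it.
- The scanner treats chromosomes independently and holds one chromosome's
  hemi positions in memory; panels are assumed panel-scale (≤ 10⁶ CpGs),
  not whole-genome.
- Duplication rate, insert size and other raw-read QC belong to upstream
  tools (they need FASTQ/BAM) and are intentionally absent.
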