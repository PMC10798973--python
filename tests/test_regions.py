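"""Region calling: window semantics, oracle agreement, merge rule, hemiR5."""

import numpy as np
import pytest

from imprintscan.classify import ClassifiedCpG, MethylationClass, ScanParameters
from imprintscan.errors import ValidationError
from imprintscan.regions import (
    HemiRegion,
    brute_force_hemi_regions,
    call_hemi_regions,
    merge_regions,
    read_region_table,
    scan_hemi_r100,
    scan_hemi_r5,
    write_region_table,
)

from conftest import make_call

C = MethylationClass


def classified(spec, start=100, step=20):
    """Build a single-chromosome classified track from class letters.

    'H' -> HEMI, 'o' -> HYPO, 'x' -> HYPER.
    """
    table = {"H": 0.5, "o": 0.0, "x": 1.0}
    out = []
    for i, ch in enumerate(spec):
        call = make_call(pos=start + i * step, meth=table[ch], n_total=30)
        klass = {"H": C.HEMI, "o": C.HYPO, "x": C.HYPER}[ch]
        out.append(ClassifiedCpG(call, klass))
    return out


class TestScanR100:
    def test_five_cpgs_within_window(self, params):
        (region,) = scan_hemi_r100("chr1", [100, 120, 140, 160, 180], params)
        assert region.n_hemi == 5 and (region.start, region.end) == (99, 180)

    def test_sparse_positions_yield_nothing(self, params):
        assert scan_hemi_r100("chr1", [100, 150, 200, 250, 300], params) == []

    def test_below_min_cpgs(self, params):
        assert scan_hemi_r100("chr1", [100, 120, 140, 160], params) == []

    def test_window_span_is_99_not_100(self, params):
        # span 99 fits a 100-base window; span 100 does not
        assert scan_hemi_r100("chr1", [100, 120, 140, 160, 199], params)
        assert scan_hemi_r100("chr1", [100, 120, 140, 160, 200], params) == []

    def test_duplicate_positions_rejected(self, params):
        with pytest.raises(ValidationError):
            scan_hemi_r100("chr1", [100, 100, 120, 140, 160], params)

    def test_oracle_equivalence_random(self, params):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(0, 51))
            pos = sorted(set(int(x) for x in rng.integers(1, 2001, size=n)))
            fast = merge_regions(scan_hemi_r100("chr", pos, params), params.merge_gap_r100)
            ref = brute_force_hemi_regions(pos, params)
            assert [(r.start, r.end, r.cpg_positions) for r in fast] == [
                (r.start, r.end, r.cpg_positions) for r in ref
            ]

    def test_adding_a_cpg_never_removes_a_region(self, params):
        rng = np.random.default_rng(7)
        for _ in range(100):
            pos = sorted(set(int(x) for x in rng.integers(1, 1500, size=30)))
            base = merge_regions(scan_hemi_r100("chr", pos, params), params.merge_gap_r100)
            extra = int(rng.integers(1, 1500))
            if extra in pos:
                continue
            grown = merge_regions(
                scan_hemi_r100("chr", sorted(pos + [extra]), params), params.merge_gap_r100
            )
            for r in base:
                assert any(set(r.cpg_positions) <= set(g.cpg_positions) for g in grown)


class TestMerge:
    def r(self, positions):
        return HemiRegion.from_positions("chr1", positions, "hemiR100")

    def test_close_regions_merge(self, params):
        a = self.r([101, 120, 140, 160, 200])
        b = self.r([250, 260, 270, 280, 290])  # distance 250-200=50 < 100
        (merged,) = merge_regions([a, b], params.merge_gap_r100)
        assert merged.n_hemi == 10 and (merged.start, merged.end) == (100, 290)

    def test_distance_exactly_gap_not_merged(self, params):
        a = self.r([101, 120, 140, 160, 200])
        b = self.r([301, 310, 320, 330, 340])  # distance 300-200=100, strict <
        assert len(merge_regions([a, b], 100)) == 2

    def test_single_region_unchanged(self, params):
        a = self.r([101, 120, 140, 160, 200])
        assert merge_regions([a], 100) == [a]

    def test_idempotent_and_gap_invariant(self, params):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pos = sorted(set(int(x) for x in rng.integers(1, 3000, size=40)))
            regions = scan_hemi_r100("chr", pos, params)
            merged = merge_regions(regions, params.merge_gap_r100)
            assert merge_regions(merged, params.merge_gap_r100) == merged
            for a, b in zip(merged, merged[1:]):
                assert b.start - a.end >= params.merge_gap_r100

    def test_mixed_kinds_rejected(self, params):
        a = self.r([101, 120, 140, 160, 200])
        b = HemiRegion.from_positions("chr1", [250, 260, 270, 280, 290], "hemiR5")
        with pytest.raises(ValidationError):
            merge_regions([a, b], 100)


class TestScanR5:
    def test_five_consecutive_hemi(self, params):
        (region,) = scan_hemi_r5(classified("HHHHH"), params)
        assert region.kind == "hemiR5" and region.n_hemi == 5

    def test_interrupted_run_rejected(self, params):
        assert scan_hemi_r5(classified("HHoHHH"), params) == []

    def test_wide_run_fails_density_criterion(self, params):
        # 5 consecutive hemi CpGs spanning 400 bp: no 100-bp window holds 5
        assert scan_hemi_r5(classified("HHHHH", step=100), params) == []

    def test_containment_in_hemir100(self, params):
        rng = np.random.default_rng(9)
        for _ in range(300):
            n = int(rng.integers(5, 50))
            pos = sorted(set(int(x) for x in rng.integers(1, 2001, size=n)))
            letters = rng.choice(list("HHox"), size=len(pos))
            cs = []
            for p, ch in zip(pos, letters):
                meth = {"H": 0.5, "o": 0.0, "x": 1.0}[ch]
                klass = {"H": C.HEMI, "o": C.HYPO, "x": C.HYPER}[ch]
                cs.append(ClassifiedCpG(make_call(pos=p, meth=meth, n_total=30), klass))
            hemi = [c.call.pos for c in cs if c.klass is C.HEMI]
            r100 = merge_regions(scan_hemi_r100("chr1", hemi, params), params.merge_gap_r100)
            r5 = merge_regions(scan_hemi_r5(cs, params), params.merge_gap_r5)
            for r in r5:
                assert any(h.start <= r.start and r.end <= h.end for h in r100)
                assert r.n_hemi >= params.min_cpgs

    def test_low_depth_input_rejected(self, params):
        cs = classified("HHHHH")
        bad = cs + [ClassifiedCpG(make_call(pos=999, n_meth=2, n_total=5), C.LOW_DEPTH)]
        with pytest.raises(ValidationError):
            scan_hemi_r5(bad, params)


class TestRegionTable:
    def test_round_trip(self, tmp_path, params):
        cs = classified("HHHHHoxHHHHH")
        regions = call_hemi_regions(cs, params)
        all_regions = regions["hemiR100"] + regions["hemiR5"]
        p = tmp_path / "regions.tsv"
        write_region_table(all_regions, p)
        back = read_region_table(p)
        assert sorted(back, key=lambda r: (r.kind, r.start)) == sorted(
            all_regions, key=lambda r: (r.kind, r.start)
        )
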