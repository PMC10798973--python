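"""Trio phasing, allele routing, PofO verdicts and the sperm germline check."""

import pytest

from imprintscan.errors import ValidationError
from imprintscan.phasing import (
    AlleleMethylation,
    PhasedObservation,
    PofOThresholds,
    TrioGenotypes,
    allele_methylation,
    call_pofo,
    germline_check,
    informative_snps,
    phase_regions,
    read_observation_table,
    read_trio_table,
)
from imprintscan.regions import HemiRegion

from conftest import make_call


def trio(snp_id, sire, dam, offspring, pos=500):
    return TrioGenotypes(snp_id, "chr1", pos, tuple(sire), tuple(dam), tuple(offspring))


REGION = HemiRegion.from_positions("chr1", [400, 420, 440, 460, 480], "hemiR100")


def obs(n_pat_meth, n_pat, n_mat_meth, n_mat, snp_pos=500, cpg_pos=440):
    """Observations at one SNP: A = paternal, G = maternal."""
    rows = []
    for i in range(n_pat):
        state = "methylated" if i < n_pat_meth else "unmethylated"
        rows.append(PhasedObservation(f"p{i}", "chr1", snp_pos, "A", cpg_pos, state))
    for i in range(n_mat):
        state = "methylated" if i < n_mat_meth else "unmethylated"
        rows.append(PhasedObservation(f"m{i}", "chr1", snp_pos, "G", cpg_pos, state))
    return rows


SNP_MAP = {("chr1", 500): {"A": "paternal", "G": "maternal"}}


class TestInformativeSNPs:
    def test_homozygous_parents_force_assignment(self):
        phasing = informative_snps([trio("s1", "AA", "GG", "AG")])
        assert phasing.allele_maps["s1"] == {"A": "paternal", "G": "maternal"}

    def test_double_heterozygous_is_uninformative(self):
        phasing = informative_snps([trio("s1", "AG", "AG", "AG")])
        assert "s1" not in phasing.allele_maps
        assert phasing.excluded["s1"] == "ambiguous_assignment"

    def test_one_het_parent_resolved_by_elimination(self):
        # A cannot come from a GG dam, so A must be paternal
        phasing = informative_snps([trio("s1", "AG", "GG", "AG")])
        assert phasing.allele_maps["s1"] == {"A": "paternal", "G": "maternal"}

    def test_homozygous_offspring_excluded(self):
        phasing = informative_snps([trio("s1", "AA", "AG", "AA")])
        assert phasing.excluded["s1"] == "offspring_homozygous"

    def test_mendelian_inconsistent_flagged_and_counted(self):
        phasing = informative_snps([trio("s1", "AA", "AA", "AG")])
        assert phasing.excluded["s1"] == "mendelian_inconsistent"
        assert phasing.n_inconsistent == 1

    def test_never_assigns_both_alleles_to_one_parent(self):
        import itertools

        bases = "AG"
        for sire in itertools.combinations_with_replacement(bases, 2):
            for dam in itertools.combinations_with_replacement(bases, 2):
                phasing = informative_snps([trio("s", sire, dam, "AG")])
                for amap in phasing.allele_maps.values():
                    assert set(amap.values()) == {"paternal", "maternal"}


class TestAlleleMethylation:
    def test_arithmetic_on_constructed_counts(self):
        am = allele_methylation(REGION, obs(48, 50, 1, 50), SNP_MAP)
        assert am.pat_meth == pytest.approx(0.96)
        assert am.mat_meth == pytest.approx(0.02)
        assert (am.n_obs_pat, am.n_obs_mat) == (50, 50)

    def test_no_observations(self):
        am = allele_methylation(REGION, [], SNP_MAP)
        assert am.pat_meth is None and am.mat_meth is None
        assert (am.n_obs_pat, am.n_obs_mat) == (0, 0)

    def test_single_allele_only(self):
        am = allele_methylation(REGION, obs(5, 5, 0, 0), SNP_MAP)
        assert am.n_obs_mat == 0 and am.pat_meth == 1.0

    def test_observation_outside_region_ignored(self):
        rows = obs(10, 10, 10, 10, cpg_pos=9999)
        am = allele_methylation(REGION, rows, SNP_MAP)
        assert am.n_obs_pat == am.n_obs_mat == 0

    def test_unmapped_allele_excluded_and_counted(self):
        rows = [PhasedObservation("r", "chr1", 500, "T", 440, "methylated")]
        am = allele_methylation(REGION, rows, SNP_MAP)
        assert am.n_excluded == 1 and am.n_obs_pat == 0


class TestCallPofO:
    def test_paternal_call(self):
        am = AlleleMethylation(0.96, 0.02, 50, 50)
        assert call_pofo(REGION, am).origin == "paternal"

    def test_no_separation_is_ambiguous(self):
        am = AlleleMethylation(0.50, 0.50, 50, 50)
        assert call_pofo(REGION, am).origin == "ambiguous"

    def test_insufficient_counts_uninformative(self):
        am = AlleleMethylation(0.96, 0.02, 3, 50)
        assert call_pofo(REGION, am).origin == "uninformative"

    def test_maternal_mirror(self):
        am = AlleleMethylation(0.04, 0.98, 30, 30)
        assert call_pofo(REGION, am).origin == "maternal"


class TestGermlineCheck:
    def sperm(self, level):
        return [make_call(pos=p, meth=level, n_total=50) for p in REGION.cpg_positions]

    def test_paternal_region_methylated_sperm_consistent(self):
        assert germline_check(REGION, self.sperm(0.96), "paternal") == "consistent"

    def test_maternal_region_unmethylated_sperm_consistent(self):
        assert germline_check(REGION, self.sperm(0.02), "maternal") == "consistent"

    def test_half_methylated_sperm_inconsistent(self):
        assert germline_check(REGION, self.sperm(0.5), "paternal") == "inconsistent"

    def test_low_depth_calls_are_no_data(self):
        calls = [make_call(pos=p, meth=0.9, n_total=5) for p in REGION.cpg_positions]
        assert germline_check(REGION, calls, "paternal") == "no_data"

    def test_unknown_origin_rejected(self):
        with pytest.raises(ValidationError):
            germline_check(REGION, self.sperm(0.9), "avuncular")


class TestReciprocalSymmetry:
    def test_swapping_parents_flips_every_call(self):
        """Swapping sire and dam genotypes must flip paternal<->maternal only."""
        trios = [trio("s1", "AA", "GG", "AG")]
        swapped = [trio("s1", "GG", "AA", "AG")]
        rows = obs(48, 50, 1, 50)
        (fwd,) = phase_regions([REGION], trios, rows)
        (rev,) = phase_regions([REGION], swapped, rows)
        assert fwd.origin == "paternal" and rev.origin == "maternal"
        assert (fwd.pat_meth, fwd.mat_meth) == (rev.mat_meth, rev.pat_meth)
        assert (fwd.n_obs_pat, fwd.n_obs_mat) == (rev.n_obs_mat, rev.n_obs_pat)


class TestTables:
    def test_trio_and_observation_round_trip(self, tmp_path):
        from imprintscan.simulate import write_observation_table, write_trio_table

        trios = [trio("s1", "AA", "GG", "AG")]
        rows = obs(2, 3, 1, 2)
        write_trio_table(trios, tmp_path / "t.tsv")
        write_observation_table(rows, tmp_path / "o.tsv")
        assert read_trio_table(tmp_path / "t.tsv") == trios
        assert read_observation_table(tmp_path / "o.tsv") == rows
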