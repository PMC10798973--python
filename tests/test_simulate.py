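"""Generator contracts: determinism, manifest invariants, emission semantics."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from imprintscan.classify import ScanParameters
from imprintscan.errors import ConfigError
from imprintscan.io import read_cgmap, write_cgmap
from imprintscan.simulate import (
    SimulationConfig,
    TruthManifest,
    simulate_all,
    simulate_cross,
    simulate_individual,
    simulate_panel,
)
from imprintscan.phasing import informative_snps


class TestConfig:
    def test_rate_bounds_enforced(self):
        with pytest.raises(ConfigError):
            SimulationConfig(background_hemi_rate=1.5)

    def test_too_few_dmr_cpgs_rejected(self):
        with pytest.raises(ConfigError, match="detectable"):
            SimulationConfig(dmr_n_cpgs=(3, 10))

    def test_candidates_must_fit_chromosome(self):
        with pytest.raises(ConfigError, match="fit"):
            simulate_panel(SimulationConfig(chromosome_length_bp=50_000))


class TestPanel:
    def test_candidates_non_overlapping_on_multiple_chroms(self, small_manifest):
        by_chrom = {}
        for c in small_manifest.candidates:
            by_chrom.setdefault(c.chrom, []).append(c)
        assert len(by_chrom) >= 2
        for cands in by_chrom.values():
            cands.sort(key=lambda c: c.start)
            for a, b in zip(cands, cands[1:]):
                assert a.end <= b.start

    def test_dmrs_inside_candidates_and_detectable(self, small_manifest):
        params = ScanParameters()
        cand_by_name = {c.name: c for c in small_manifest.candidates}
        for dmr in small_manifest.dmrs:
            host = cand_by_name[dmr.candidate]
            assert host.start <= dmr.interval.start and dmr.interval.end <= host.end
            # at least min_cpgs CpGs within one window span: guaranteed detectable
            pos = dmr.cpg_positions
            assert any(
                pos[i + params.min_cpgs - 1] - pos[i] <= params.window_bp - 1
                for i in range(len(pos) - params.min_cpgs + 1)
            )
            assert len(pos) >= params.min_cpgs

    def test_half_paternal_half_maternal(self, small_manifest):
        origins = [d.origin for d in small_manifest.dmrs]
        assert origins.count("paternal") == origins.count("maternal")

    def test_zero_dmrs_allowed(self):
        m = simulate_panel(SimulationConfig(seed=2, n_dmrs=0))
        assert m.dmrs == [] and m.snps == []

    def test_snps_do_not_collide_with_cpgs(self, small_manifest):
        cpgs = {
            (chrom, p)
            for chrom, ps in small_manifest.cpg_positions.items()
            for p in ps
        }
        for snp in small_manifest.snps:
            assert (snp.chrom, snp.pos) not in cpgs

    def test_manifest_json_round_trip(self, small_manifest, tmp_path):
        p = tmp_path / "truth.json"
        small_manifest.to_json(p)
        back = TruthManifest.from_json(p)
        assert back == small_manifest


class TestIndividual:
    def test_cgmap_round_trip_exact(self, small_manifest, small_config, tmp_path):
        calls = simulate_individual(small_manifest, "offspring_blood", "LWxMS", small_config)
        p = tmp_path / "x.cgmap.gz"
        write_cgmap(calls, p, compress=True)
        assert read_cgmap(p) == calls

    def test_sperm_reflects_paternal_germline(self, small_manifest, small_config):
        calls = simulate_individual(small_manifest, "sperm", "LWxMS", small_config)
        by_pos = {(c.chrom, c.pos): c for c in calls}
        for dmr in small_manifest.dmrs:
            levels = [
                by_pos[(dmr.interval.chrom, p)].meth_level for p in dmr.cpg_positions
            ]
            mean = float(np.mean(levels))
            if dmr.origin == "paternal":
                assert mean > 0.9
            else:
                assert mean < 0.1

    def test_offspring_dmr_levels_hemi_at_zero_noise(self, small_manifest, small_config):
        cfg = small_config.replace(meth_noise_sd=0.0, depth_floor=20)
        calls = simulate_individual(small_manifest, "offspring_blood", "LWxMS", cfg)
        by_pos = {(c.chrom, c.pos): c for c in calls}
        for dmr in small_manifest.dmrs:
            for p in dmr.cpg_positions:
                call = by_pos[(dmr.interval.chrom, p)]
                assert 0.4 <= call.meth_level <= 0.6
                # exactly the balanced-allele expectation ceil(d/2)/d
                assert call.n_meth == (call.n_total + 1) // 2

    def test_unknown_role_rejected(self, small_manifest, small_config):
        from imprintscan.errors import ValidationError

        with pytest.raises(ValidationError):
            simulate_individual(small_manifest, "liver", "LWxMS", small_config)


class TestCross:
    def test_every_snp_informative_by_construction(self, small_manifest, small_config):
        cross = simulate_cross(small_manifest, small_config)
        for offspring, trios in cross.trios.items():
            phasing = informative_snps(trios)
            assert len(phasing.allele_maps) == len(small_manifest.snps)
            assert not phasing.excluded

    def test_reciprocal_offspring_have_swapped_maps(self, small_manifest, small_config):
        cross = simulate_cross(small_manifest, small_config)
        (a, b) = cross.reciprocal_pairs()[0]
        map_a = informative_snps(cross.trios[a]).allele_maps
        map_b = informative_snps(cross.trios[b]).allele_maps
        for snp_id in map_a:
            assert map_a[snp_id] == {
                allele: ("paternal" if parent == "maternal" else "maternal")
                for allele, parent in map_b[snp_id].items()
            }

    def test_observation_states_follow_allele_origin(self, small_manifest, small_config):
        cfg = small_config.replace(meth_noise_sd=0.0)
        cross = simulate_cross(small_manifest, cfg)
        offspring = sorted(cross.direction)[0]
        phasing = informative_snps(cross.trios[offspring])
        origin = {d.name: d.origin for d in small_manifest.dmrs}
        pos_to_dmr = {}
        for d in small_manifest.dmrs:
            for p in d.cpg_positions:
                pos_to_dmr[(d.interval.chrom, p)] = d.name
        for obs in cross.observations[offspring]:
            parent = phasing.by_position[(obs.chrom, obs.snp_pos)][obs.allele]
            expected = parent == origin[pos_to_dmr[(obs.chrom, obs.cpg_pos)]]
            assert (obs.meth_state == "methylated") == expected


class TestDeterminismAndQC:
    def test_identical_seed_identical_bytes(self, tmp_path):
        cfg = SimulationConfig(
            seed=3, n_candidates=4, n_dmrs=2, candidate_size_bp=(5000, 9000), n_qc_reads=500
        )
        digests = []
        for sub in ("a", "b"):
            files = simulate_all(cfg, tmp_path / sub)
            digests.append(
                {p.name: hashlib.md5(p.read_bytes()).hexdigest() for p in sorted((tmp_path / sub).iterdir())}
            )
        assert digests[0] == digests[1]

    def test_depth_track_matches_read_pileup(self, small_manifest, small_config):
        from imprintscan.simulate import simulate_qc_inputs

        qc_in = simulate_qc_inputs(small_manifest, small_config)
        total_read_bases = sum(len(r) for r in qc_in.reads)
        assert qc_in.track.total_depth_sum() == total_read_bases

    def test_off_target_reads_truly_off_target(self, small_manifest, small_config):
        from imprintscan.qc import off_target_fraction
        from imprintscan.simulate import simulate_qc_inputs

        qc_in = simulate_qc_inputs(small_manifest, small_config)
        measured = off_target_fraction(qc_in.reads, small_manifest.candidates)
        n = small_config.n_qc_reads
        p = small_config.off_target_rate
        sd = 100 * np.sqrt(p * (1 - p) / n)
        assert abs(measured - 100 * p) < 3 * sd
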