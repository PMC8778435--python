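"""The synthetic cohort generator and its planted-truth guarantees."""

import numpy as np
import pytest

from prophagekit.seqio import (Feature, FeatureKind, GenomeRecord,
                               gc_fraction, reverse_complement)
from prophagekit.synthetic_data import (SimulationConfig, SyntheticTruth,
                                        derive_spacer, generate_cohort,
                                        mutate, plant_crispr_array,
                                        plant_prophage, random_dna,
                                        random_orf, scrub_motifs,
                                        simulate_depth)


class TestPrimitives:
    def test_random_dna_gc_tracks_target(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 50_000, 0.635)
        assert gc_fraction(seq) == pytest.approx(0.635, abs=0.01)

    def test_random_orf_is_stop_free(self):
        rng = np.random.default_rng(0)
        orf = random_orf(rng, 200, 0.62)
        assert orf.startswith("ATG") and orf.endswith("TAA")
        codons = [orf[i:i + 3] for i in range(3, len(orf) - 3, 3)]
        assert not {"TAA", "TAG", "TGA"} & set(codons)

    def test_mutate_respects_protection(self):
        rng = np.random.default_rng(0)
        seq = "A" * 1000
        out = mutate(seq, 0.5, rng, protected=[(100, 200)])
        assert out[100:200] == "A" * 100
        assert out != seq

    def test_scrub_removes_motif_both_orientations(self):
        rng = np.random.default_rng(0)
        motif = "TTCCGTAT"
        seq = "A" * 50 + motif + "C" * 50 + reverse_complement(motif) + "G" * 50
        out = scrub_motifs(seq, [motif], rng)
        assert motif not in out
        assert reverse_complement(motif) not in out

    def test_scrub_spares_protected(self):
        rng = np.random.default_rng(0)
        motif = "TTCCGTAT"
        seq = "A" * 10 + motif + "C" * 30
        out = scrub_motifs(seq, [motif], rng, protected=[(10, 18)])
        assert out[10:18] == motif

    def test_derive_spacer_exact_mismatch_count(self):
        rng = np.random.default_rng(3)
        proto = random_dna(rng, 34, 0.5)
        for m in (0, 1, 3, 4):
            spacer = derive_spacer(proto, m, rng)
            assert sum(a != b for a, b in zip(proto, spacer)) == m


class TestConfigValidation:
    def test_prophage_larger_than_genome(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, genome_length=10_000)

    def test_variable_sites_incompatible_with_identity_floor(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, n_variable_sites=20)

    def test_tr_length_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, tr_length=80)

    def test_induction_floor(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, induction_range=(0.5, 2.0))


class TestCohort:
    def test_deterministic_under_seed(self, cohort, default_config):
        genomes, truth = cohort
        genomes2, truth2 = generate_cohort(
            SimulationConfig(seed=default_config.seed))
        assert [g.sequence for g in genomes2] == \
            [g.sequence for g in genomes]
        assert truth2.to_json() == truth.to_json()

    def test_no_prophages_config_gives_empty_truth(self):
        cfg = SimulationConfig(seed=2, n_genomes=3, genome_length=60_000,
                               clade_sizes=(), n_core_genes=5,
                               n_accessory_genes=4, n_unique_genes=2)
        genomes, truth = generate_cohort(cfg)
        assert len(genomes) == 3
        assert truth.prophages == []
        assert truth.arrays == []

    def test_every_genome_has_all_trna_isotypes(self, cohort):
        genomes, _ = cohort
        for g in genomes:
            isotypes = {f.attributes["isotype"]
                        for f in g.features if f.kind == FeatureKind.tRNA}
            assert {"Leu", "Arg", "Ala", "Ser"} <= isotypes

    def test_att_cores_flank_every_prophage(self, cohort_genomes,
                                            cohort_truth):
        for p in cohort_truth.prophages:
            seq = cohort_genomes[p.genome_id].sequence
            la = len(p.att_core)
            assert seq[p.start - la:p.start] == p.att_core
            assert seq[p.end - la:p.end] == p.att_core

    def test_prophage_region_size_and_gc(self, cohort_genomes, cohort_truth,
                                         default_config):
        lo, hi = default_config.prophage_size_range
        glo, ghi = default_config.prophage_gc_range
        for p in cohort_truth.prophages:
            assert lo <= p.end - p.start <= hi
            gc = gc_fraction(
                cohort_genomes[p.genome_id].sequence[p.start:p.end])
            assert glo - 0.015 <= gc <= ghi + 0.015

    def test_spacer_truth_matches_protospacers(self, cohort_genomes,
                                               cohort_truth):
        for s in cohort_truth.spacers:
            if s.prophage_id is None:
                continue
            p = cohort_truth.prophage(s.prophage_id)
            seq = cohort_genomes[p.genome_id].sequence
            proto = seq[s.position[0]:s.position[1]]
            if s.strand == "-":
                proto = reverse_complement(proto)
            assert sum(a != b for a, b in zip(proto, s.sequence)) == \
                s.mismatches
            if s.pam:
                if s.strand == "+":
                    assert seq[s.position[0] - 3:s.position[0]] == "TCC"
                else:
                    assert reverse_complement(
                        seq[s.position[1]:s.position[1] + 3]) == "TCC"

    def test_dgr_truth_variable_sites_match_sequence(self, cohort_genomes,
                                                     cohort_truth):
        checked = 0
        for p in cohort_truth.prophages:
            if p.dgr is None:
                continue
            seq = cohort_genomes[p.genome_id].sequence
            tr = seq[p.dgr.tr[0]:p.dgr.tr[1]]
            vr = seq[p.dgr.vr[0]:p.dgr.vr[1]]
            diffs = [i for i, (a, b) in enumerate(zip(tr, vr)) if a != b]
            assert diffs == sorted(p.dgr.variable_sites)
            identity = 1 - len(diffs) / len(tr)
            assert identity > 0.90
            checked += 1
        assert checked >= 2

    def test_rix_motif_only_at_planted_sites(self, cohort_genomes,
                                             cohort_truth):
        from prophagekit.dgr_shufflon import find_rix_sites
        for p in cohort_truth.prophages:
            if p.shufflon is None:
                continue
            seq = cohort_genomes[p.genome_id].sequence[p.start:p.end]
            sites = find_rix_sites(seq)
            expect_direct = sorted(x - p.start
                                   for x in p.shufflon.rix_direct)
            expect_inverted = sorted(x - p.start
                                     for x in p.shufflon.rix_inverted)
            assert [x for x, o in sites if o == "direct"] == expect_direct
            assert [x for x, o in sites if o == "inverted"] == \
                expect_inverted

    def test_truth_json_roundtrip(self, cohort_truth, tmp_path):
        path = tmp_path / "truth.json"
        cohort_truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        assert back.to_json() == cohort_truth.to_json()


class TestPlantingOperations:
    def _host_with_trna(self):
        rng = np.random.default_rng(9)
        att = "CAACCCCATGGAGGTTCAAGTCCTCTCGCCCGCACCATCTGAA"
        left = random_dna(rng, 2000, 0.6)
        right = random_dna(rng, 2000, 0.6)
        trna_seq = random_dna(rng, 40, 0.55) + att
        genome = GenomeRecord(
            id="host", sequence=left + trna_seq + right,
            features=[Feature(kind=FeatureKind.tRNA, start=2000,
                              end=2000 + len(trna_seq),
                              attributes={"isotype": "Leu",
                                          "product": "tRNA-Leu"})])
        return genome, att, rng

    def test_plant_then_excise_restores_host(self):
        from prophagekit.activity_evidence import excise
        from prophagekit.prophage_finder import ProphageRegion
        genome, att, rng = self._host_with_trna()
        interior = random_dna(rng, 5000, 0.6)
        lysogen, region = plant_prophage(genome, interior, att,
                                         genome.features[0])
        assert len(lysogen) == len(genome) + len(interior) + len(att)
        pr = ProphageRegion(host_id="host", start=region[0], end=region[1],
                            complete=True, att_core=att)
        result = excise(lysogen, pr)
        assert result.restored_host.sequence == genome.sequence

    def test_plant_prophage_requires_att_at_trna(self):
        genome, _att, rng = self._host_with_trna()
        with pytest.raises(ValueError, match="att core"):
            plant_prophage(genome, "ACGT" * 100, "A" * 30,
                           genome.features[0])

    def test_plant_crispr_array_structure(self):
        rng = np.random.default_rng(4)
        genome = GenomeRecord(id="g", sequence=random_dna(rng, 5000, 0.5))
        repeat = random_dna(rng, 29, 0.5)
        spacers = [random_dna(rng, 34, 0.5) for _ in range(3)]
        planted, interval = plant_crispr_array(genome, 2500, repeat, spacers)
        body = planted.sequence[interval[0]:interval[1]]
        assert body == repeat + "".join(s + repeat for s in spacers)

    def test_plant_crispr_array_validation(self):
        genome = GenomeRecord(id="g", sequence="ACGT" * 1000)
        with pytest.raises(ValueError):
            plant_crispr_array(genome, 10, "ACGT" * 3, ["A" * 34] * 3)
        with pytest.raises(ValueError):
            plant_crispr_array(genome, 10, "ACGTACGTACGTACGTACGTACGTA",
                               ["A" * 34])


class TestDepth:
    def test_uniform_depth_ratio_one(self):
        from prophagekit.activity_evidence import coverage_ratio
        rng = np.random.default_rng(0)
        depth = simulate_depth(20_000, [(5000, 9000, 1.0)], 50.0, rng)
        assert coverage_ratio(depth, (5000, 9000)) == pytest.approx(
            1.0, abs=0.05)

    def test_induction_factor_reflected(self):
        from prophagekit.activity_evidence import coverage_ratio
        rng = np.random.default_rng(0)
        depth = simulate_depth(50_000, [(10_000, 20_000, 5.2)], 100.0, rng)
        ratio = coverage_ratio(depth, (10_000, 20_000))
        assert 4.5 <= ratio <= 6.0

    def test_factor_below_one_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_depth(1000, [(10, 20, 0.9)], 50.0, rng)
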