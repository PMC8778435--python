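"""CRISPR array detection, spacer matching and targeting summaries."""

import numpy as np
import pytest

from conftest import naive_hamming_hits, random_dna_str
from prophagekit.crispr_targeting import (MIN_BITSCORE, check_pam,
                                          dedup_spacers, detect_arrays,
                                          find_protospacers,
                                          ProtospacerHit, spacer_bitscore,
                                          targeting_matrix,
                                          unique_targeting_fraction)
from prophagekit.seqio import GenomeRecord, reverse_complement
from prophagekit.synthetic_data import scrub_motifs


class TestDetectArrays:
    def test_cohort_arrays_recovered_exactly(self, cohort_genomes,
                                             cohort_truth):
        truth_spacer = {s.spacer_id: s.sequence
                        for s in cohort_truth.spacers}
        found = {}
        for g in cohort_genomes.values():
            for arr in detect_arrays(g):
                found[(arr.genome_id, arr.start, arr.end)] = arr
        assert len(found) == len(cohort_truth.arrays)
        for ta in cohort_truth.arrays:
            arr = found[(ta.genome_id, ta.start, ta.end)]
            assert arr.repeat_consensus == ta.repeat
            assert arr.spacers == [truth_spacer[i] for i in ta.spacer_ids]

    def test_background_genome_has_no_arrays(self, cohort_genomes):
        assert detect_arrays(cohort_genomes["G00"]) == []

    def test_two_distant_arrays_detected_separately(self):
        rng = np.random.default_rng(5)
        repeat = random_dna_str(rng, 29)
        spacers = [random_dna_str(rng, 34) for _ in range(3)]
        body = repeat + "".join(s + repeat for s in spacers)
        background = scrub_motifs(random_dna_str(rng, 110_000), [repeat],
                                  rng)
        seq = background[:30_000] + body + background[30_000:80_000] \
            + body + background[80_000:]
        arrays = detect_arrays(GenomeRecord(id="g", sequence=seq))
        assert len(arrays) == 2
        assert all(a.spacers == spacers for a in arrays)

    def test_four_repeats_give_three_spacers(self):
        rng = np.random.default_rng(6)
        repeat = random_dna_str(rng, 29)
        spacers = [random_dna_str(rng, 34) for _ in range(3)]
        body = repeat + "".join(s + repeat for s in spacers)
        background = scrub_motifs(random_dna_str(rng, 4000), [repeat], rng)
        seq = background[:2000] + body + background[2000:]
        arrays = detect_arrays(GenomeRecord(id="g", sequence=seq))
        assert len(arrays) == 1
        assert arrays[0].n_repeats == 4
        assert len(arrays[0].spacers) == 3


class TestBitscore:
    def test_median_spacer_with_three_mismatches_is_the_cutoff(self):
        assert spacer_bitscore(34, 3) == pytest.approx(44.1, abs=0.05)
        assert spacer_bitscore(34, 3) >= MIN_BITSCORE

    def test_perfect_match_score(self):
        assert spacer_bitscore(34, 0) == pytest.approx(67.9, abs=0.05)

    def test_four_mismatches_fall_below_cutoff(self):
        assert spacer_bitscore(34, 4) == pytest.approx(36.2, abs=0.05)
        assert spacer_bitscore(34, 4) < MIN_BITSCORE

    def test_strictly_decreasing_in_mismatches(self):
        scores = [spacer_bitscore(34, m) for m in range(8)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_short_spacer_with_three_mismatches_needs_both_rules(self):
        # 26-nt spacer, 3 mismatches: allowed by the mismatch rule but
        # rejected by the bit-score rule
        assert spacer_bitscore(26, 3) < MIN_BITSCORE


class TestFindProtospacers:
    def test_planted_spacers_recovered(self, cohort_genomes, cohort_truth,
                                       prophage_sequences):
        spacers = {s.spacer_id: s.sequence for s in cohort_truth.spacers}
        hits = find_protospacers(spacers, prophage_sequences)
        indexed = {(h.spacer_id, h.prophage_id, h.start): h for h in hits}
        for s in cohort_truth.spacers:
            if s.prophage_id is None or s.mismatches > 3:
                continue
            key = (s.spacer_id, s.prophage_id, s.position_in_prophage[0])
            assert key in indexed
            hit = indexed[key]
            assert hit.mismatches == s.mismatches
            assert hit.strand == s.strand
            assert hit.pam_tcc == s.pam

    def test_four_mismatch_spacer_not_recovered_at_source(self,
                                                          cohort_truth,
                                                          prophage_sequences):
        over = [s for s in cohort_truth.spacers
                if s.mismatches is not None and s.mismatches > 3]
        assert over, "the cohort plants one beyond-rule spacer"
        for s in over:
            hits = find_protospacers({s.spacer_id: s.sequence},
                                     prophage_sequences)
            assert not any(h.prophage_id == s.prophage_id
                           and h.start == s.position_in_prophage[0]
                           for h in hits)

    def test_decoy_spacers_hit_nothing(self, cohort_truth,
                                       prophage_sequences):
        decoys = {s.spacer_id: s.sequence for s in cohort_truth.spacers
                  if s.prophage_id is None}
        assert decoys
        assert find_protospacers(decoys, prophage_sequences) == []

    def test_agrees_with_bruteforce_oracle_on_small_prophages(self):
        rng = np.random.default_rng(8)
        prophages = {f"p{i}": random_dna_str(rng, 4000) for i in range(3)}
        spacers = {}
        for i in range(6):
            src = prophages[f"p{i % 3}"]
            pos = int(rng.integers(0, len(src) - 34))
            probe = list(src[pos:pos + 34])
            for j in rng.choice(34, size=i % 5, replace=False):
                probe[j] = {"A": "C", "C": "G", "G": "T",
                            "T": "A"}[probe[j]]
            spacers[f"s{i}"] = "".join(probe)
        spacers["decoy"] = random_dna_str(rng, 34)
        hits = find_protospacers(spacers, prophages)
        expected = set()
        for sid, sp in spacers.items():
            for pid, seq in prophages.items():
                for strand, probe in (("+", sp),
                                      ("-", reverse_complement(sp))):
                    for pos, mm in naive_hamming_hits(probe, seq, 3):
                        if spacer_bitscore(len(sp), mm) >= MIN_BITSCORE:
                            expected.add((sid, pid, pos, strand, mm))
        got = {(h.spacer_id, h.prophage_id, h.start, h.strand,
                h.mismatches) for h in hits}
        assert got == expected
        assert expected  # the scenario actually produces hits

    def test_strand_symmetry(self):
        rng = np.random.default_rng(9)
        prophage = random_dna_str(rng, 3000)
        spacers = {"s": prophage[1000:1034]}
        fwd = find_protospacers(spacers, {"p": prophage})
        rev = find_protospacers(spacers,
                                {"p": reverse_complement(prophage)})
        assert len(fwd) == len(rev) == 1
        assert fwd[0].strand != rev[0].strand
        assert rev[0].start == len(prophage) - fwd[0].end


class TestPam:
    def _hit(self, start, end, strand="+"):
        return ProtospacerHit(spacer_id="s", prophage_id="p", start=start,
                              end=end, strand=strand, mismatches=0,
                              bitscore=67.9)

    def test_plus_strand_pam(self):
        seq = "AAAA" + "TCC" + "G" * 20 + "AAAA"
        assert check_pam(self._hit(7, 27), seq) is True

    def test_non_pam_context(self):
        seq = "AAAA" + "GGA" + "G" * 20 + "AAAA"
        assert check_pam(self._hit(7, 27), seq) is False

    def test_minus_strand_pam(self):
        # PAM 5' of the protospacer on the minus strand appears as GGA
        # immediately 3' of the interval on the plus strand
        seq = "AAAA" + "C" * 20 + "GGA" + "AAAA"
        assert check_pam(self._hit(4, 24, strand="-"), seq) is True

    def test_edge_flagged(self):
        hit = self._hit(1, 21)
        assert check_pam(hit, "A" * 30) is False
        assert hit.pam_edge


class TestSummaries:
    def test_dedup_counts_and_carriers(self, cohort_genomes, cohort_truth):
        arrays = []
        for g in cohort_genomes.values():
            arrays.extend(detect_arrays(g))
        unique, carriers, total = dedup_spacers(arrays)
        assert total == len(cohort_truth.spacers)
        assert len(unique) == len({s.sequence for s in cohort_truth.spacers})

    def test_shared_spacer_has_multiple_carriers(self):
        from prophagekit.crispr_targeting import SpacerArray
        arrays = [SpacerArray("g1", 0, 100, "R" * 29, ["A" * 34, "C" * 34]),
                  SpacerArray("g2", 0, 100, "R" * 29, ["A" * 34])]
        unique, carriers, total = dedup_spacers(arrays)
        assert total == 3
        assert len(unique) == 2
        shared = next(i for i, s in unique.items() if s == "A" * 34)
        assert carriers[shared] == ["g1", "g2"]

    def test_printed_unique_fraction(self):
        # 46 of 555 unique spacers target prophages -> 8.3%
        assert unique_targeting_fraction(46, 555) * 100 == pytest.approx(
            8.3, abs=0.05)

    def test_cohort_matrix_and_self_targeting(self, cohort_genomes,
                                              cohort_truth,
                                              prophage_sequences):
        arrays = []
        for g in cohort_genomes.values():
            arrays.extend(detect_arrays(g))
        unique, carriers, _total = dedup_spacers(arrays)
        hits = find_protospacers(unique, prophage_sequences)
        clade_of = {p.prophage_id: p.clade for p in cohort_truth.prophages}
        prophage_host = {p.prophage_id: p.genome_id
                         for p in cohort_truth.prophages}
        summary = targeting_matrix(
            hits, clade_of, carriers, sorted(cohort_genomes),
            prophage_host=prophage_host, n_unique_spacers=len(unique))
        matrix = summary["matrix"]
        # the planted self-targeting spacer (own prophage, PAM present)
        truth_self = [s for s in cohort_truth.spacers
                      if s.prophage_id is not None and s.pam
                      and s.array_genome ==
                      cohort_truth.prophage(s.prophage_id).genome_id]
        assert truth_self
        flagged = {(r["host"], r["prophage"]) for r in
                   summary["self_targeting"]}
        for s in truth_self:
            assert (s.array_genome, s.prophage_id) in flagged
        pam_flags = [r["pam_tcc"] for r in summary["self_targeting"]
                     if (r["host"], r["prophage"]) in
                     {(s.array_genome, s.prophage_id) for s in truth_self}]
        assert any(pam_flags)
        # every array host with planted targeting spacers shows counts
        for a in cohort_truth.arrays:
            planted = [s for s in cohort_truth.spacers
                       if s.array_genome == a.genome_id
                       and s.prophage_id is not None and s.mismatches <= 3]
            if planted:
                assert matrix.loc[a.genome_id].sum() > 0

    def test_empty_hits_zero_matrix(self):
        summary = targeting_matrix([], {"p": 1}, {}, ["g1"],
                                   n_unique_spacers=10)
        assert summary["matrix"].to_numpy().sum() == 0
        assert summary["unique_spacer_fraction"] == 0.0
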