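"""Scanner tests: folding-rule matches against brute-force enumeration."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from imotifkit import (
    MotifRule,
    SequenceRecord,
    count_vs_loopmax,
    decompose,
    expected_hits_iid,
    find_hits,
    revcomp,
    scan_fasta,
)

from conftest import random_dna
from oracles import admissible_placements, brute_find_hits

C5T3 = "CCCCC" + ("TTT" + "CCCCC") * 3  # 29 nt model sequence
DAP = "CCCCCGCCCCCGCCCCCGCCCCCGCCCCC"  # 29 nt genomic candidate


def rec(seq: str, name: str = "seq") -> SequenceRecord:
    return SequenceRecord(id=name, sequence=seq)


class TestRuleValidation:
    def test_defaults_encode_the_folding_rule(self):
        rule = MotifRule()
        assert (rule.base, rule.tract_len, rule.n_tracts, rule.loop_min,
                rule.loop_max) == ("C", 5, 4, 1, 19)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(loop_min=0), dict(tract_len=0), dict(n_tracts=1),
         dict(loop_min=5, loop_max=4), dict(base="A")],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MotifRule(**kwargs)


class TestFindHits:
    def test_model_sequence_single_full_span_hit(self):
        (hit,) = find_hits(rec(C5T3))
        assert (hit.start, hit.end) == (0, 29)
        assert hit.loop_lengths == (3, 3, 3)

    def test_no_cytosine_no_hits(self):
        assert find_hits(rec("A" * 29)) == []

    def test_all_c_loops_are_admissible(self):
        # 24 consecutive C: loops may themselves be cytosine
        (hit,) = find_hits(rec("C" * 24))
        assert hit.loop_lengths == (1, 1, 1)
        assert (hit.start, hit.end) == (0, 23)

    def test_dap_leftmost_minimal_loops(self):
        (hit,) = find_hits(rec(DAP))
        assert (hit.start, hit.end) == (0, 23)
        assert [s for s, _ in hit.tract_intervals] == [0, 6, 12, 18]
        assert hit.loop_lengths == (1, 1, 1)

    def test_trailing_tract_cannot_seed_second_hit(self):
        hits = find_hits(rec(DAP))
        assert len(hits) == 1  # the final C5 at [24,29) has no partners left

    def test_sequence_shorter_than_motif_is_empty_not_error(self):
        assert find_hits(rec("CCCCC")) == []

    def test_n_breaks_tracts_but_may_sit_in_loops(self):
        seq = "CCCCC" + "N" + ("CCCCC" + "N") * 2 + "CCCCC"
        (hit,) = find_hits(rec(seq))
        assert hit.loop_lengths == (1, 1, 1)
        assert find_hits(rec("CCNCC" + ("TCCCCC" * 3) + "T")) == []

    def test_matched_sequence_is_the_span(self):
        (hit,) = find_hits(rec(C5T3))
        assert hit.matched_sequence == C5T3

    def test_oracle_equivalence_on_random_sequences(self, c_rich_sequences,
                                                    default_rule):
        """Exact agreement with the exhaustive-enumeration oracle."""
        checked_hits = 0
        for record in c_rich_sequences:
            expected = brute_find_hits(record.sequence, default_rule)
            got = [(h.start, h.end, h.loop_lengths) for h in find_hits(record, default_rule)]
            assert got == expected
            checked_hits += len(got)
        assert checked_hits > 20  # the fixture must actually exercise matches

    def test_hit_geometry_invariant(self, c_rich_sequences, default_rule):
        for record in c_rich_sequences:
            for h in find_hits(record, default_rule):
                assert h.end - h.start == (
                    default_rule.n_tracts * default_rule.tract_len
                    + sum(h.loop_lengths)
                )
                assert all(
                    default_rule.loop_min <= l <= default_rule.loop_max
                    for l in h.loop_lengths
                )


class TestScanFasta:
    def test_g_run_motif_reported_on_minus_strand(self):
        motif = "GGGGGTGGGGGTGGGGGTGGGGG"
        seq = "A" * 100 + motif + "A" * 50
        hits = scan_fasta([rec(seq)], strands="both")
        assert len(hits) == 1
        (hit,) = hits
        assert (hit.start, hit.end, hit.strand) == (100, 123, "-")
        assert hit.matched_sequence == revcomp(motif)

    def test_empty_record_list(self):
        assert scan_fasta([], MotifRule()) == []

    def test_plus_only_ignores_g_runs(self):
        seq = "A" * 10 + "GGGGGTGGGGGTGGGGGTGGGGG" + "A" * 10
        assert scan_fasta([rec(seq)], strands="plus") == []

    def test_strand_mirror_symmetry(self, rng, default_rule):
        """Scanning S and revcomp(S) gives mirrored, strand-swapped hits."""
        probs = (0.15, 0.40, 0.25, 0.20)
        for _ in range(50):
            s = random_dna(rng, int(rng.integers(50, 200)), probs)
            fwd = scan_fasta([rec(s)], default_rule, strands="both")
            bwd = scan_fasta([rec(revcomp(s))], default_rule, strands="both")
            mirrored = sorted(
                (len(s) - h.end, len(s) - h.start, "+" if h.strand == "-" else "-")
                for h in bwd
            )
            assert sorted((h.start, h.end, h.strand) for h in fwd) == mirrored

    def test_recovers_planted_motifs_exactly(self):
        from imotifkit.simulate import PlantSpec, simulate_genome

        planted = [(PlantSpec(loop_lengths=(3, 5, 2)), "+")] * 5 + [
            (PlantSpec(loop_lengths=(1, 1, 1)), "-")
        ] * 5
        record, truth = simulate_genome(60_000, planted=planted, seed=7)
        hits = scan_fasta([record], strands="both")
        assert {(h.start, h.end, h.strand) for h in hits} == {
            (iv.start, iv.end, iv.strand) for iv in truth.intervals
        }


class TestDecompose:
    def test_model_sequence_strict(self):
        d = decompose(rec(C5T3))
        assert d.loop_lengths == (3, 3, 3)
        assert d.total_loop_length == 9
        assert not d.fallback_used

    def test_homopolymer_c24_strict_with_c_loops(self):
        d = decompose(rec("C" * 24, "ATXN2L"))
        assert d.tract_intervals == ((0, 5), (6, 11), (12, 17), (18, 23))
        assert d.loop_lengths == (1, 1, 1)
        assert not d.fallback_used

    def test_runx1_2_falls_back_to_longest_runs(self):
        seq = "CCCCCCTCCCCCTGCCTCTCCCTCCCCCCTTTCCCC"  # C-runs 6,5,2,1,3,6,4
        d = decompose(rec(seq, "RUNX1-2"))
        assert d.fallback_used
        assert [e - s for s, e in d.tract_intervals] == [6, 5, 6, 4]
        assert d.loop_lengths == (1, 11, 3)
        assert d.total_loop_length == 15

    def test_too_few_runs_is_undecomposable(self):
        with pytest.raises(ValueError, match="undecomposable"):
            decompose(rec("CCCCCTTTCCCCCTTTCC"))


class TestLoopMaxScaling:
    def test_counts_non_decreasing(self, c_rich_sequences):
        counts = count_vs_loopmax(c_rich_sequences, loopmax_values=[7, 13, 19])
        assert counts[7] <= counts[13] <= counts[19]

    def test_below_loop_min_rejected(self):
        with pytest.raises(ValueError, match="loop_max 0"):
            count_vs_loopmax([], MotifRule(), loopmax_values=[0])


class TestExpectedHits:
    def test_zero_tract_probability_zero_expectation(self):
        rule = MotifRule()
        assert expected_hits_iid(rule, (0.5, 0.0, 0.25, 0.25), 10_000) == 0.0

    def test_probabilities_must_be_valid(self):
        with pytest.raises(ValueError):
            expected_hits_iid(MotifRule(), (1.2, -0.2, 0.0, 0.0), 100)
        with pytest.raises(ValueError):
            expected_hits_iid(MotifRule(), (0.3, 0.3, 0.3, 0.3), 100)

    def test_exhaustive_enumeration_oracle(self):
        """Mean (start, loop-combination) match count over all 4^8 sequences
        equals the closed-form expectation for a miniature rule."""
        rule = MotifRule(base="C", tract_len=2, n_tracts=2, loop_min=1, loop_max=2)
        length = 8
        total = 0
        for tup in itertools.product("ACGT", repeat=length):
            total += len(admissible_placements("".join(tup), rule))
        mean = total / 4**length
        expected = expected_hits_iid(rule, (0.25,) * 4, length)
        assert expected == pytest.approx(mean, rel=1e-12)

    def test_cubic_law_doubling_ratio(self):
        rule_l = MotifRule(loop_max=64)
        rule_2l = MotifRule(loop_max=128)
        probs = (0.25,) * 4
        ratio = expected_hits_iid(rule_2l, probs, 10**7) / expected_hits_iid(
            rule_l, probs, 10**7
        )
        assert ratio == pytest.approx(8.0, rel=0.05)

    def test_loglog_slope_is_three(self):
        """Expectation grows as the cube of the loop range for 4 tracts."""
        loopmaxes = np.array([4, 8, 16, 32])
        e = np.array(
            [
                expected_hits_iid(MotifRule(loop_max=int(L)), (0.25,) * 4, 10**7)
                for L in loopmaxes
            ]
        )
        slope = np.polyfit(np.log(loopmaxes), np.log(e), 1)[0]
        assert slope == pytest.approx(3.0, abs=0.1)
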