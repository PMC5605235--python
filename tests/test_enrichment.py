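"""Promoter-window, overlap and enrichment-statistics tests."""

import numpy as np
import pytest

from imotifkit import (
    GenomicInterval,
    TssRecord,
    chance_expected_fraction,
    chi_squared_enrichment,
    genes_with_multiple_hits,
    go_enrichment,
    overlap_hits,
    promoter_windows,
    read_go_map,
    read_tss,
)

from oracles import bh_qvalues, brute_coverage_fraction, brute_overlap

SIZES = {"chr1": 1_000_000}


def window(start, end, name="g", chrom="chr1"):
    return GenomicInterval(chrom, start, end, name=name)


class TestPromoterWindows:
    def test_plus_strand_window_is_upstream(self):
        (w,) = promoter_windows(
            [TssRecord("g1", "chr1", 5000, "+")], 1000, SIZES
        )
        assert (w.start, w.end) == (4000, 5000)

    def test_minus_strand_window_is_downstream_in_coordinates(self):
        (w,) = promoter_windows(
            [TssRecord("g1", "chr1", 5000, "-")], 1000, SIZES
        )
        assert (w.start, w.end) == (5001, 6001)

    def test_clipping_at_chromosome_start(self):
        (w,) = promoter_windows(
            [TssRecord("g1", "chr1", 200, "+")], 1000, SIZES
        )
        assert (w.start, w.end) == (0, 200)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            promoter_windows([TssRecord("g1", "chrZ", 100, "+")], 1000, SIZES)

    def test_window_emptied_by_clipping_is_dropped(self):
        assert promoter_windows([TssRecord("g1", "chr1", 0, "+")], 1000, SIZES) == []


class TestOverlapHits:
    def test_single_bp_overlap_counts(self):
        n, per_gene = overlap_hits([window(100, 130, "hit")], [window(129, 1129, "g1")])
        assert n == 1 and per_gene == {"g1": 1}

    def test_half_open_adjacency_does_not_count(self):
        n, per_gene = overlap_hits([window(0, 20, "hit")], [window(20, 1020, "g1")])
        assert n == 0 and per_gene == {}

    def test_hit_spanning_two_windows_counts_once_but_touches_both(self):
        windows = [window(0, 1000, "g1"), window(990, 1990, "g2")]
        n, per_gene = overlap_hits([window(995, 1005, "hit")], windows)
        assert n == 1
        assert per_gene == {"g1": 1, "g2": 1}

    def test_matches_brute_force_on_random_fixture(self, rng):
        hits, windows = [], []
        for i in range(300):
            s = int(rng.integers(0, 50_000))
            hits.append(window(s, s + int(rng.integers(1, 40)), f"h{i}"))
        for j in range(80):
            s = int(rng.integers(0, 50_000))
            windows.append(window(s, s + 1000, f"g{j}"))
        assert overlap_hits(hits, windows) == brute_overlap(hits, windows)

    def test_multiple_hit_genes(self):
        assert genes_with_multiple_hits({"a": 1, "b": 2, "c": 5}) == 2
        assert genes_with_multiple_hits({}) == 0


class TestChanceFraction:
    def test_single_window_fraction(self):
        assert chance_expected_fraction([window(0, 1000)], {"chr1": 100_000}) == 0.01

    def test_duplicate_windows_union(self):
        ws = [window(500, 1500), window(500, 1500)]
        assert chance_expected_fraction(ws, {"chr1": 100_000}) == 0.01

    def test_zero_genome_length_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            chance_expected_fraction([window(0, 10)], {})

    def test_matches_per_base_oracle(self, rng):
        windows = []
        for j in range(50):
            s = int(rng.integers(0, 999_000))
            windows.append(window(s, s + 1000, f"g{j}"))
        got = chance_expected_fraction(windows, SIZES)
        assert got == pytest.approx(brute_coverage_fraction(windows, SIZES), abs=1e-12)


class TestChiSquared:
    def test_exact_expectation_gives_zero(self):
        res = chi_squared_enrichment(20, 100, 0.2)
        assert res.chi_squared == 0.0 and res.p_value == 1.0

    def test_hand_worked_example(self):
        # (30-20)^2/20 + (70-80)^2/80 = 5 + 1.25
        res = chi_squared_enrichment(30, 100, 0.2)
        assert res.chi_squared == pytest.approx(6.25)
        assert 0 < res.p_value < 0.05

    def test_invariant_under_cell_label_swap(self):
        a = chi_squared_enrichment(30, 100, 0.2)
        b = chi_squared_enrichment(70, 100, 0.8)
        assert a.chi_squared == pytest.approx(b.chi_squared)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_expected_fraction_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_enrichment(1, 10, 0.0)

    def test_small_expected_cell_warns_in_result(self):
        res = chi_squared_enrichment(1, 10, 0.01)
        assert res.warnings and "expected cell" in res.warnings[0]


class TestGoEnrichment:
    def _setup(self, rng, n_genes=500, term_sizes=(120, 150, 200), n_hit=60):
        genes = [f"g{i}" for i in range(n_genes)]
        go_map = {}
        for t, size in enumerate(term_sizes):
            for g in rng.choice(genes, size=size, replace=False):
                go_map.setdefault(str(g), set()).add(f"T{t}")
        hit = set(str(g) for g in rng.choice(genes, size=n_hit, replace=False))
        return hit, set(genes), go_map

    def test_min_genes_filter_excludes_small_terms(self, rng):
        hit, universe, go_map = self._setup(rng, term_sizes=(120, 80))
        results = go_enrichment(hit, universe, go_map, min_genes=100)
        assert [r.go_id for r in results] == ["T0"]

    def test_hit_genes_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            go_enrichment({"x"}, {"a"}, {}, min_genes=1)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            go_enrichment(set(), set(), {})

    def test_qvalues_match_textbook_bh(self, rng):
        hit, universe, go_map = self._setup(
            rng, term_sizes=(110, 120, 130, 140, 150), n_hit=80
        )
        results = go_enrichment(hit, universe, go_map, min_genes=100)
        by_term = {r.go_id: r for r in results}
        ps = [by_term[t].p_value for t in sorted(by_term)]
        qs = [by_term[t].q_value for t in sorted(by_term)]
        assert qs == pytest.approx(bh_qvalues(ps))

    def test_qvalues_monotone_in_p_and_bounded(self, rng):
        hit, universe, go_map = self._setup(
            rng, term_sizes=(110, 120, 130, 140, 150), n_hit=80
        )
        results = go_enrichment(hit, universe, go_map, min_genes=100)
        ordered = sorted(results, key=lambda r: r.p_value)
        qs = [r.q_value for r in ordered]
        assert all(q1 <= q2 + 1e-15 for q1, q2 in zip(qs, qs[1:]))
        assert all(0 <= q <= 1 for q in qs)
        assert all(r.q_value >= r.p_value - 1e-15 for r in results)

    def test_enriched_direction_when_hits_concentrated(self, rng):
        genes = [f"g{i}" for i in range(400)]
        term_members = genes[:120]
        go_map = {g: {"T0"} for g in term_members}
        hit = set(term_members[:50]) | set(genes[300:310])
        (res,) = go_enrichment(hit, set(genes), go_map, min_genes=100)
        assert res.direction == "enriched"
        assert res.q_value < 0.05


class TestEndToEndEnrichment:
    def test_promoter_planted_motifs_detected_as_enriched(self):
        """Motifs planted overwhelmingly inside promoter windows come out
        significant (p < 0.01) in >= 95% of 100 seeded replicates."""
        from imotifkit import scan_fasta
        from imotifkit.simulate import PlantSpec, simulate_genome

        genome_length = 400_000
        significant = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            planted = [(PlantSpec(), "+")] * 8
            record, truth = simulate_genome(
                genome_length, planted=planted, seed=seed
            )
            tss = []
            for j, iv in enumerate(truth.intervals):
                if rng.random() < 0.9:  # ~10x preference for promoters
                    tss.append(TssRecord(f"planted_{j}", record.id, iv.end, "+"))
            for j in range(30):
                tss.append(
                    TssRecord(
                        f"decoy_{j}", record.id,
                        int(rng.integers(1000, genome_length)), "+",
                    )
                )
            windows = promoter_windows(
                tss, 1000, {record.id: genome_length}
            )
            hits = [
                GenomicInterval(h.source_id, h.start, h.end, name="hit")
                for h in scan_fasta([record], strands="both")
            ]
            observed, _ = overlap_hits(hits, windows)
            fraction = chance_expected_fraction(windows, {record.id: genome_length})
            res = chi_squared_enrichment(observed, len(hits), fraction)
            if res.p_value < 0.01:
                significant += 1
        assert significant >= 95


class TestAnnotationReaders:
    def test_read_tss_converts_to_zero_based(self, tmp_path):
        p = tmp_path / "tss.tsv"
        p.write_text(
            "gene_id\tchrom\ttss_position_1based\tstrand\n"
            "g1\tchr1\t5001\t+\n"
        )
        (rec,) = read_tss(p)
        assert rec.tss == 5000 and rec.strand == "+"

    def test_read_go_map_groups_terms(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text("gene_id\tgo_id\ng1\tGO:1\ng1\tGO:2\ng2\tGO:1\n")
        assert read_go_map(p) == {"g1": {"GO:1", "GO:2"}, "g2": {"GO:1"}}
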