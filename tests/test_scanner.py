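"""Both-strand scanning, composite pairing, affinity, and clustering."""

import numpy as np
import pytest

from myrfscan import (
    ConsensusModel,
    classify_affinity,
    pair_composites,
    scan_heptamers,
    scan_region,
)
from myrfscan.motif import MotifMatch, reverse_complement
from myrfscan.panel import build_oligo
from myrfscan.simulate import generate_background

from conftest import naive_scan, random_dna


def as_triples(matches):
    return {(m.start, m.strand, m.mismatch_positions) for m in matches}


def consensus_pair(spacer: int, second_strand: str = "+") -> list[MotifMatch]:
    """Two perfect-consensus matches with the given spacer, hand-built."""
    a = MotifMatch("seq", 0, "+", (), 0.0)
    b = MotifMatch("seq", 7 + spacer, second_strand, (), 0.0)
    return [a, b]


class TestScanHeptamers:
    def test_motif_free_background_is_empty(self, model):
        seq = generate_background(40, seed=11, model=model)
        assert scan_heptamers(seq, model) == []

    def test_short_sequence_yields_empty_list(self, model):
        assert scan_heptamers("ACG", model) == []

    def test_planted_pair_centers_ten_apart(self, model):
        oligo = build_oligo("(c)3(c)", model)
        matches = [m for m in scan_heptamers(oligo.sequence, model) if m.strand == "+"]
        assert len(matches) == 2
        assert matches[1].center - matches[0].center == 10

    def test_minus_strand_reported_in_forward_coordinates(self, model):
        seq = "AATTAATT" + reverse_complement("CTGGCAC") + "AATTAATT"
        matches = scan_heptamers(seq, model)
        minus = [m for m in matches if m.strand == "-" and not m.mismatch_positions]
        assert any(m.start == 8 for m in minus)

    def test_n_counts_as_universal_mismatch(self, model):
        assert any(
            m.mismatch_positions == (5,)
            for m in scan_heptamers("CTGGNAC", model)
        )
        assert scan_heptamers("NNNNNNN", model) == []

    @pytest.mark.parametrize("budget", [0, 1, 2])
    def test_oracle_equivalence_random_sequences(self, rng, budget):
        """Exact agreement with a naive all-windows enumeration."""
        model = ConsensusModel(max_total_mismatches=budget)
        for _ in range(25):
            seq = random_dna(rng, int(rng.integers(7, 400)))
            assert as_triples(scan_heptamers(seq, model)) == naive_scan(seq, budget=budget)

    def test_sorted_by_start(self, rng, model):
        seq = random_dna(rng, 1000)
        starts = [m.start for m in scan_heptamers(seq, model)]
        assert starts == sorted(starts)


class TestPairComposites:
    def test_one_turn_head_to_tail(self, model):
        sites = pair_composites(consensus_pair(3), model, mode="candidate")
        assert len(sites) == 1
        site = sites[0]
        assert (site.spacing_class, site.orientation_class) == ("one_turn", "head_to_tail")
        assert site.center_distance == 10
        assert site.affinity_class == "strong"

    def test_two_turns_never_pairs(self, model):
        for mode in ("candidate", "high_affinity"):
            assert pair_composites(consensus_pair(13), model, mode=mode) == []

    def test_one_and_a_half_turns_head_to_head(self, model):
        sites = pair_composites(consensus_pair(7, second_strand="-"), model, mode="candidate")
        assert len(sites) == 1
        assert sites[0].spacing_class == "one_and_a_half_turns"
        assert sites[0].orientation_class == "head_to_head"

    def test_candidate_admits_off_phase_high_affinity_does_not(self, model):
        for spacer in (4, 5, 6, 8):
            assert len(pair_composites(consensus_pair(spacer), model, "candidate")) == 1
            assert pair_composites(consensus_pair(spacer), model, "high_affinity") == []

    def test_tail_to_tail_flagged_untested(self, model):
        a = MotifMatch("seq", 0, "-", (), 0.0)
        b = MotifMatch("seq", 10, "+", (), 0.0)
        sites = pair_composites([a, b], model, "candidate")
        assert sites[0].orientation_class == "tail_to_tail"
        assert "untested_orientation" in sites[0].flags

    def test_mismatch_budget_is_summed_over_both_heptamers(self, model):
        a = MotifMatch("seq", 0, "+", (2, 3), model.penalty_of((2, 3)))
        b = MotifMatch("seq", 10, "+", (4,), model.penalty_of((4,)))
        assert pair_composites([a, b], model, "candidate") == []

    def test_mixed_sequence_ids_error(self, model):
        a = MotifMatch("s1", 0, "+", (), 0.0)
        b = MotifMatch("s2", 10, "+", (), 0.0)
        with pytest.raises(ValueError, match="multiple sequences"):
            pair_composites([a, b], model)


class TestClassifyAffinity:
    @pytest.mark.parametrize(
        "spacer, positions, expected",
        [
            (3, (), "strong"),            # perfect (c)3(c)
            (3, (7,), "none"),            # position 7 is disqualifying
            (3, (4, 4), "weak"),          # two position-4 changes retain binding
            (3, (4,), "strong"),          # position 4 alone: no major effect
            (3, (1,), "weak"),
            (3, (4, 1), "weak"),
            (3, (4, 2), "none"),
            (5, (), "none"),              # off-phase spacing beats any penalty
            (7, (), "strong"),
        ],
    )
    def test_affinity_rules(self, model, spacer, positions, expected):
        penalty = model.penalty_of(positions)
        assert classify_affinity(spacer, model, penalty) == expected

    def test_monotone_in_mismatches(self, model):
        """An extra mismatch in either heptamer never improves the class."""
        rank = {"none": 0, "weak": 1, "strong": 2}
        for spacer in (3, 7):
            for base in [(), (1,), (4,), (4, 4)]:
                current = classify_affinity(spacer, model, model.penalty_of(base))
                for extra in range(1, 8):
                    worse = model.penalty_of(tuple(base) + (extra,))
                    assert rank[classify_affinity(spacer, model, worse)] <= rank[current]


class TestScanRegion:
    def test_three_in_phase_motifs_one_cluster(self, model):
        oligo = build_oligo("(c)3(c)3(c)", model)
        result = scan_region(oligo.sequence, model)
        assert len(result.matches) == 3
        assert len(result.sites) == 2
        assert len(result.clusters) == 1
        cluster = result.clusters[0]
        assert cluster.affinity_class == "strong"
        # max-scoring combination: same score as a single perfect pair
        pair = scan_region(build_oligo("(c)3(c)", model).sequence, model)
        assert cluster.score == pair.clusters[0].score

    def test_motif_free_background_empty_at_every_level(self, model):
        seq = generate_background(200, seed=5, model=model)
        result = scan_region(seq, model)
        assert result.matches == result.sites == result.clusters == ()

    def test_planted_cassette_recovered_at_offset(self, model):
        from myrfscan.simulate import _plant
        background = generate_background(300, seed=9, model=model)
        seq, planted = _plant(background, "(c)3(c)", 120, model, seed=9)
        result = scan_region(seq, model)
        assert len(result.clusters) == 1
        assert result.clusters[0].affinity_class == "strong"
        assert result.clusters[0].start == planted[0][0]
        assert abs(planted[0][0] - 120) <= 10  # planted at the requested offset

    def test_strand_symmetry(self, rng, model):
        """Scanning the reverse complement mirrors coordinates and strands."""
        for _ in range(10):
            seq = random_dna(rng, 300)
            fwd = scan_region(seq, model)
            rev = scan_region(reverse_complement(seq), model)
            n = len(seq)
            mirrored = {
                (n - m.end, "-" if m.strand == "+" else "+", m.mismatch_positions)
                for m in fwd.matches
            }
            assert {(m.start, m.strand, m.mismatch_positions) for m in rev.matches} == mirrored
            assert sorted(s.affinity_class for s in fwd.sites) == sorted(
                s.affinity_class for s in rev.sites
            )
            assert sorted(c.affinity_class for c in fwd.clusters) == sorted(
                c.affinity_class for c in rev.clusters
            )

    def test_extra_in_phase_motif_never_changes_cluster_class(self, model):
        for spec, extended in [("(c)3(c)", "(c)3(c)3(c)"), ("(c)7(c)", "(c)7(c)3(c)")]:
            short = scan_region(build_oligo(spec, model).sequence, model)
            longer = scan_region(build_oligo(extended, model).sequence, model)
            assert len(longer.clusters) == len(short.clusters) == 1
            assert longer.clusters[0].affinity_class == short.clusters[0].affinity_class
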