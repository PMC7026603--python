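"""Target-gene triage set algebra and the quantification helpers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myrfscan import (
    DeTable,
    PeakGeneTable,
    StageLists,
    chip_enrichment,
    fold_induction,
    intersect_targets,
    normalize_to_max,
    stage_classify,
)
from myrfscan.triage import assign_nearest_gene


def de_table(rows):
    return DeTable(pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue"]))


def peak_table(gene_ids):
    return PeakGeneTable(
        pd.DataFrame(
            [
                {"gene_id": g, "peak_id": f"p{i}", "chrom": "chr1",
                 "start": 100 * i, "end": 100 * i + 50}
                for i, g in enumerate(gene_ids)
            ],
            columns=["gene_id", "peak_id", "chrom", "start", "end"],
        )
    )


TOY_DE = [
    ("gA", -2.0, 0.01),   # passes, has peak
    ("gB", -1.5, 0.04),   # passes, has peak
    ("gC", -3.0, 0.001),  # passes, no peak
    ("gD", -0.5, 0.01),   # fails fold change
    ("gE", -2.0, 0.20),   # fails p-value
    ("gF", 1.0, 0.90),    # fails both
]


class TestIntersectTargets:
    def test_toy_table_brute_force(self):
        """Six genes, three pass the DE filter, two of those are peak-associated."""
        de = de_table(TOY_DE)
        peaks = peak_table(["gA", "gB", "gF"])
        result = intersect_targets(de, peaks)
        expected_pass = {g for g, lfc, p in TOY_DE if lfc <= -1.0 and p <= 0.05}
        assert result.candidates == expected_pass & {"gA", "gB", "gF"} == {"gA", "gB"}
        assert result.venn == (1, 1, 2)  # gC | gF | gA,gB

    def test_empty_de_table(self):
        result = intersect_targets(de_table([]), peak_table(["gA"]))
        assert result.candidates == frozenset() and result.overlap == 0

    def test_matches_naive_set_comprehension(self, rng):
        genes = [f"g{i}" for i in range(200)]
        rows = [
            (g, float(rng.uniform(-4, 2)), float(rng.uniform(0, 1))) for g in genes
        ]
        with_peaks = [g for g in genes if rng.random() < 0.4]
        result = intersect_targets(de_table(rows), peak_table(with_peaks))
        naive = {
            g for g, lfc, p in rows
            if lfc <= -math.log2(2.0) and p <= 0.05 and g in set(with_peaks)
        }
        assert result.candidates == naive

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            de_table([("gA", -2, 0.01), ("gA", -3, 0.02)])

    def test_malformed_peak_interval_rejected(self):
        with pytest.raises(ValueError, match="start >= end"):
            PeakGeneTable(
                pd.DataFrame(
                    [{"gene_id": "g", "peak_id": "p", "chrom": "chr1",
                      "start": 50, "end": 50}]
                )
            )


class TestStageClassify:
    def test_partition_property(self):
        candidates = {f"g{i}" for i in range(30)}
        stages = StageLists(
            opc_enriched=frozenset({"g0", "g1", "g2", "gX"}),
            ol_enriched=frozenset({"g3", "g4"}),
        )
        part = stage_classify(candidates, stages)
        assert part.opc_specific == {"g0", "g1", "g2"}
        assert part.ol_specific == {"g3", "g4"}
        assert part.opc_specific | part.ol_specific | part.unchanged == candidates
        assert not (part.opc_specific & part.ol_specific)
        assert not (part.unchanged & (part.opc_specific | part.ol_specific))

    def test_candidates_disjoint_from_lists_all_unchanged(self):
        stages = StageLists(frozenset({"x"}), frozenset({"y"}))
        part = stage_classify({"a", "b"}, stages)
        assert part.counts == (0, 0, 2)

    def test_single_gene_in_opc_list(self):
        stages = StageLists(frozenset({"g"}), frozenset())
        part = stage_classify({"g"}, stages)
        assert (part.opc_specific, part.ol_specific, part.unchanged) == (
            frozenset({"g"}), frozenset(), frozenset()
        )

    def test_overlapping_stage_lists_rejected(self):
        with pytest.raises(ValueError, match="both stage lists"):
            StageLists(frozenset({"g"}), frozenset({"g"}))

    def test_none_candidates_rejected(self):
        with pytest.raises(ValueError):
            stage_classify(None, StageLists(frozenset(), frozenset()))


class TestChipEnrichment:
    def test_equal_adjusted_cycles_give_100_percent(self):
        assert chip_enrichment(20.0, 20.0, input_fraction=1.0) == pytest.approx(100.0)

    def test_one_extra_ip_cycle_halves_recovery(self):
        assert chip_enrichment(21.0, 20.0) == pytest.approx(50.0)

    def test_input_fraction_correction(self):
        # 10% input: the input Ct understates total chromatin by log2(10) cycles
        full = chip_enrichment(20.0, 20.0, input_fraction=1.0)
        tenth = chip_enrichment(20.0, 20.0 + math.log2(10), input_fraction=0.1)
        assert tenth == pytest.approx(full)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        ct_ip=st.floats(5, 35),
        ct_input=st.floats(5, 35),
        delta=st.floats(0.1, 5),
    )
    def test_strictly_decreasing_in_ip_cycles(self, ct_ip, ct_input, delta):
        assert chip_enrichment(ct_ip + delta, ct_input) < chip_enrichment(ct_ip, ct_input)

    def test_scales_with_input_cycles(self):
        assert chip_enrichment(20, 21) == pytest.approx(2 * chip_enrichment(20, 20))

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_invalid_input_fraction(self, bad):
        with pytest.raises(ValueError):
            chip_enrichment(20, 20, input_fraction=bad)

    def test_normalize_to_max(self):
        out = normalize_to_max([2.0, 5.0, 10.0])
        assert out == pytest.approx([0.2, 0.5, 1.0])
        assert normalize_to_max([7.0]).max() == 1.0


class TestFoldInduction:
    def test_identical_conditions_give_exactly_one(self):
        result = fold_induction([5.0, 7.0, 6.0], [5.0, 7.0, 6.0])
        assert result.mean == 1.0 and result.sem == 0.0

    def test_mean_of_ratios(self):
        result = fold_induction([12.0, 14.0, 13.0], [1.0, 1.0, 1.0])
        assert result.mean == pytest.approx(13.0)
        assert result.sem == pytest.approx(np.std([12, 14, 13], ddof=1) / math.sqrt(3))

    def test_single_replicate_sem_undefined(self):
        result = fold_induction([10.0], [2.0])
        assert result.mean == 5.0 and math.isnan(result.sem)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fold_induction([1.0], [0.0])


class TestNearestGeneAssigner:
    def test_assigns_nearest_tss_per_chromosome(self):
        peaks = pd.DataFrame(
            [
                {"peak_id": "p1", "chrom": "chr1", "start": 900, "end": 1100},
                {"peak_id": "p2", "chrom": "chr1", "start": 5000, "end": 5200},
                {"peak_id": "p3", "chrom": "chr2", "start": 100, "end": 300},
            ]
        )
        tss = pd.DataFrame(
            [
                {"gene_id": "gA", "chrom": "chr1", "pos": 1000},
                {"gene_id": "gB", "chrom": "chr1", "pos": 6000},
                {"gene_id": "gC", "chrom": "chr2", "pos": 150},
            ]
        )
        table = assign_nearest_gene(peaks, tss)
        pairs = set(zip(table.frame["peak_id"], table.frame["gene_id"]))
        assert pairs == {("p1", "gA"), ("p2", "gB"), ("p3", "gC")}
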