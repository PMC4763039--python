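"""Comparative banding-pattern classes A-P and event-group summaries."""

import itertools

import pytest

from msapkit.core import BandMatrix, BandMatrixError, LanePresence
from msapkit.datasets import comparison_band_matrix, pattern_class_counts
from msapkit.patterns import (
    GROUPS,
    PATTERN_BITS,
    PATTERN_GROUP,
    ComparisonSummary,
    classify_pair,
    event_counts_table,
    summarize_comparison,
)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "control, treatment, code, group",
        [
            ((1, 1), (1, 1), "A", "no_change"),      # (msp, hpa) per sample
            ((0, 0), (1, 1), "G", "demethylation"),
            ((1, 1), (0, 1), "K", "methylation"),
        ],
    )
    def test_printed_examples(self, control, treatment, code, group):
        cls = classify_pair(
            LanePresence(hpa=control[1], msp=control[0]),
            LanePresence(hpa=treatment[1], msp=treatment[0]),
        )
        assert (cls.code, cls.group) == (code, group)

    def test_all_16_tuples_hit_each_class_once(self):
        seen = {}
        for c_msp, c_hpa, t_msp, t_hpa in itertools.product((0, 1), repeat=4):
            cls = classify_pair(LanePresence(c_hpa, c_msp), LanePresence(t_hpa, t_msp))
            assert cls.bits == (c_msp, c_hpa, t_msp, t_hpa)
            seen[cls.code] = cls.group
        assert sorted(seen) == [chr(ord("A") + i) for i in range(16)]
        group_sizes = {g: sum(1 for v in seen.values() if v == g) for g in GROUPS}
        assert group_sizes == {"no_change": 4, "demethylation": 6, "methylation": 6}

    def test_identical_patterns_are_exactly_the_no_change_diagonal(self):
        for msp, hpa in itertools.product((0, 1), repeat=2):
            p = LanePresence(hpa, msp)
            assert classify_pair(p, p).group == "no_change"
        diagonal = {bits for code, bits in PATTERN_BITS.items() if code in "ABCD"}
        assert diagonal == {(m, h, m, h) for m, h in itertools.product((0, 1), repeat=2)}

    def test_swapping_samples_is_the_event_involution(self):
        """Exchanging control and treatment maps each demethylation class
        to its methylation partner and vice versa (E-K, F-L, G-N, H-M,
        I-O, J-P), and fixes the no-change classes."""
        pairs = {"E": "K", "F": "L", "G": "N", "H": "M", "I": "O", "J": "P"}
        for code, bits in PATTERN_BITS.items():
            swapped = (bits[2], bits[3], bits[0], bits[1])
            partner = next(c for c, b in PATTERN_BITS.items() if b == swapped)
            if code in pairs:
                assert partner == pairs[code]
            elif code in pairs.values():
                assert pairs[partner] == code
            else:
                assert partner == code


class TestComparisonSummary:
    def test_dormant_bud_comparison_matches_printed_groups(self):
        counts = pattern_class_counts()["DBL-vs-DBH"].to_dict()
        summary = ComparisonSummary.from_class_counts("DBH", "DBL", counts)
        assert summary.n_total == 602
        assert summary.n_group == {"no_change": 561, "demethylation": 39, "methylation": 2}
        assert summary.pct_group_rounded() == {
            "no_change": 93.2, "demethylation": 6.5, "methylation": 0.3,
        }

    def test_fruit_set_comparison_matches_printed_groups(self):
        counts = pattern_class_counts()["FSL-vs-FSH"].to_dict()
        summary = ComparisonSummary.from_class_counts("FSH", "FSL", counts)
        assert summary.n_group == {"no_change": 507, "demethylation": 15, "methylation": 18}
        assert summary.pct_group_rounded() == {
            "no_change": 93.9, "demethylation": 2.8, "methylation": 3.3,
        }

    def test_matrix_expansion_roundtrip(self):
        """Expanding class counts to a band matrix and re-classifying
        recovers the fixture counts exactly."""
        for comparison in ("DBL-vs-DBH", "GTL-vs-GTH"):
            matrix = comparison_band_matrix(comparison)
            treatment, control = comparison.split("-vs-")
            summary = summarize_comparison(matrix, control, treatment)
            expected = pattern_class_counts()[comparison].to_dict()
            assert summary.n_class == expected

    def test_sample_compared_to_identical_copy_is_all_no_change(self, small_matrix):
        cells = dict(small_matrix.cells)
        for locus in small_matrix.loci:
            cells[(locus, "S1_copy")] = small_matrix.presence(locus, "S1")
        matrix = BandMatrix(cells=cells)
        summary = summarize_comparison(matrix, "S1", "S1_copy")
        assert summary.pct_group["no_change"] == 100.0

    def test_identical_control_and_treatment_errors(self, small_matrix):
        with pytest.raises(BandMatrixError, match="must differ"):
            summarize_comparison(small_matrix, "S1", "S1")

    def test_fully_absent_pair_needs_another_observation(self):
        cells = {
            ("L1", "A"): LanePresence(0, 0), ("L1", "B"): LanePresence(0, 0),
            ("L2", "A"): LanePresence(1, 1), ("L2", "B"): LanePresence(1, 1),
        }
        # L1 unobserved anywhere: excluded
        assert summarize_comparison(BandMatrix(cells=cells), "A", "B").n_total == 1
        # L1 observed in a third sample: class D
        cells[("L1", "C")] = LanePresence(1, 0)
        cells[("L2", "C")] = LanePresence(1, 1)
        summary = summarize_comparison(BandMatrix(cells=cells), "A", "B")
        assert summary.n_class["D"] == 1 and summary.n_total == 2


class TestEventCountsTable:
    def test_group_by_comparison_table(self):
        frame = pattern_class_counts()
        summaries = [
            ComparisonSummary.from_class_counts("DBH", "DBL", frame["DBL-vs-DBH"].to_dict()),
            ComparisonSummary.from_class_counts("FSH", "FSL", frame["FSL-vs-FSH"].to_dict()),
        ]
        table = event_counts_table(summaries)
        assert table.row_labels == ["demethylation", "methylation"]
        assert table.col_labels == ["DBL-vs-DBH", "FSL-vs-FSH"]
        assert table.cells.tolist() == [[39, 15], [2, 18]]

    def test_columns_preserve_input_order(self):
        frame = pattern_class_counts()
        summaries = [
            ComparisonSummary.from_class_counts("FSH", "FSL", frame["FSL-vs-FSH"].to_dict()),
            ComparisonSummary.from_class_counts("DBH", "DBL", frame["DBL-vs-DBH"].to_dict()),
        ]
        assert event_counts_table(summaries).col_labels == ["FSL-vs-FSH", "DBL-vs-DBH"]

    def test_single_comparison_rejected(self):
        frame = pattern_class_counts()
        summary = ComparisonSummary.from_class_counts("DBH", "DBL", frame["DBL-vs-DBH"].to_dict())
        with pytest.raises(ValueError, match="at least two"):
            event_counts_table([summary])
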