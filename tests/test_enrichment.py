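import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromae.annotation import GeneInterval
from chromae.coverage import BedGraphTrack
from chromae.enrichment import (
    ProcessParams,
    build_enrichment_table,
    control_floor_filter,
    normalize,
    quantile_rank,
    read_table,
    write_table,
)


def rank_oracle(values):
    """Sort-and-average-ties oracle for the fractional quantile rank."""
    values = list(values)
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j + 1) / 2  # mean of 1-based positions spanned
        for k in range(i, j + 1):
            ranks[order[k]] = avg / n
        i = j + 1
    return np.array(ranks)


class TestQuantileRank:
    def test_untied_values(self):
        assert quantile_rank([3, 1, 2]) == pytest.approx([1.0, 1 / 3, 2 / 3])

    def test_all_tied(self):
        # mean of ranks {1,2,3,4}/4
        assert quantile_rank([5, 5, 5, 5]) == pytest.approx([0.625] * 4)

    def test_singleton(self):
        assert quantile_rank([7.0]) == pytest.approx([1.0])

    def test_empty_and_nan_rejected(self):
        with pytest.raises(ValueError):
            quantile_rank([])
        with pytest.raises(ValueError):
            quantile_rank([1.0, float("nan")])

    def test_matches_oracle_on_random_vectors_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            values = rng.integers(0, 8, size=rng.integers(1, 40)).astype(float)
            np.testing.assert_array_equal(
                quantile_rank(values), rank_oracle(values)
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_monotone_transform_invariance(self, values):
        # ranks depend only on order, so any strictly monotone transform
        # leaves them unchanged (power-of-two scaling is exact in floats,
        # so distinct inputs stay distinct)
        arr = np.asarray(values)
        transformed = arr * 4.0
        np.testing.assert_allclose(
            quantile_rank(arr), quantile_rank(transformed), atol=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_idempotent_in_rank_order(self, values):
        once = quantile_rank(np.asarray(values))
        np.testing.assert_allclose(quantile_rank(once), once, atol=1e-12)


class TestControlFloor:
    def test_zero_threshold_keeps_all(self):
        kept, removed = control_floor_filter({"a": 0.0, "b": 5.0}, 0.0)
        assert kept == {"a", "b"} and removed == set()

    def test_threshold_comparison(self):
        kept, removed = control_floor_filter(
            {"a": 0.1, "b": 0.5, "c": 1.2}, 0.5
        )
        assert kept == {"b", "c"} and removed == {"a"}

    def test_all_below_gives_empty_survivors(self, caplog):
        kept, _ = control_floor_filter({"a": 0.1}, 5.0)
        assert kept == set()


class TestNormalize:
    @pytest.mark.parametrize(
        "chip,control,pseudo,expected",
        [(4.0, 2.0, 0.0, 2.0), (3.0, 3.0, 0.0, 1.0), (0.0, 2.0, 0.5, 0.2)],
    )
    def test_control_ratio(self, chip, control, pseudo, expected):
        assert normalize(chip, control, 100, "control", pseudo) == pytest.approx(
            expected
        )

    def test_length_mode_is_the_per_base_mean(self):
        assert normalize(3.5, None, 100, "length") == 3.5

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            normalize(1.0, 0.0, 100, "control", 0.0)


def make_tracks(tmp_path, genes, chip_values, control_values, name="m"):
    chip = tmp_path / f"{name}_chip.bedgraph"
    ctrl = tmp_path / f"{name}_ctrl.bedgraph"
    with open(chip, "w") as fc, open(ctrl, "w") as fk:
        for g, cv, kv in zip(genes, chip_values, control_values):
            fc.write(f"{g.chrom}\t{g.start}\t{g.end}\t{cv}\n")
            fk.write(f"{g.chrom}\t{g.start}\t{g.end}\t{kv}\n")
    return BedGraphTrack(chip), BedGraphTrack(ctrl)


class TestBuildEnrichmentTable:
    genes = [
        GeneInterval(f"g{i}", "chr1", i * 100, i * 100 + 50, "+")
        for i in range(10)
    ]

    def test_ranks_are_permutation_of_grid(self, tmp_path):
        chip_vals = [float(v) for v in [5, 3, 8, 1, 9, 2, 7, 4, 6, 10]]
        chip, ctrl = make_tracks(tmp_path, self.genes, chip_vals, [1.0] * 10)
        table, report = build_enrichment_table(
            {"mark": chip}, ctrl, self.genes,
            ProcessParams(control_threshold=0.0),
        )
        assert table.shape == (10, 1)
        assert report.empty
        assert sorted(table["mark"]) == pytest.approx(
            [(i + 1) / 10 for i in range(10)]
        )

    def test_control_floor_removes_rows_before_ranking(self, tmp_path):
        controls = [0.01] * 3 + [1.0] * 7
        chip, ctrl = make_tracks(
            tmp_path, self.genes, list(range(1, 11)), controls
        )
        table, report = build_enrichment_table(
            {"mark": chip}, ctrl, self.genes,
            ProcessParams(control_threshold=0.1),
        )
        assert len(table) == 7
        assert set(report["gene_id"]) == {"g0", "g1", "g2"}
        assert set(report["reason"]) == {"below_control_floor"}
        # ranks are over the 7 survivors only
        assert sorted(table["mark"]) == pytest.approx(
            [(i + 1) / 7 for i in range(7)]
        )

    def test_mark_identical_to_control_gives_equal_ranks(self, tmp_path):
        vals = [float(v) for v in range(1, 11)]
        chip, ctrl = make_tracks(tmp_path, self.genes, vals, vals)
        table, _ = build_enrichment_table({"mark": chip}, ctrl, self.genes)
        assert table["mark"].nunique() == 1  # all ratios 1.0, all ranks tied

    def test_deterministic_output_files(self, tmp_path):
        chip, ctrl = make_tracks(
            tmp_path, self.genes, list(range(1, 11)), [1.0] * 10
        )
        table, _ = build_enrichment_table({"mark": chip}, ctrl, self.genes)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_table(table, p1)
        write_table(table, p2)
        assert p1.read_bytes() == p2.read_bytes()
        roundtrip = read_table(p1)
        pd.testing.assert_frame_equal(roundtrip, table, atol=1e-6)

    def test_requires_mark_track(self):
        with pytest.raises(ValueError, match="at least one mark"):
            build_enrichment_table({}, None, self.genes)
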