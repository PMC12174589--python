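"""Purity, hit ranking, report formatting and pick-list selection."""

import math

import numpy as np
import pandas as pd
import pytest

from wellseq.wellcall import (
    AsvWellTable,
    format_purity,
    purity,
    select_recoverable,
    top_hits,
    write_report,
)


def _table(data, sequences=None):
    """Build an AsvWellTable from {asv: {(plate, well): count}}."""
    cols = sorted({pw for row in data.values() for pw in row})
    counts = pd.DataFrame(
        0, index=sorted(data), columns=pd.MultiIndex.from_tuples(cols)
    )
    for asv, row in data.items():
        for pw, c in row.items():
            counts.loc[asv, pw] = c
    return AsvWellTable(counts=counts, sequences=sequences or {})


class TestPurity:
    @pytest.mark.parametrize(
        "count, total, expected",
        [
            (1446, 1490, 97.05),
            (1343, 1391, 96.55),
            (539, 887, 60.77),
            (997, 997, 100.0),
            (0, 50, 0.0),
            (1, 3, 33.33),
            (2, 3, 66.67),
        ],
    )
    def test_worked_examples(self, count, total, expected):
        assert purity(count, total) == expected

    def test_empty_well_is_undefined(self):
        assert math.isnan(purity(0, 0))

    def test_rounding_is_half_up(self):
        # 100 * 1/800 = 0.125 -> 0.13 under half-up (banker's would give 0.12)
        assert purity(1, 800) == 0.13

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            purity(10, 5)

    def test_unrounded_purities_close_to_100_per_well(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=12)
        total = int(counts.sum())
        rounded = [purity(int(c), total) for c in counts]
        assert abs(sum(rounded) - 100) <= 0.01 * len(counts)


class TestFormatPurity:
    @pytest.mark.parametrize(
        "value, text",
        [(97.05, "97.05"), (100.0, "100"), (49.5, "49.5"), (0.0, "0"),
         (98.99, "98.99"), (float("nan"), "NaN")],
    )
    def test_report_rendering(self, value, text):
        assert format_purity(value) == text


class TestTopHits:
    def test_ranked_by_count_descending(self):
        table = _table({
            1: {("plate1", "G2"): 1446, ("plate10", "C6"): 997, ("plate16", "D1"): 732},
            2: {("plate1", "G2"): 44},
        })
        hits = top_hits(1, table, 3)
        assert [h.count for h in hits] == [1446, 997, 732]
        assert hits[0].cell() == "plate1_G2 | 1446 | 97.05"
        assert hits[1].cell() == "plate10_C6 | 997 | 100"
        assert hits[2].cell() == "plate16_D1 | 732 | 100"

    def test_fillers_distinguish_empty_and_occupied_wells(self):
        # A1 empty (total 0 -> NaN), A2 occupied by another ASV (-> 0)
        table = _table({
            1: {("plate14", "D5"): 2, ("plate1", "A1"): 0, ("plate1", "A2"): 0},
            2: {("plate1", "A2"): 30},
        })
        hits = top_hits(1, table, 3)
        assert hits[0].cell() == "plate14_D5 | 2 | 100"
        assert hits[1].cell() == "plate1_A1 | 0 | NaN"
        assert hits[2].cell() == "plate1_A2 | 0 | 0"

    def test_equal_counts_fall_back_to_lexicographic_order(self):
        table = _table({1: {("p1", "B1"): 5, ("p1", "A2"): 5, ("p1", "A1"): 5}})
        hits = top_hits(1, table, 3)
        assert [f"{h.plate_id}_{h.well}" for h in hits] == ["p1_A1", "p1_A2", "p1_B1"]

    def test_count_tie_broken_by_purity(self):
        table = _table({
            1: {("p1", "A1"): 50, ("p1", "B1"): 50},
            2: {("p1", "A1"): 50},  # A1 total 100 -> purity 50; B1 -> 100
        })
        hits = top_hits(1, table, 2)
        assert str(hits[0].well) == "B1" and hits[0].purity == 100.0

    def test_unknown_asv_rejected(self):
        table = _table({1: {("p1", "A1"): 1}})
        with pytest.raises(KeyError):
            top_hits(99, table)


class TestReport:
    def test_cells_match_published_format(self, tmp_path):
        table = _table(
            {
                1: {("plate33", "H1"): 1343, ("plate33", "H8"): 1269,
                    ("plate30", "B7"): 888},
                2: {("plate33", "H1"): 48, ("plate33", "H8"): 13},
            },
            sequences={1: "ACGT", 2: "TTTT"},
        )
        tax = {1: {"Kingdom": "Bacteria", "Genus": "Pseudomonas"}}
        path = tmp_path / "report.csv"
        report = write_report({1: "ACGT", 2: "TTTT"}, table, tax, n=3, path=path)
        assert report.loc[0, "top_count_1"] == "plate33_H1 | 1343 | 96.55"
        assert report.loc[0, "top_count_2"] == "plate33_H8 | 1269 | 98.99"
        assert report.loc[0, "Genus"] == "Pseudomonas"
        assert list(report.columns) == [
            "ASV", "Sequence", "Kingdom", "Phylum", "Class", "Order", "Family",
            "Genus", "top_count_1", "top_count_2", "top_count_3",
        ]

    def test_round_trip_recovers_counts_and_purities(self, tmp_path):
        rng = np.random.default_rng(1)
        data = {
            asv: {("p1", f"A{c}"): int(n) for c, n in
                  zip(range(1, 5), rng.integers(0, 2000, size=4))}
            for asv in (1, 2, 3)
        }
        table = _table(data)
        path = tmp_path / "report.csv"
        write_report({a: "N" for a in data}, table, None, n=3, path=path)
        back = pd.read_csv(path)
        totals = table.counts.sum(axis=0)
        for _, row in back.iterrows():
            for i in (1, 2, 3):
                plate_well, count, pur = [
                    t.strip() for t in row[f"top_count_{i}"].split("|")
                ]
                plate, well = plate_well.rsplit("_", 1)
                assert int(count) == table.counts.loc[row["ASV"], (plate, well)]
                expected = purity(int(count), int(totals[(plate, well)]))
                assert pur == format_purity(expected)

    def test_empty_asv_set_gives_header_only(self, tmp_path):
        table = _table({1: {("p1", "A1"): 1}})
        path = tmp_path / "empty.csv"
        report = write_report({}, table, None, n=3, path=path)
        assert len(report) == 0
        assert path.read_text().count("\n") == 1


class TestSelectRecoverable:
    def test_boundary_inclusive(self):
        # exactly 60 reads at exactly 20.00% purity qualifies
        table = _table({1: {("p1", "A1"): 60}, 2: {("p1", "A1"): 240}})
        assert purity(60, 300) == 20.0
        picks = select_recoverable([1], table)
        assert 1 in picks and picks[1].count == 60

    def test_below_read_floor_excluded(self):
        table = _table({1: {("p1", "A1"): 59}, 2: {("p1", "A1"): 3}})
        assert purity(59, 62) > 90
        assert select_recoverable([1], table) == {}

    def test_just_below_purity_floor_excluded(self):
        table = _table({1: {("p1", "A1"): 1999}, 2: {("p1", "A1"): 8001}})
        assert purity(1999, 10000) == 19.99
        assert select_recoverable([1], table) == {}

    def test_planted_qualifying_asvs_all_found(self):
        rng = np.random.default_rng(2)
        data, qualifying = {}, set()
        for asv in range(1, 26):
            count = int(rng.integers(10, 200))
            other = int(rng.integers(0, 300))
            data[asv] = {("p1", f"A{(asv - 1) % 12 + 1}"): 0}  # placeholder
            data[asv] = {(f"p{asv}", "A1"): count}
            data[asv][(f"p{asv}", "A2")] = 0
            data.setdefault(1000 + asv, {})[(f"p{asv}", "A1")] = other
            if count >= 60 and purity(count, count + other) >= 20:
                qualifying.add(asv)
        table = _table(data)
        picks = select_recoverable(range(1, 26), table)
        assert set(picks) == qualifying
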