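"""Rarefaction, core ASVs, isolate matching and categorization."""

import numpy as np
import pandas as pd
import pytest

from wellseq import simdata
from wellseq.ecology import (
    Category,
    CommunityTable,
    categorize_isolates,
    core_asvs,
    core_asvs_by_host,
    match_isolates,
    rarefy,
)


def _table(rows, columns, host=None):
    counts = pd.DataFrame(rows, columns=columns)
    counts.index = [f"s{i}" for i in range(len(counts))]
    h = pd.Series(host, index=counts.index) if host is not None else None
    return CommunityTable(counts, h)


class TestRarefy:
    def test_sample_at_target_depth_unchanged(self):
        t = _table([[600, 400]], ["a", "b"])
        out = rarefy(t, depth=1000, seed=1)
        assert out.counts.loc["s0"].tolist() == [600, 400]

    def test_subsampled_depths_exact_and_bounded(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 500, size=(4, 10))
        t = _table(rows, [f"a{i}" for i in range(10)])
        depth = int(rows.sum(axis=1).min())
        out = rarefy(t, depth=depth, seed=2)
        assert (out.counts.sum(axis=1) == depth).all()
        assert (out.counts.values <= rows).all()

    def test_shallow_samples_dropped(self):
        t = _table([[5, 5], [600, 400]], ["a", "b"])
        out = rarefy(t, depth=100, seed=3)
        assert list(out.counts.index) == ["s1"]

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(4)
        rows = rng.integers(0, 500, size=(3, 20))
        t = _table(rows, [f"a{i}" for i in range(20)])
        a = rarefy(t, depth=1000, seed=9).counts
        b = rarefy(t, depth=1000, seed=9).counts
        assert a.equals(b)

    def test_hypergeometric_mean_preserves_proportions(self):
        # one ASV at 50% of a deep sample: mean rarefied share ~ 50%
        t = _table([[5000, 5000]], ["a", "b"])
        shares = [
            rarefy(t, depth=200, seed=s).counts.loc["s0", "a"] / 200
            for s in range(200)
        ]
        se = np.sqrt(0.25 / 200) / np.sqrt(200)  # hypergeometric ~ binomial here
        assert abs(np.mean(shares) - 0.5) < 4 * se

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            rarefy(_table([[1]], ["a"]), depth=0)


class TestCoreAsvs:
    def test_prevalent_abundant_asv_is_core(self):
        # 1% in 8 of 10 samples: prevalence 0.8 >= 0.7, abundance >= 0.1%
        rows = [[10, 990] if i < 8 else [0, 1000] for i in range(10)]
        t = _table(rows, ["x", "y"])
        assert "x" in core_asvs(t)

    def test_below_detection_everywhere_not_core(self):
        rows = [[5, 9995] for _ in range(10)]  # 0.05% < 0.1%
        t = _table(rows, ["x", "y"])
        assert "x" not in core_asvs(t)

    def test_insufficient_prevalence_not_core(self):
        rows = [[10, 990] if i < 6 else [0, 1000] for i in range(10)]
        t = _table(rows, ["x", "y"])
        assert "x" not in core_asvs(t)

    def test_raising_prevalence_never_grows_core(self):
        rng = np.random.default_rng(5)
        rows = rng.integers(0, 50, size=(12, 30))
        t = _table(rows, [f"a{i}" for i in range(30)])
        previous = None
        for p in (0.3, 0.5, 0.7, 0.9):
            current = core_asvs(t, prevalence_min=p)
            if previous is not None:
                assert current <= previous
            previous = current

    def test_per_host_groups_computed_separately(self):
        rows = [[100, 0, 900], [100, 0, 900], [0, 100, 900], [0, 100, 900]]
        t = _table(rows, ["pea_core", "corn_core", "shared"],
                   host=["pea", "pea", "corn", "corn"])
        cores = core_asvs_by_host(t)
        assert cores["pea"] == {"pea_core", "shared"}
        assert cores["corn"] == {"corn_core", "shared"}

    def test_empty_group_rejected(self):
        t = _table([[1]], ["a"])
        with pytest.raises(ValueError):
            core_asvs(CommunityTable(t.counts.iloc[:0]))

    def test_planted_cores_recovered_exactly(self):
        table, truth = simdata.simulate_community(
            n_samples=10,
            n_asvs=40,
            core_spec=[simdata.PlantedCore(prevalence=1.0, rel_abundance=0.01)] * 5,
            seed=42,
        )
        assert core_asvs(table) == truth.core_asvs
        assert len(truth.core_asvs) == 5


class TestMatchIsolates:
    def test_exact_match_and_unmatched(self):
        t = _table([[10, 10]], ["AAAA", "CCCC"])
        recs = match_isolates({"i1": "AAAA", "i2": "GGGG"}, t)
        by_id = {r.isolate_id: r for r in recs}
        assert by_id["i1"].matched_asv == "AAAA"
        assert by_id["i2"].matched_asv is None and not by_id["i2"].ambiguous

    def test_near_match_within_budget(self):
        t = _table([[10, 10]], ["AAAAAAAA", "CCCCCCCC"])
        recs = match_isolates({"i1": "AAAAAAAT"}, t, max_mismatch=1)
        assert recs[0].matched_asv == "AAAAAAAA"

    def test_equidistant_candidates_ambiguous(self):
        t = _table([[10, 10]], ["AAAAAAAA", "AAAAAAAC"])
        recs = match_isolates({"i1": "AAAAAAAG"}, t, max_mismatch=1)
        assert recs[0].matched_asv is None and recs[0].ambiguous


class TestCategorizeIsolates:
    def _community(self):
        # 10 samples x 6 ASVs: asv0/asv1 core (high prevalence+abundance);
        # asv2 abundant but only half-prevalent; asv3-5 sparse and lean
        cols = [f"asv{i}" for i in range(6)]
        rows = []
        for s in range(10):
            rows.append([
                300 if s > 0 else 0,   # 9/10 prevalence
                500,                   # ubiquitous
                400 if s < 5 else 0,   # prevalence 0.5 -> never core
                100 if s < 5 else 0,
                20 if s < 3 else 0,
                5 if s < 2 else 0,
            ])
        return _table(rows, cols)

    def test_core_top50_rare_assignment(self):
        t = self._community()
        isolates = {f"i{i}": f"asv{i}" for i in range(6)}
        recs = categorize_isolates(match_isolates(isolates, t), t)
        cats = {r.isolate_id: r.category for r in recs}
        assert cats["i0"] == Category.CORE
        assert cats["i1"] == Category.CORE
        assert cats["i2"] == Category.TOP50  # rank 3 of 6, upper half
        assert cats["i4"] == Category.RARE
        assert cats["i5"] == Category.RARE
        assert all(c != Category.UNMATCHED for c in cats.values())

    def test_categories_partition_matched_isolates(self):
        t = self._community()
        isolates = {f"i{i}": f"asv{i}" for i in range(6)}
        isolates["stranger"] = "T" * 60
        recs = categorize_isolates(match_isolates(isolates, t), t)
        matched = [r for r in recs if r.matched_asv is not None]
        assert all(
            r.category in (Category.CORE, Category.TOP50, Category.RARE)
            for r in matched
        )
        unmatched = [r for r in recs if r.matched_asv is None]
        assert all(r.category == Category.UNMATCHED for r in unmatched)

    def test_noncore_upper_half_is_top50_and_median_inclusive(self):
        # 4 ASVs occupying only 4 of 10 samples: prevalence 0.4 rules out
        # core, so the abundance rank decides; ranks 1-2 are the upper half
        rows = [[40, 30, 20, 10] if i < 4 else [0, 0, 0, 0] for i in range(10)]
        t = _table(rows, ["a", "b", "c", "d"])
        recs = categorize_isolates(
            match_isolates({"ia": "a", "ib": "b", "ic": "c", "id": "d"}, t), t
        )
        cats = {r.isolate_id: r.category for r in recs}
        assert cats["ia"] == Category.TOP50 and cats["ib"] == Category.TOP50
        assert cats["ic"] == Category.RARE and cats["id"] == Category.RARE
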