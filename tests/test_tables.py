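import numpy as np
import pandas as pd
import pytest

from snownet.tables import (
    BACTERIA,
    FUNGI,
    SNOW_COVERED,
    SNOW_FREE,
    AsvTable,
    SampleMetadata,
    ValidationError,
    abundant_asvs_per_group,
    condition_exclusive_core,
    core_asvs,
    load_asv_table,
    relative_abundance,
    write_asv_table,
)


def _meta(locations, conditions, samples=None):
    samples = samples or [f"s{i}" for i in range(len(locations))]
    return SampleMetadata(
        pd.DataFrame(
            {"location": locations, "condition": conditions},
            index=pd.Index(samples, name="sample_id"),
        )
    )


class TestAsvTable:
    def test_round_trip(self, toy_table, tmp_path):
        path = tmp_path / "counts.tsv"
        write_asv_table(toy_table, path)
        loaded = load_asv_table(path, FUNGI)
        pd.testing.assert_frame_equal(loaded.counts, toy_table.counts)

    def test_transposed_orientation(self, toy_table, tmp_path):
        path = tmp_path / "counts_t.tsv"
        toy_table.counts.T.to_csv(path, sep="\t", index_label="asv_id")
        loaded = load_asv_table(path, FUNGI, orientation="asvs_by_samples")
        pd.testing.assert_frame_equal(loaded.counts, toy_table.counts)

    def test_all_zero_column_dropped(self, caplog):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]}, index=["s1", "s2"])
        table = AsvTable(counts, BACTERIA)
        assert table.asv_ids == ["a"]

    @pytest.mark.parametrize(
        "counts",
        [
            pd.DataFrame({"a": [1, -1]}, index=["s1", "s2"]),
            pd.DataFrame({"a": [0.5, 1.0]}, index=["s1", "s2"]),
        ],
        ids=["negative", "non-integer"],
    )
    def test_invalid_counts_raise(self, counts):
        with pytest.raises(ValidationError):
            AsvTable(counts, FUNGI)

    def test_duplicate_ids_raise(self):
        counts = pd.DataFrame([[1, 2], [3, 4]], index=["s1", "s1"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="duplicate sample"):
            AsvTable(counts, FUNGI)

    def test_empty_table_raises(self):
        with pytest.raises(ValidationError):
            AsvTable(pd.DataFrame(), FUNGI)


class TestCoreAsvs:
    def test_present_everywhere_is_core(self):
        counts = pd.DataFrame(
            {"core": [1, 2, 1], "patchy": [3, 0, 5]},
            index=["s0", "s1", "s2"],
        )
        meta = _meta(["A", "B", "C"], [SNOW_FREE] * 3, ["s0", "s1", "s2"])
        assert core_asvs(AsvTable(counts, FUNGI), meta) == {"core"}

    def test_two_of_three_locations_not_core(self):
        counts = pd.DataFrame({"x": [1, 1, 0]}, index=["s0", "s1", "s2"])
        meta = _meta(["A", "B", "C"], [SNOW_FREE] * 3, ["s0", "s1", "s2"])
        assert core_asvs(AsvTable(counts, FUNGI), meta) == set()

    def test_seeded_fixture_matches_brute_force(self):
        rng = np.random.default_rng(3)
        n, p = 12, 10
        locations = ["A", "B", "C"] * 4
        counts = (rng.random((n, p)) < 0.3).astype(int)
        counts[:, :4] = 0
        for j, loc_rows in enumerate([range(0, 4), range(4, 8), range(8, 12)]):
            counts[list(loc_rows)[j % 4], :4] = 1  # seed 4 ASVs into every location
        counts[0, 4:] += 1  # keep remaining columns non-empty
        samples = [f"s{i}" for i in range(n)]
        table = AsvTable(
            pd.DataFrame(counts, index=samples, columns=[f"a{j}" for j in range(p)]), FUNGI
        )
        meta = _meta(
            ["A", "B", "C", "A", "B", "C", "A", "B", "C", "A", "B", "C"],
            [SNOW_FREE] * 12,
            samples,
        )
        # independent brute-force occurrence scan
        expected = set()
        for asv in table.asv_ids:
            locs = {
                meta.table.at[s, "location"]
                for s in samples
                if table.counts.at[s, asv] > 0
            }
            if locs == {"A", "B", "C"}:
                expected.add(asv)
        assert {"a0", "a1", "a2", "a3"} <= expected
        assert core_asvs(table, meta) == expected

    def test_single_location_errors(self):
        counts = pd.DataFrame({"a": [1, 1]}, index=["s0", "s1"])
        meta = _meta(["A", "A"], [SNOW_FREE, SNOW_COVERED], ["s0", "s1"])
        with pytest.raises(ValidationError, match="single location"):
            core_asvs(AsvTable(counts, FUNGI), meta)

    def test_core_monotone_under_added_counts(self, default_dataset):
        fungal, _, _, meta, _ = default_dataset
        before = core_asvs(fungal, meta)
        boosted = fungal.counts.copy()
        boosted.iloc[0] += 1  # adding counts can only add detections
        after = core_asvs(AsvTable(boosted, FUNGI), meta)
        assert before <= after


class TestRelativeAbundance:
    def test_values(self):
        counts = pd.DataFrame({"a": [2, 1], "b": [2, 2], "c": [0, 7]}, index=["s1", "s2"])
        rel = relative_abundance(AsvTable(counts, FUNGI))
        assert rel.loc["s1"].tolist() == [0.5, 0.5, 0.0]
        np.testing.assert_allclose(rel.loc["s2"].tolist(), [0.1, 0.2, 0.7])
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_depth_sample_named(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [1, 0]}, index=["ok", "empty"])
        table = AsvTable.__new__(AsvTable)  # bypass drop to keep the zero row
        table.counts = counts
        table.kingdom = FUNGI
        with pytest.raises(ValidationError, match="empty"):
            relative_abundance(table)


class TestAbundantAsvs:
    def _table_meta(self):
        counts = pd.DataFrame(
            {"big": [10, 20, 30, 40], "small": [90, 180, 270, 360]},
            index=[f"s{i}" for i in range(4)],
        )
        meta = _meta(
            ["A", "A", "B", "B"],
            [SNOW_FREE, SNOW_COVERED, SNOW_FREE, SNOW_COVERED],
            [f"s{i}" for i in range(4)],
        )
        return AsvTable(counts, FUNGI), meta

    def test_threshold_zero_keeps_all(self):
        table, meta = self._table_meta()
        groups = abundant_asvs_per_group(table, meta, 0.0)
        assert all(set(v) == {"big", "small"} for v in groups.values())

    def test_ten_percent_asv_included_everywhere(self):
        table, meta = self._table_meta()
        groups = abundant_asvs_per_group(table, meta, 0.07)
        assert all("big" in v for v in groups.values())

    def test_threshold_near_one_empty(self):
        table, meta = self._table_meta()
        groups = abundant_asvs_per_group(table, meta, 0.95)
        assert all(v == [] for v in groups.values())

    def test_zero_threshold_superset_property(self, default_dataset):
        fungal, _, _, meta, _ = default_dataset
        all_groups = abundant_asvs_per_group(fungal, meta, 0.0)
        strict = abundant_asvs_per_group(fungal, meta, 0.01)
        for group, asvs in strict.items():
            assert set(asvs) <= set(all_groups[group])


class TestConditionExclusiveCore:
    def test_partition(self):
        counts = pd.DataFrame(
            {
                "free_only": [3, 0, 1, 0],
                "cov_only": [0, 2, 0, 4],
                "shared": [1, 1, 1, 1],
            },
            index=[f"s{i}" for i in range(4)],
        )
        meta = _meta(
            ["A", "A", "B", "B"],
            [SNOW_FREE, SNOW_COVERED, SNOW_FREE, SNOW_COVERED],
            [f"s{i}" for i in range(4)],
        )
        table = AsvTable(counts, FUNGI)
        part = condition_exclusive_core(table, meta, set(table.asv_ids))
        assert part.at["free_only", "category"] == "snow-free-only"
        assert part.at["cov_only", "category"] == "snow-covered-only"
        assert part.at["shared", "category"] == "both"
        assert part.at["free_only", "n_samples_snow_free"] == 2
        assert part.at["free_only", "n_samples_snow_covered"] == 0

    def test_planted_exclusives_recovered(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(8)]
        conditions = [SNOW_FREE, SNOW_COVERED] * 4
        counts = pd.DataFrame(
            rng.integers(1, 5, size=(8, 5)),
            index=samples,
            columns=[f"a{j}" for j in range(5)],
        )
        free_rows = [i for i, c in enumerate(conditions) if c == SNOW_FREE]
        cov_rows = [i for i, c in enumerate(conditions) if c == SNOW_COVERED]
        counts.iloc[cov_rows, 0] = 0  # a0, a1 planted snow-free-only
        counts.iloc[cov_rows, 1] = 0
        meta = _meta(["A", "B"] * 4, conditions, samples)
        table = AsvTable(counts, BACTERIA)
        part = condition_exclusive_core(table, meta, set(table.asv_ids))
        free_only = set(part.index[part["category"] == "snow-free-only"])
        assert free_only == {"a0", "a1"}
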