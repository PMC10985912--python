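import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snownet.community import (
    alpha_diversity,
    bray_curtis,
    groupwise_kruskal_dunn,
    permanova,
    phylum_richness_contrast,
)
from snownet.tables import (
    FUNGI,
    SNOW_COVERED,
    SNOW_FREE,
    AsvTable,
    SampleMetadata,
    Taxonomy,
    ValidationError,
)


def _table(rows, samples=None):
    arr = np.asarray(rows)
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    return AsvTable(
        pd.DataFrame(arr, index=samples, columns=[f"a{j}" for j in range(arr.shape[1])]),
        FUNGI,
    )


class TestAlphaDiversity:
    def test_uniform_sample(self):
        rec = alpha_diversity(_table([[5, 5, 5, 5]])).iloc[0]
        assert rec["richness"] == 4
        assert rec["shannon"] == pytest.approx(np.log(4), abs=1e-12)

    def test_single_taxon(self):
        rec = alpha_diversity(_table([[10, 0, 1], [10, 0, 0]])).iloc[1]
        assert rec["richness"] == 1
        assert rec["shannon"] == 0.0

    def test_hand_computed(self):
        rec = alpha_diversity(_table([[1, 2, 3]])).iloc[0]
        p = np.array([1, 2, 3]) / 6
        assert rec["shannon"] == pytest.approx(-(p * np.log(p)).sum())
        assert rec["shannon"] == pytest.approx(1.0114, abs=1e-4)

    def test_scale_invariance(self):
        a = alpha_diversity(_table([[3, 5, 9, 2]]))["shannon"].iloc[0]
        b = alpha_diversity(_table([[30, 50, 90, 20]]))["shannon"].iloc[0]
        assert a == pytest.approx(b)

    def test_shannon_bounded_by_log_richness(self, small_dataset):
        fungal, *_ = small_dataset
        records = alpha_diversity(fungal)
        assert (records["shannon"] <= np.log(records["richness"]) + 1e-9).all()

    def test_zero_depth_errors(self):
        table = _table([[1, 1], [2, 3]])
        table.counts.iloc[1] = 0
        with pytest.raises(ValidationError):
            alpha_diversity(table)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        d = bray_curtis(np.array([[1.0, 0.0], [0.0, 4.0]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_computed(self):
        d = bray_curtis(np.array([[2.0, 1.0, 0.0], [0.0, 1.0, 3.0]]))
        assert d.iloc[0, 1] == pytest.approx(5 / 7)

    def test_depth_invariance_on_proportions(self):
        x = np.array([[2.0, 1.0, 1.0], [1.0, 1.0, 2.0]])
        p = x / x.sum(axis=1, keepdims=True)
        q = (10 * x) / (10 * x).sum(axis=1, keepdims=True)
        pd.testing.assert_frame_equal(bray_curtis(p), bray_curtis(q))

    def test_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(1)
        d = bray_curtis(rng.random((6, 4))).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)


class TestPermanova:
    def test_identical_samples_zero_r2(self):
        x = np.tile([1.0, 2.0, 3.0], (6, 1))
        d = bray_curtis(x)
        res = permanova(d, ["a", "a", "a", "b", "b", "b"], n_permutations=99, seed=0)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    def test_separated_clusters_significant(self):
        rng = np.random.default_rng(4)
        a = rng.dirichlet([10, 1, 1, 1], size=8)
        b = rng.dirichlet([1, 1, 1, 10], size=8)
        d = bray_curtis(np.vstack([a, b]))
        res = permanova(d, ["a"] * 8 + ["b"] * 8, n_permutations=999, seed=1)
        assert res.p_value <= 0.05
        assert res.r2 > 0.3

    def test_zero_permutations_error(self):
        d = bray_curtis(np.eye(4))
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "b", "b"], n_permutations=0)

    def test_constant_labels_error(self):
        d = bray_curtis(np.eye(4))
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 4, n_permutations=9)

    def test_matches_scikit_bio(self):
        """Pseudo-F agrees with the independent PERMANOVA in scikit-bio."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        x = rng.random((10, 5))
        d = bray_curtis(x / x.sum(axis=1, keepdims=True))
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(d, labels, n_permutations=99, seed=0)
        dm = skbio_stats.DistanceMatrix(d.to_numpy(), ids=[str(i) for i in range(10)])
        theirs = skbio_stats.permanova(dm, grouping=labels, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_null_pvalues_roughly_uniform(self):
        """Under exchangeable labels the permutation p-value is uniform."""
        rng = np.random.default_rng(9)
        pvals = []
        for i in range(120):
            x = rng.random((12, 5))
            d = bray_curtis(x / x.sum(axis=1, keepdims=True))
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            pvals.append(permanova(d, labels, n_permutations=99, seed=i).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPhylumRichnessContrast:
    def _dataset(self, shift=0):
        rng = np.random.default_rng(2)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        conditions = [SNOW_FREE] * 30 + [SNOW_COVERED] * 30
        meta = SampleMetadata(
            pd.DataFrame(
                {"location": ["L"] * n, "condition": conditions},
                index=pd.Index(samples, name="sample_id"),
            )
        )
        n_a, n_b = 30, 30
        pres_a = (rng.random((n, n_a)) < 0.4).astype(int)
        p_b = np.where(np.arange(n)[:, None] >= 30, 0.4 + shift, 0.4)
        pres_b = (rng.random((n, n_b)) < p_b).astype(int)
        counts = np.hstack([pres_a, pres_b]) * rng.integers(1, 9, size=(n, n_a + n_b))
        counts[:, 0] += 1  # avoid zero-depth samples
        table = AsvTable(
            pd.DataFrame(counts, index=samples, columns=[f"a{j}" for j in range(n_a + n_b)]),
            FUNGI,
        )
        tax = Taxonomy(
            pd.DataFrame(
                {"phylum": ["PhyA"] * n_a + ["PhyB"] * n_b},
                index=[f"a{j}" for j in range(n_a + n_b)],
            )
        )
        return table, tax, meta

    def test_planted_richness_shift_detected(self):
        table, tax, meta = self._dataset(shift=0.25)
        out = phylum_richness_contrast(table, tax, meta, min_asvs=10)
        row = out[out["phylum"] == "PhyB"].iloc[0]
        assert row["p_kruskal"] < 0.05
        assert row["median_snow_covered"] > row["median_snow_free"]
        null_row = out[out["phylum"] == "PhyA"].iloc[0]
        assert null_row["p_kruskal"] > 0.01

    def test_min_asvs_infinite_empty(self):
        table, tax, meta = self._dataset()
        assert phylum_richness_contrast(table, tax, meta, min_asvs=np.inf).empty

    def test_absent_phylum_median_zero(self):
        table, tax, meta = self._dataset()
        counts = table.counts.copy()
        counts.iloc[:30, 30:] = 0  # PhyB absent from all snow-free samples
        table2 = AsvTable(counts, FUNGI)
        keep = [a for a in table2.asv_ids]
        tax2 = Taxonomy(tax.assignments.loc[keep].copy())
        out = phylum_richness_contrast(table2, tax2, meta, min_asvs=5)
        row = out[out["phylum"] == "PhyB"].iloc[0]
        assert row["median_snow_free"] == 0.0


class TestKruskalDunn:
    def _meta(self, groups):
        samples = [f"s{i}" for i in range(len(groups))]
        return SampleMetadata(
            pd.DataFrame(
                {"location": groups, "condition": [SNOW_FREE] * len(groups)},
                index=pd.Index(samples, name="sample_id"),
            )
        )

    def test_null_data_no_dunn(self):
        rng = np.random.default_rng(0)
        groups = ["A", "B", "C"] * 40
        meta = self._meta(groups)
        values = pd.Series(rng.normal(size=len(groups)), index=meta.sample_ids)
        res = groupwise_kruskal_dunn(values, meta, factor="location")
        assert res.omnibus_p > 0.05
        assert res.dunn is None

    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(1)
        groups = ["A", "B", "C"] * 20
        meta = self._meta(groups)
        values = rng.normal(size=len(groups))
        values[np.array(groups) == "C"] += 3.0  # 3 SD shift
        res = groupwise_kruskal_dunn(pd.Series(values, index=meta.sample_ids), meta, "location")
        assert res.omnibus_p < 0.05
        dunn = res.dunn
        flagged = dunn[dunn["p_holm"] < 0.05]
        assert all("C" in {r.group_a, r.group_b} for r in flagged.itertuples())
        assert len(flagged) == 2

    def test_two_groups_single_comparison(self):
        rng = np.random.default_rng(2)
        groups = ["A", "B"] * 30
        meta = self._meta(groups)
        values = rng.normal(size=len(groups))
        values[np.array(groups) == "B"] += 2.0
        res = groupwise_kruskal_dunn(pd.Series(values, index=meta.sample_ids), meta, "location")
        assert res.dunn is not None and len(res.dunn) == 1
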