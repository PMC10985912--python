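import numpy as np
import pandas as pd
import pytest

from snownet._lasso import (
    HAVE_NUMBA,
    NeighborhoodState,
    neighborhood_paths_numba,
    neighborhood_paths_sklearn,
)
from snownet.filtering import FilteredPairTable, FilterPair, build_grid
from snownet.inference import (
    ClrMatrix,
    StarsSettings,
    default_subsample_size,
    infer_condition_networks,
    infer_network,
    joint_clr,
    lambda_max,
    make_lambda_path,
    mb_fit,
    refit_and_weight,
    stars_select,
    _standardize,
)
from snownet.synthetic import BOTH, PlantedEdge, generate_dataset
from snownet.tables import BACTERIA, FUNGI, SNOW_COVERED, SNOW_FREE

from conftest import small_sim_config


def _frame(arr, prefix):
    arr = np.atleast_2d(arr)
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestJointClr:
    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        f = _frame(rng.integers(0, 50, (6, 4)), "f")
        b = _frame(rng.integers(0, 500, (6, 9)), "b")
        clr = joint_clr(f, b)
        np.testing.assert_allclose(clr.values.sum(axis=1), 0.0, atol=1e-9)

    def test_constant_row_is_zero(self):
        clr = joint_clr(_frame([[3, 3]], "f"), _frame([[3, 3]], "b"))
        np.testing.assert_allclose(clr.values.to_numpy(), 0.0, atol=1e-12)

    def test_hand_computed_pseudocount(self):
        clr = joint_clr(_frame([[0]], "f"), _frame([[3]], "b"))
        m = (np.log(1) + np.log(4)) / 2
        np.testing.assert_allclose(
            clr.values.to_numpy()[0], [np.log(1) - m, np.log(4) - m], atol=1e-12
        )
        assert clr.values.to_numpy()[0, 1] == pytest.approx(0.6931, abs=1e-4)

    def test_sample_mismatch_errors(self):
        f = _frame([[1], [2]], "f")
        b = _frame([[1], [2]], "b").iloc[::-1]
        with pytest.raises(ValueError, match="same order"):
            joint_clr(f, b)

    def test_per_kingdom_variant_centres_blocks(self):
        rng = np.random.default_rng(1)
        f = _frame(rng.integers(0, 50, (5, 3)), "f")
        b = _frame(rng.integers(0, 500, (5, 7)), "b")
        clr = joint_clr(f, b, per_kingdom=True)
        vals = clr.values.to_numpy()
        np.testing.assert_allclose(vals[:, :3].sum(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(vals[:, 3:].sum(axis=1), 0.0, atol=1e-9)

    def test_kingdom_tags(self):
        clr = joint_clr(_frame([[1, 2]], "f"), _frame([[1, 2, 3]], "b"))
        assert list(clr.kingdoms) == [FUNGI, FUNGI, BACTERIA, BACTERIA, BACTERIA]


class TestMbFit:
    def _clr(self, data):
        data = np.asarray(data, dtype=float)
        frame = _frame(data - data.mean(axis=1, keepdims=True), "x")
        return ClrMatrix(values=frame, kingdoms=np.array([FUNGI] * data.shape[1]))

    def test_full_shrinkage_above_lambda_max(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(20, 5))
        clr = self._clr(data)
        lmax = lambda_max(clr.values.to_numpy())
        B = mb_fit(clr, lmax * 1.001)
        assert np.all(B == 0)

    def test_duplicated_feature_mutually_selected(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=20)
        noise = rng.normal(size=(20, 2))
        data = np.column_stack([z, z, noise[:, 0], noise[:, 1]])
        clr = self._clr(data)
        B = mb_fit(clr, 0.1)
        assert B[0, 1] != 0 and B[1, 0] != 0
        # closed form: lasso of y on its duplicate has coefficient 1 − λ
        assert B[0, 1] == pytest.approx(0.9, abs=0.05)

    def test_sample_permutation_invariant(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(15, 4))
        clr = self._clr(data)
        B1 = mb_fit(clr, 0.2)
        perm = rng.permutation(15)
        clr2 = ClrMatrix(
            values=clr.values.iloc[perm], kingdoms=clr.kingdoms
        )
        B2 = mb_fit(clr2, 0.2)
        np.testing.assert_allclose(B1, B2, atol=1e-8)

    def test_negative_lambda_errors(self):
        clr = self._clr(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError):
            mb_fit(clr, -0.1)

    def test_path_monotone_for_single_predictor(self):
        # 2 features: closed-form lasso ⇒ support can only grow as λ shrinks
        rng = np.random.default_rng(5)
        z = rng.normal(size=30)
        data = np.column_stack([z, 0.6 * z + 0.8 * rng.normal(size=30)])
        zstd = _standardize(data - data.mean(axis=1, keepdims=True))
        lambdas = make_lambda_path(1.0, 10)
        B = neighborhood_paths_numba(zstd, lambdas) if HAVE_NUMBA else \
            neighborhood_paths_sklearn(zstd, lambdas)
        support = (B != 0).sum(axis=(1, 2))
        assert np.all(np.diff(support) >= 0)


class TestSolverAgreement:
    def test_numba_matches_sklearn_objective(self):
        """Our coordinate-descent solver and scikit-learn's lasso_path reach
        the same optimum (objective within solver tolerance, supports close)."""
        rng = np.random.default_rng(6)
        n, p = 30, 20
        z = _standardize(rng.normal(size=(n, p)))
        lambdas = make_lambda_path(lambda_max(z), 8)
        B1 = neighborhood_paths_numba(z, lambdas)
        B2 = neighborhood_paths_sklearn(z, lambdas)

        def objective(B):
            total = 0.0
            for l, lam in enumerate(lambdas):
                for j in range(p):
                    b = B[l, :, j].copy()
                    b[j] = 0.0
                    r = z[:, j] - z @ b
                    total += 0.5 * np.dot(r, r) / n + lam * np.abs(b).sum()
            return total

        assert objective(B1) <= objective(B2) + 1e-6
        np.testing.assert_allclose(B1, B2, atol=5e-2)


class TestStarsSelect:
    def _clr(self, n=40, p=8, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(n, p))
        frame = _frame(data - data.mean(axis=1, keepdims=True), "x")
        return ClrMatrix(values=frame, kingdoms=np.array([FUNGI] * p))

    def test_fixed_seed_reproducible(self):
        clr = self._clr()
        r1 = stars_select(clr, seed=5)
        r2 = stars_select(clr, seed=5)
        assert r1.lambda_selected == r2.lambda_selected
        assert r1.instability_path == r2.instability_path

    def test_always_empty_graph_has_zero_instability(self):
        clr = self._clr()
        lmax = lambda_max(clr.values.to_numpy())
        path = np.array([lmax * 3.0, lmax * 2.5, lmax * 2.0])
        res = stars_select(clr, lambda_path=path, seed=0)
        assert all(d == 0.0 for _, d in res.instability_path)
        net = refit_and_weight(clr, res.lambda_selected)
        assert net.n_edges == 0

    def test_subsample_size_rule(self):
        assert default_subsample_size(40) == 20
        assert default_subsample_size(400) == 200
        assert default_subsample_size(10000) == 1000

    def test_planted_pair_recovered_across_seeds(self):
        """A strongly correlated pair enters the selected graph in nearly
        every random subsampling replicate (scaled-down repeated check)."""
        rng = np.random.default_rng(10)
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            z = rng.standard_normal((60, 10))
            z[:, 1] = 0.8 * z[:, 0] + np.sqrt(1 - 0.64) * rng.standard_normal(60)
            frame = _frame(z - z.mean(axis=1, keepdims=True), "x")
            clr = ClrMatrix(values=frame, kingdoms=np.array([FUNGI] * 10))
            res = stars_select(clr, seed=seed)
            net = refit_and_weight(clr, res.lambda_selected)
            if frozenset(("x0", "x1")) in net.edges:
                hits += 1
        assert hits >= int(0.9 * n_seeds)


class TestRefitAndWeight:
    def test_symmetrization_takes_larger_magnitude(self):
        # duplicate pair with asymmetric noise: both directions selected,
        # weight must equal the larger-|.| directional coefficient
        rng = np.random.default_rng(11)
        z = rng.standard_normal(50)
        data = np.column_stack(
            [z, z + 0.1 * rng.standard_normal(50)] +
            [rng.standard_normal(50) for _ in range(8)]
        )
        frame = _frame(data - data.mean(axis=1, keepdims=True), "x")
        clr = ClrMatrix(values=frame, kingdoms=np.array([FUNGI] * 10))
        net = refit_and_weight(clr, 0.3, symmetrize="max")
        B = mb_fit(clr, 0.3)
        w = net.graph.edges["x0", "x1"]["weight"]
        assert w == pytest.approx(
            B[0, 1] if abs(B[0, 1]) >= abs(B[1, 0]) else B[1, 0]
        )

    def test_orphans_removed(self):
        rng = np.random.default_rng(12)
        z = rng.standard_normal(40)
        data = np.column_stack(
            [z, z] + [rng.standard_normal(40) for _ in range(8)]
        )
        frame = _frame(data - data.mean(axis=1, keepdims=True), "x")
        clr = ClrMatrix(values=frame, kingdoms=np.array([FUNGI] * 10))
        net = refit_and_weight(clr, 0.55)
        assert set(net.graph.nodes) == {"x0", "x1"}
        assert net.dataset_nodes[FUNGI] == [f"x{i}" for i in range(10)]

    def test_sign_matches_weight(self):
        rng = np.random.default_rng(13)
        z = rng.standard_normal(50)
        data = np.column_stack([z, -z + 0.2 * rng.standard_normal(50)])
        frame = _frame(data - data.mean(axis=1, keepdims=True), "x")
        clr = ClrMatrix(values=frame, kingdoms=np.array([FUNGI, FUNGI]))
        net = refit_and_weight(clr, 0.3)
        d = net.graph.edges["x0", "x1"]
        assert d["sign"] == -1 and d["weight"] < 0


@pytest.fixture(scope="module")
def planted_run():
    # ρ=0.9 keeps the pair's CLR correlation above the StARS-selected
    # penalty after compositional attenuation (single fixed-seed check)
    cfg = small_sim_config(
        seed=17,
        planted_edges=[
            PlantedEdge(0, 0, 1, BOTH, rho=0.9),
            PlantedEdge(1, 1, -1, SNOW_COVERED, rho=0.9),
        ],
    )
    fungal, bacterial, _, meta, truth = generate_dataset(cfg)
    grid = build_grid(fungal, bacterial, (5,), (5,))
    free, covered = infer_condition_networks(grid[0], meta, StarsSettings(), seed=3)
    return free, covered, truth


class TestInferConditionNetworks:
    def test_both_conditions_inferred(self, planted_run):
        free, covered, _ = planted_run
        assert free.condition == SNOW_FREE
        assert covered.condition == SNOW_COVERED
        assert free.pair == FilterPair(5, 5)

    def test_planted_edge_present_with_sign(self, planted_run):
        free, covered, truth = planted_run
        both_key = frozenset((truth.edges[0].fungal_id, truth.edges[0].bacterial_id))
        assert both_key in free.edges and both_key in covered.edges
        cov_key = frozenset((truth.edges[1].fungal_id, truth.edges[1].bacterial_id))
        assert cov_key in covered.edges
        a, b = sorted(cov_key)
        assert covered.graph.edges[a, b]["sign"] == -1

    def test_feature_order_invariance(self):
        cfg = small_sim_config(seed=19, n_fungi=12, n_bacteria=20,
                               n_core_fungi=4, n_core_bacteria=6)
        fungal, bacterial, _, meta, _ = generate_dataset(cfg)
        samples = fungal.sample_ids
        net1 = infer_network(fungal.counts, bacterial.counts, seed=1)
        shuffled = fungal.counts[list(reversed(fungal.asv_ids))]
        net2 = infer_network(shuffled, bacterial.counts, seed=1)
        assert net1.edges == net2.edges

    def test_missing_condition_errors(self, small_dataset):
        fungal, bacterial, _, meta, _ = small_dataset
        free_only = meta.table[meta.table["condition"] == SNOW_FREE]
        from snownet.tables import SampleMetadata

        meta_free = SampleMetadata(free_only.copy())
        sub_f = fungal.subset_samples(meta_free.sample_ids)
        sub_b = bacterial.subset_samples(meta_free.sample_ids)
        pair = FilteredPairTable(fungal=sub_f, bacterial=sub_b, pair=FilterPair(1, 1))
        with pytest.raises(ValueError, match="snow-covered"):
            infer_condition_networks(pair, meta_free, seed=0)
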