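"""Group one-sample tests, z-conversion, cluster inference, RM-ANOVA, BH FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ketsim.exceptions import ValidationError
from ketsim.group_inference import (
    ClusterTable,
    cluster_threshold,
    extract_roi_means,
    fdr_bh,
    one_sample_t_map,
    repeated_measures_anova,
    roi_anova_family,
    t_to_z,
    z_map_from_t,
)
from ketsim.maps import ConnectivityMap, StatMap


def _maps(arr):
    return [ConnectivityMap(data=a) for a in arr]


class TestOneSampleT:
    def test_symmetric_pair_gives_zero_t(self):
        arr = np.zeros((2, 1, 1, 1))
        arr[0] = -1.0
        arr[1] = 1.0
        assert one_sample_t_map(_maps(arr)).data[0, 0, 0] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # values 1, 2, 3: mean 2, sd 1, t = 2 / (1/sqrt(3)) = 3.4641
        arr = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1)
        t = one_sample_t_map(_maps(arr))
        assert t.data[0, 0, 0] == pytest.approx(3.4641, abs=1e-4)
        assert t.df == 2

    def test_matches_textbook_formula_and_scipy(self, rng):
        X = rng.standard_normal((7, 3, 3, 2))
        tmap = one_sample_t_map(_maps(X))
        flat = X.reshape(7, -1)
        oracle = flat.mean(0) / (flat.std(0, ddof=1) / np.sqrt(7))
        assert np.max(np.abs(tmap.data.reshape(-1) - oracle)) < 1e-10
        scipy_t = stats.ttest_1samp(flat, 0.0, axis=0).statistic
        assert np.max(np.abs(tmap.data.reshape(-1) - scipy_t)) < 1e-10

    def test_needs_two_participants(self, rng):
        with pytest.raises(ValidationError):
            one_sample_t_map(_maps(rng.standard_normal((1, 2, 2, 2))))

    def test_zero_sd_voxels_masked(self):
        arr = np.ones((4, 1, 1, 2))
        arr[:, 0, 0, 1] = [0.0, 1.0, 2.0, 3.0]
        tmap = one_sample_t_map(_maps(arr))
        assert not tmap.mask[0, 0, 0]
        assert np.isnan(tmap.data[0, 0, 0])
        assert tmap.mask[0, 0, 1]


class TestTtoZ:
    def test_median_maps_to_median(self):
        assert t_to_z(0.0, 5) == pytest.approx(0.0, abs=1e-12)

    def test_large_df_limit(self):
        assert t_to_z(3.29, 10**7) == pytest.approx(3.29, abs=1e-3)

    def test_matches_quantile_composition_oracle(self):
        oracle = stats.norm.ppf(stats.t.cdf(2.0, 17))
        assert t_to_z(2.0, 17) == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize("df", [1, 3, 17, 100])
    def test_odd_and_strictly_increasing(self, df):
        grid = np.linspace(-30, 30, 101)
        z = t_to_z(grid, df)
        assert np.allclose(z, -t_to_z(-grid, df), atol=1e-10)
        assert np.all(np.diff(z) > 0)

    def test_extreme_t_stays_finite(self):
        z = t_to_z(80.0, 20)
        assert np.isfinite(z) and z > 8

    def test_nan_propagates(self):
        out = t_to_z(np.array([np.nan, 1.0]), 10)
        assert np.isnan(out[0]) and np.isfinite(out[1])


class TestClusterInference:
    def test_all_zero_map_yields_empty_table(self, rng):
        zmap = StatMap(data=np.zeros((6, 6, 6)), statistic="z")
        table = cluster_threshold(zmap, _maps(rng.standard_normal((5, 6, 6, 6))), n_perm=100)
        assert len(table) == 0

    def test_isolated_voxel_is_single_candidate(self, rng):
        z = np.zeros((6, 6, 6))
        z[3, 3, 3] = 4.0
        table = cluster_threshold(
            StatMap(data=z, statistic="z"), _maps(rng.standard_normal((5, 6, 6, 6))), n_perm=100
        )
        assert len(table) == 1
        assert table.table.iloc[0]["size"] == 1
        assert table.table.iloc[0]["peak_z"] == pytest.approx(4.0)

    def test_planted_block_labelled_as_one_cluster_of_exact_size(self, rng):
        z = np.zeros((8, 8, 8))
        z[2:4, 2:7, 3] = 5.0  # 2 x 5 x 1 block = 10 voxels
        table = cluster_threshold(
            StatMap(data=z, statistic="z"), _maps(rng.standard_normal((5, 8, 8, 8))), n_perm=100
        )
        assert len(table) == 1
        assert int(table.table.iloc[0]["size"]) == 10

    def test_positive_and_negative_clusters_labelled_separately(self, rng):
        z = np.zeros((8, 8, 8))
        z[1:3, 1, 1] = 4.5
        z[1:3, 1, 2] = -4.5  # face-adjacent but opposite sign
        table = cluster_threshold(
            StatMap(data=z, statistic="z"), _maps(rng.standard_normal((5, 8, 8, 8))), n_perm=100
        )
        assert len(table) == 2
        assert set(table.table["sign"]) == {1, -1}

    def test_labels_invariant_to_participant_order(self, rng):
        maps = _maps(rng.standard_normal((8, 6, 6, 6)) + 0.8)
        zmap = z_map_from_t(one_sample_t_map(maps))
        t1 = cluster_threshold(zmap, maps, cdt=2.0, n_perm=100, seed=1)
        t2 = cluster_threshold(zmap, maps[::-1], cdt=2.0, n_perm=100, seed=1)
        assert np.array_equal(t1.labels, t2.labels)

    def test_low_permutation_count_warns(self, rng):
        z = np.zeros((6, 6, 6))
        z[0, 0, 0] = 4.0
        with pytest.warns(UserWarning, match="cannot resolve"):
            cluster_threshold(
                StatMap(data=z, statistic="z"),
                _maps(rng.standard_normal((5, 6, 6, 6))),
                alpha=0.005,
                n_perm=100,
            )


class TestRoiMeans:
    def _clusters(self, labels):
        rows = []
        for cid in np.unique(labels):
            if cid == 0:
                continue
            rows.append(
                {
                    "cluster_id": int(cid), "sign": 1, "size": int((labels == cid).sum()),
                    "peak_z": 5.0, "peak_i": 0, "peak_j": 0, "peak_k": 0,
                    "p_fwe": 0.01, "significant": True,
                }
            )
        return ClusterTable(
            table=pd.DataFrame(rows), labels=labels, cdt=3.29, alpha=0.05, n_perm=100
        )

    def test_constant_map_means(self, rng):
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[0, :2, 0] = 1
        labels[2, 2, 2] = 2
        means = extract_roi_means(ConnectivityMap(data=np.full((4, 4, 4), 2.5)), self._clusters(labels))
        assert np.allclose(means, 2.5)

    def test_single_voxel_roi_returns_that_voxel(self, rng):
        data = rng.standard_normal((4, 4, 4))
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[1, 2, 3] = 1
        means = extract_roi_means(ConnectivityMap(data=data), self._clusters(labels))
        assert means[0] == pytest.approx(data[1, 2, 3])

    def test_matches_loop_oracle(self, rng):
        data = rng.standard_normal((5, 5, 5))
        labels = np.zeros((5, 5, 5), dtype=int)
        labels[:2, :2, 0] = 1
        labels[3:, 3:, 4] = 2
        means = extract_roi_means(ConnectivityMap(data=data), self._clusters(labels))
        for cid in (1, 2):
            vals = [data[i, j, k] for i, j, k in np.argwhere(labels == cid)]
            assert means[cid - 1] == pytest.approx(np.mean(vals), abs=1e-12)


class TestRmAnova:
    def test_identical_conditions_give_null_result(self, rng):
        col = rng.standard_normal(6)
        res = repeated_measures_anova(np.column_stack([col, col, col]))
        assert res.F == 0.0 and res.p == 1.0

    def test_two_conditions_equals_squared_paired_t(self, rng):
        Y = rng.standard_normal((9, 2))
        res = repeated_measures_anova(Y)
        t = stats.ttest_rel(Y[:, 0], Y[:, 1]).statistic
        assert res.F == pytest.approx(t**2, abs=1e-8)

    def test_matches_sums_of_squares_oracle_and_statsmodels(self, rng):
        Y = rng.standard_normal((10, 3))
        res = repeated_measures_anova(Y)
        # brute-force two-way (subject x condition) decomposition
        grand = Y.mean()
        ss_cond = 10 * np.sum((Y.mean(0) - grand) ** 2)
        ss_subj = 3 * np.sum((Y.mean(1) - grand) ** 2)
        ss_err = np.sum((Y - grand) ** 2) - ss_cond - ss_subj
        F = (ss_cond / 2) / (ss_err / 18)
        assert res.F == pytest.approx(F, abs=1e-8)
        from statsmodels.stats.anova import AnovaRM

        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 3),
                "cond": np.tile(np.arange(3), 10),
                "y": Y.reshape(-1),
            }
        )
        sm_res = AnovaRM(long, "y", "subject", within=["cond"]).fit()
        assert res.F == pytest.approx(float(sm_res.anova_table["F Value"].iloc[0]), abs=1e-8)
        assert res.p == pytest.approx(float(sm_res.anova_table["Pr > F"].iloc[0]), abs=1e-8)

    def test_family_fdr_is_applied_across_rois(self, rng):
        mats = [rng.standard_normal((8, 3)) for _ in range(4)]
        results = roi_anova_family(mats)
        ps = np.array([r.p for r in results])
        adj = np.array([r.p_fdr for r in results])
        expect = fdr_bh(ps)[0]
        assert np.allclose(adj, expect)
        assert np.all(adj >= ps - 1e-12)

    def test_missing_cells_rejected(self):
        Y = np.ones((4, 3))
        Y[0, 0] = np.nan
        with pytest.raises(ValidationError):
            repeated_measures_anova(Y)


class TestFdrBh:
    def test_single_p_unchanged(self):
        adj, rej = fdr_bh(np.array([0.03]), q=0.05)
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_stated_example_all_rejected(self):
        # sorted p_i <= i * 0.05 / 4 fails for none under step-up
        adj, rej = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert rej.all()

    def test_large_ps_not_rejected(self):
        _, rej = fdr_bh(np.array([0.5, 0.9]), q=0.05)
        assert not rej.any()

    def test_matches_exhaustive_step_up_reference_on_all_subsets(self):
        base = np.array([0.001, 0.011, 0.024, 0.04, 0.049, 0.2])

        def reference(p, q):
            m = len(p)
            order = np.argsort(p)
            ranked = p[order]
            thresh = q * (np.arange(1, m + 1)) / m
            passing = np.nonzero(ranked <= thresh)[0]
            k = passing.max() + 1 if len(passing) else 0
            reject = np.zeros(m, dtype=bool)
            reject[order[:k]] = True
            adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
            out = np.empty(m)
            out[order] = np.minimum(adj, 1.0)
            return out, reject

        for size in range(1, 7):
            for subset in itertools.combinations(range(6), size):
                p = base[list(subset)]
                adj, rej = fdr_bh(p, q=0.05)
                ref_adj, ref_rej = reference(p, 0.05)
                assert np.allclose(adj, ref_adj, atol=1e-12)
                assert np.array_equal(rej, ref_rej)
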