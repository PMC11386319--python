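"""Tests of voxelwise group inference: t maps, GLM, clusters, rank tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ccgrad as cg
from ccgrad.masks import sheet_mask
from ccgrad.stats import DesignInfo, design_from_table
from oracles import balanced_anova_interaction_f, enumerate_u_pvalue


def _balanced_table(n_per_cell, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for d in ("ADHD", "HC"):
        for a in ("child", "adolescent"):
            for _ in range(n_per_cell):
                rows.append(
                    {
                        "id": f"s{i:03d}", "diagnosis": d,
                        "age_group": a,
                        "sex": "M" if rng.random() < 0.5 else "F",
                        "site": "siteA" if rng.random() < 0.6 else "siteB",
                    }
                )
                i += 1
    return pd.DataFrame(rows)


class TestOneSampleT:
    def test_hand_value(self):
        sm = cg.one_sample_t(np.array([[1.0], [2.0], [3.0]]))
        assert sm.statistic[0] == pytest.approx(2 / (1 / np.sqrt(3)))
        assert sm.df == (2,)

    def test_symmetric_values_give_zero(self):
        sm = cg.one_sample_t(np.array([[-1.0], [0.0], [1.0]]))
        assert sm.statistic[0] == pytest.approx(0.0)

    def test_zero_variance_missing_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            sm = cg.one_sample_t(np.full((4, 2), 3.14))
        assert np.isnan(sm.statistic).all()


class TestGlmInteraction:
    def test_flat_cells_give_zero_f(self):
        df = _balanced_table(3)
        design = design_from_table(df, covariates=False)
        maps = np.ones((len(df), 2))
        maps += np.random.default_rng(0).standard_normal((len(df), 1)) * 0  # constant
        # add subject noise orthogonal to design? constant maps -> F = 0/0;
        # use equal cell means with within-cell noise instead
        maps = np.random.default_rng(1).standard_normal((len(df), 2))
        cell_effect = np.zeros(len(df))
        maps += cell_effect[:, None]
        out = cg.glm_interaction(maps, design)
        # no planted interaction: F should be small, and identical under
        # exchange of rows together with the design
        assert out["F_interaction"].statistic.max() < 15

    def test_matches_classical_anova_oracle(self):
        rng = np.random.default_rng(7)
        n = 20
        df = _balanced_table(n)
        design = design_from_table(df, covariates=False)
        cell = (df.diagnosis + "-" + df.age_group).to_numpy()
        y = rng.standard_normal(len(df))
        delta = {"ADHD-adolescent": 0.4, "ADHD-child": -0.4,
                 "HC-adolescent": -0.4, "HC-child": 0.4}
        y += np.array([delta[c] for c in cell])
        out = cg.glm_interaction(y[:, None], design)
        cells = {
            (0, 0): y[cell == "ADHD-child"],
            (0, 1): y[cell == "ADHD-adolescent"],
            (1, 0): y[cell == "HC-child"],
            (1, 1): y[cell == "HC-adolescent"],
        }
        f_ref = balanced_anova_interaction_f(cells)
        assert out["F_interaction"].statistic[0] == pytest.approx(f_ref, abs=1e-8)
        assert out["F_interaction"].df == (1, 4 * n - 4)

    def test_pure_interaction_nulls_main_effects(self):
        df = _balanced_table(3)
        design = design_from_table(df, covariates=False)
        cell = (df.diagnosis + "-" + df.age_group).to_numpy()
        delta = {"ADHD-adolescent": 1.0, "ADHD-child": -1.0,
                 "HC-adolescent": -1.0, "HC-child": 1.0}
        y = np.array([delta[c] for c in cell])
        out = cg.glm_interaction(y[:, None], design)
        assert abs(out["t_main_diagnosis"].statistic[0]) < 1e-6
        assert abs(out["t_main_age"].statistic[0]) < 1e-6
        assert out["F_interaction"].statistic[0] > 1e10  # zero residual

    def test_row_exchange_invariance(self):
        rng = np.random.default_rng(2)
        df = _balanced_table(5)
        y = rng.standard_normal((len(df), 4))
        perm = rng.permutation(len(df))
        out1 = cg.glm_interaction(y, design_from_table(df, covariates=False))
        out2 = cg.glm_interaction(
            y[perm], design_from_table(df.iloc[perm].reset_index(drop=True),
                                       covariates=False)
        )
        np.testing.assert_allclose(
            out1["F_interaction"].statistic, out2["F_interaction"].statistic,
            atol=1e-9,
        )

    def test_rank_deficient_design_rejected(self):
        df = _balanced_table(3)
        df["site"] = "siteA"
        df.loc[df.diagnosis == "ADHD", "sex"] = "M"
        df.loc[df.diagnosis == "HC", "sex"] = "F"  # sex == diagnosis
        with pytest.raises(ValueError, match="rank"):
            design_from_table(df)


class TestMannWhitney:
    def test_complete_separation(self):
        res = cg.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.method == "exact"

    def test_identical_multisets_half_u(self):
        res = cg.mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.u_statistic == pytest.approx(4.5)  # n1*n2/2
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_exact_p_matches_enumeration(self, rng):
        for n1, n2 in [(2, 2), (3, 3), (4, 4), (5, 6), (3, 8)]:
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2)
            u_ref, p_ref = enumerate_u_pvalue(x, y)
            res = cg.mann_whitney(x, y)
            assert res.u_statistic == u_ref
            assert res.method == "exact"
            assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_spec_example_enumerated(self):
        res = cg.mann_whitney([1, 3], [2, 4])
        assert res.u_statistic == 1.0
        assert res.p_value == pytest.approx(2 / 3, abs=1e-12)

    def test_u_symmetry(self, rng):
        x = rng.standard_normal(12)
        y = rng.standard_normal(15)
        a = cg.mann_whitney(x, y)
        b = cg.mann_whitney(y, x)
        assert a.u_statistic + b.u_statistic == pytest.approx(12 * 15)

    def test_exact_close_to_normal_approx(self, rng):
        """Sanity band: enumeration and normal approximation agree within
        0.03 for n1 = n2 = 10 continuous samples."""
        from scipy.stats import mannwhitneyu

        for _ in range(5):
            x = rng.standard_normal(10)
            y = rng.standard_normal(10)
            p_exact = cg.mann_whitney(x, y).p_value
            p_norm = mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
            assert abs(p_exact - p_norm) < 0.03

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="empty"):
            cg.mann_whitney([], [1.0])


class TestPermutationCluster:
    @pytest.fixture(scope="class")
    def geometry(self):
        return sheet_mask(60, "m")

    def test_deterministic(self, geometry):
        rng = np.random.default_rng(5)
        df = _balanced_table(6)
        maps = rng.standard_normal((len(df), 60))
        design = design_from_table(df)
        a = cg.permutation_cluster(maps, design, "interaction", geometry,
                                   n_perm=120, seed=3)
        b = cg.permutation_cluster(maps, design, "interaction", geometry,
                                   n_perm=120, seed=3)
        assert [(c["size"], c["corrected_p"]) for c in a.clusters] == [
            (c["size"], c["corrected_p"]) for c in b.clusters
        ]

    def test_planted_focal_effect_detected(self, geometry):
        rng = np.random.default_rng(6)
        df = _balanced_table(12)
        cell = (df.diagnosis + "-" + df.age_group).to_numpy()
        maps = rng.standard_normal((len(df), 60))
        sign = {"ADHD-adolescent": 1.0, "ADHD-child": -1.0,
                "HC-adolescent": -1.0, "HC-child": 1.0}
        planted = np.arange(20, 32)  # contiguous block on the sheet
        maps[:, planted] += 2.0 * np.array([sign[c] for c in cell])[:, None]
        res = cg.permutation_cluster(maps, design_from_table(df), "interaction",
                                     geometry, n_perm=200, seed=1)
        sig = res.significant()
        assert sig
        best = max(sig, key=lambda c: c["size"])
        assert len(set(best["voxels"]) & set(planted)) >= 6

    def test_no_suprathreshold_returns_empty(self, geometry):
        df = _balanced_table(4)
        maps = np.random.default_rng(0).standard_normal((len(df), 60)) * 1e-6
        res = cg.permutation_cluster(maps, design_from_table(df), "interaction",
                                     geometry, cluster_z=50.0, n_perm=100, seed=0)
        assert res.clusters == []

    def test_corrected_p_monotone_in_size(self, geometry):
        rng = np.random.default_rng(9)
        df = _balanced_table(10)
        cell = (df.diagnosis + "-" + df.age_group).to_numpy()
        maps = rng.standard_normal((len(df), 60))
        sign = {"ADHD-adolescent": 1.0, "ADHD-child": -1.0,
                "HC-adolescent": -1.0, "HC-child": 1.0}
        maps[:, 5:25] += 1.5 * np.array([sign[c] for c in cell])[:, None]
        maps[:, 40:44] += 1.5 * np.array([sign[c] for c in cell])[:, None]
        res = cg.permutation_cluster(maps, design_from_table(df), "interaction",
                                     geometry, n_perm=150, seed=2)
        by_size = sorted(res.clusters, key=lambda c: c["size"])
        ps = [c["corrected_p"] for c in by_size]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


class TestPosthoc:
    def test_singleton_cluster_and_separation(self):
        df = _balanced_table(4)
        cell = (df.diagnosis + "-" + df.age_group).to_numpy()
        maps = np.zeros((len(df), 3))
        maps[cell == "ADHD-adolescent"] = 10.0 + np.arange(4)[:, None]
        maps[cell == "HC-adolescent"] = -10.0 - np.arange(4)[:, None]
        clusters = cg.ClusterResult(
            clusters=[{"voxels": np.array([1]), "size": 1, "peak_stat": 1.0,
                       "corrected_p": 0.01}],
            threshold_used=2.3, n_permutations=100, seed=0,
        )
        table = cg.posthoc_cluster_comparisons(maps, clusters, df)
        row = table[(table.group1 == "ADHD-adolescent")
                    & (table.group2 == "HC-adolescent")].iloc[0]
        assert row.u == 16  # complete separation: U = n1*n2
        assert row.p < 0.05
        # singleton cluster mean equals the voxel value
        assert (
            maps[cell == "ADHD-adolescent", 1].mean() == 10.0 + np.arange(4).mean()
        )
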