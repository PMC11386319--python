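"""Tests of the synthetic cohort generator and its planted structure."""

import numpy as np
import pytest
from scipy.stats import pearsonr

import ccgrad as cg
from ccgrad.synthetic import CELLS, network_indices


class TestPlantPositions:
    def test_no_effect_case_all_cells_identical(self):
        cfg = cg.CohortConfig(kappa=1.0, delta_dmn=0.0, delta_vn=0.0, seed=3)
        truths = [cg.plant_positions(cfg, c) for c in CELLS]
        for t in truths[1:]:
            np.testing.assert_array_equal(t.u, truths[0].u)
            np.testing.assert_array_equal(t.v, truths[0].v)

    def test_kappa_scales_positions_exactly(self):
        cfg = cg.CohortConfig(kappa=0.7, seed=3)
        hc = cg.plant_positions(cfg, "HC-child")
        adhd = cg.plant_positions(cfg, "ADHD-child")
        assert np.max(np.abs(adhd.u)) == pytest.approx(0.7 * np.max(np.abs(hc.u)))
        np.testing.assert_allclose(adhd.u, 0.7 * hc.u)

    def test_developmental_shift_means(self):
        cfg = cg.CohortConfig(delta_dmn=0.15, delta_vn=0.15, seed=3)
        child = cg.plant_positions(cfg, "HC-child")
        adol = cg.plant_positions(cfg, "HC-adolescent")
        dmn = child.shifted_sets["DMN"]
        vn = child.shifted_sets["VN"]
        # mean shift equals delta up to Monte-Carlo error of the base draw
        assert (adol.u[dmn] - child.u[dmn]).mean() == pytest.approx(0.15, abs=0.03)
        assert (adol.u[vn] - child.u[vn]).mean() == pytest.approx(-0.15, abs=0.03)
        # non-shifted networks untouched
        other = np.setdiff1d(np.arange(cfg.v_ctx), np.concatenate([dmn, vn]))
        np.testing.assert_array_equal(adol.u[other], child.u[other])

    def test_adhd_adolescent_omits_development(self):
        cfg = cg.CohortConfig(seed=4)
        np.testing.assert_array_equal(
            cg.plant_positions(cfg, "ADHD-adolescent").u,
            cg.plant_positions(cfg, "ADHD-child").u,
        )

    def test_unknown_cell_errors(self):
        with pytest.raises(ValueError, match="unknown design cell"):
            cg.plant_positions(cg.CohortConfig(), "HC-infant")

    def test_positions_cover_axis_continuously(self):
        """No gap wider than the sparsified support in the base positions."""
        cfg = cg.CohortConfig(seed=5)
        t = cg.plant_positions(cfg, "HC-child")
        gaps = np.diff(np.sort(t.u))
        assert gaps.max() < 0.15

    def test_network_labels_partition(self):
        t = cg.plant_positions(cg.CohortConfig(seed=1), "HC-child")
        assert set(np.unique(t.network_label)) == set(range(1, 8))
        dmn = network_indices(t.network_label, "DMN")
        vn = network_indices(t.network_label, "VN")
        assert t.u[dmn].mean() > 0.5
        assert t.u[vn].mean() < -0.5

    def test_planted_fr_scales_with_kappa(self):
        cfg = cg.CohortConfig(kappa=0.6, seed=9)
        hc = cg.plant_positions(cfg, "HC-child")
        adhd = cg.plant_positions(cfg, "ADHD-child")
        fr = lambda p: p.max() - p.min()
        assert fr(adhd.u) == pytest.approx(0.6 * fr(hc.u))


class TestSimulateTimeseries:
    def test_equal_positions_correlate_perfectly_without_noise(self):
        cfg = cg.CohortConfig(noise_sigma=0.0, seed=2, t_points=100)
        truth = cg.plant_positions(cfg, "HC-child")
        truth.u[1] = truth.u[0]  # duplicate position
        ts_ctx, _ = cg.simulate_timeseries(truth, cfg, np.random.default_rng(0))
        r = pearsonr(ts_ctx[:, 0], ts_ctx[:, 1]).statistic
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_cross_correlation_decays_with_distance(self):
        cfg = cg.CohortConfig(noise_sigma=0.0, seed=2, t_points=600)
        truth = cg.plant_positions(cfg, "HC-child")
        ts_ctx, ts_cb = cg.simulate_timeseries(truth, cfg, np.random.default_rng(1))
        i = int(np.argmin(truth.u))  # near -1
        j_far = int(np.argmax(truth.v))  # near +1
        j_near = int(np.argmin(np.abs(truth.v - truth.u[i])))
        r_far = pearsonr(ts_ctx[:, i], ts_cb[:, j_far]).statistic
        r_near = pearsonr(ts_ctx[:, i], ts_cb[:, j_near]).statistic
        assert r_far < r_near

    def test_deterministic_given_seed(self):
        cfg = cg.CohortConfig(seed=2, t_points=60)
        truth = cg.plant_positions(cfg, "HC-child")
        a = cg.simulate_timeseries(truth, cfg, np.random.default_rng(7))
        b = cg.simulate_timeseries(truth, cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_too_few_timepoints_error(self):
        cfg = cg.CohortConfig(seed=2)
        cfg.t_points = 20
        truth = cg.plant_positions(cfg, "HC-child")
        with pytest.raises(ValueError, match="t_points"):
            cg.simulate_timeseries(truth, cfg, np.random.default_rng(0))


class TestSimulateConnectivity:
    def test_matched_positions_give_tanh_z0(self):
        cfg = cg.CohortConfig(noise_sigma=0.0, seed=2)
        truth = cg.plant_positions(cfg, "HC-child")
        truth.v[0] = truth.u[0]
        r = cg.simulate_connectivity(truth, cfg, np.random.default_rng(0))
        assert r[0, 0] == pytest.approx(np.tanh(1.0), abs=1e-12)

    def test_noiseless_kernel_monotone_in_distance(self):
        cfg = cg.CohortConfig(noise_sigma=0.0, seed=2)
        truth = cg.plant_positions(cfg, "HC-child")
        r = cg.simulate_connectivity(truth, cfg, np.random.default_rng(0))
        i = 0
        d = np.abs(truth.u[i] - truth.v)
        order = np.argsort(d)
        assert (np.diff(r[i, order]) <= 1e-12).all()

    def test_noise_sd_matches_model(self):
        cfg = cg.CohortConfig(noise_sigma=0.1, seed=2)
        truth = cg.plant_positions(cfg, "HC-child")
        rng = np.random.default_rng(3)
        kernel = 1.0 * np.exp(-((truth.u[:, None] - truth.v[None, :]) ** 2) / 0.5)
        draws = np.stack(
            [
                np.arctanh(
                    np.clip(cg.simulate_connectivity(truth, cfg, rng), -1 + 1e-12, 1 - 1e-12)
                )
                for _ in range(200)
            ]
        )
        sd = (draws - kernel).std(axis=0).mean()
        assert abs(sd - 0.1) / 0.1 < 0.15


class TestSymptoms:
    def test_zero_slope_decouples_scores(self):
        cfg = cg.CohortConfig(symptom_slope=0.0, n_per_cell=15, seed=6,
                              mode="connectivity")
        cohort = cg.build_cohort(cfg)
        df = cohort.to_dataframe()
        hc = df[df.diagnosis == "HC"]
        region = {c: t.u[t.symptom_region].mean() for c, t in cohort.truth.items()}
        x = np.array([region[f"{d}-{a}"] for d, a in zip(hc.diagnosis, hc.age_group)])
        r, _ = pearsonr(x, hc.hyperactivity_impulsivity)
        # CI for r at n=30 comfortably contains 0 under the null
        assert abs(r) < 0.45

    def test_zero_noise_gives_perfect_negative_correlation(self):
        cfg = cg.CohortConfig(symptom_noise=0.0, symptom_slope=1.0, n_per_cell=8,
                              seed=6, mode="connectivity")
        cohort = cg.build_cohort(cfg)
        df = cohort.to_dataframe()
        hc = df[df.diagnosis == "HC"]
        region = {c: t.u[t.symptom_region].mean() for c, t in cohort.truth.items()}
        x = np.array([region[f"{d}-{a}"] for d, a in zip(hc.diagnosis, hc.age_group)])
        r, _ = pearsonr(x, hc.hyperactivity_impulsivity)
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_scores_nonnegative_and_adhd_higher(self):
        cohort = cg.build_cohort(
            cg.CohortConfig(n_per_cell=10, seed=6, mode="connectivity")
        )
        df = cohort.to_dataframe()
        assert (df.hyperactivity_impulsivity >= 0).all()
        assert (
            df[df.diagnosis == "ADHD"].hyperactivity_impulsivity.mean()
            > df[df.diagnosis == "HC"].hyperactivity_impulsivity.mean()
        )


class TestBuildCohort:
    def test_deterministic(self):
        cfg = cg.CohortConfig(n_per_cell=3, seed=8, mode="connectivity")
        a = cg.build_cohort(cfg)
        b = cg.build_cohort(cfg)
        assert a.to_dataframe().equals(b.to_dataframe())
        for rec in a.records:
            np.testing.assert_array_equal(a.data[rec.id], b.data[rec.id])

    def test_all_cells_filled_and_sites_present(self):
        cohort = cg.build_cohort(cg.CohortConfig(n_per_cell=5, seed=8,
                                                 mode="connectivity"))
        df = cohort.to_dataframe()
        assert set(df.diagnosis + "-" + df.age_group) == set(CELLS)
        assert set(df.site) == {"siteA", "siteB"}

    def test_age_bands_respected(self):
        df = cg.build_cohort(
            cg.CohortConfig(n_per_cell=5, seed=8, mode="connectivity")
        ).to_dataframe()
        child = df[df.age_group == "child"].age
        adol = df[df.age_group == "adolescent"].age
        assert ((child >= 7.0) & (child < 12.0)).all()
        assert ((adol >= 12.0) & (adol <= 18.0)).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            cg.CohortConfig(kappa=0.0)
        with pytest.raises(ValueError):
            cg.CohortConfig(n_per_cell=1)
        with pytest.raises(ValueError):
            cg.CohortConfig(network_centers={"A": 0.1, "B": 0.9})
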