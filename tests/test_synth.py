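"""Synthetic-data generators: determinism, calibration recovery, phantoms."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from fatvt.segmentation import classify_ct, classify_mri, mass_of
from fatvt.stats import anova_unbalanced, pearson_r, poisson_regression
from fatvt.substrate import HybridLabel, OverlapRegion
from fatvt.synth import (
    SynthConfig,
    draw_masses,
    gen_2d_substrate,
    gen_cohort_counts,
    gen_eam_points,
    gen_ventricle_images,
    latent_corr,
    lognormal_params,
    stream,
)


class TestConfig:
    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            SynthConfig(mass_corr=1.0)
        with pytest.raises(ValueError):
            SynthConfig(fat_mass_sd=0.0)
        with pytest.raises(ValueError):
            SynthConfig(overlap_fraction={"apex": 1.2})

    def test_degenerate_shell_rejected(self):
        from fatvt.synth.config import ShellSpec

        with pytest.raises(ValueError):
            SynthConfig(shell=ShellSpec(voxel_mm=12.0))

    def test_streams_order_independent(self):
        cfg = SynthConfig(seed=3)
        a1 = stream(cfg, 5, "images").normal(size=4)
        _ = stream(cfg, 0, "images").normal(size=100)
        a2 = stream(cfg, 5, "images").normal(size=4)
        np.testing.assert_array_equal(a1, a2)


class TestDeterminism:
    def test_images_bit_identical_for_same_seed(self, synth_config, one_heart):
        hu2, lge2, truth2 = gen_ventricle_images(synth_config, 0)
        np.testing.assert_array_equal(one_heart[0].data, hu2.data)
        np.testing.assert_array_equal(one_heart[1].data, lge2.data)
        np.testing.assert_array_equal(one_heart[2][0].data, truth2[0].data)

    def test_different_hearts_differ(self, synth_config, one_heart):
        hu2, _, _ = gen_ventricle_images(synth_config, 1)
        assert not np.array_equal(one_heart[0].data, hu2.data)

    def test_cohort_table_deterministic(self):
        cfg = SynthConfig(seed=11)
        t1 = gen_cohort_counts(cfg, 100)
        t2 = gen_cohort_counts(cfg, 100)
        pd.testing.assert_frame_equal(t1, t2)

    def test_eam_points_deterministic(self, synth_config, one_heart):
        p1 = gen_eam_points(one_heart[2], synth_config, 0)
        p2 = gen_eam_points(one_heart[2], synth_config, 0)
        np.testing.assert_array_equal(
            [p.activation_time for p in p1], [p.activation_time for p in p2]
        )


class TestCohortCalibration:
    def test_latent_corr_closed_form(self):
        # oracle: simulate the copula at large n and compare the Pearson r
        rng = np.random.default_rng(0)
        _, s1 = lognormal_params(19.0, 13.0)
        _, s2 = lognormal_params(26.3, 14.2)
        rho = latent_corr(0.639, s1, s2)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=400_000)
        r = np.corrcoef(np.exp(s1 * z[:, 0]), np.exp(s2 * z[:, 1]))[0, 1]
        assert r == pytest.approx(0.639, abs=0.01)

    def test_mass_moments_small_cohort(self):
        cfg = SynthConfig(seed=5)
        fat, scar = draw_masses(cfg, 24, stream(cfg, "m"))
        se = cfg.fat_mass_sd / np.sqrt(24)
        assert abs(fat.mean() - cfg.fat_mass_mean) < 3 * se

    def test_null_rate_ratios_give_flat_regression(self):
        cfg = SynthConfig(seed=5, vt_rate_ratio_per_5p55g=1.0,
                          scar_rate_ratio=1.0)
        df = gen_cohort_counts(cfg, 4000)
        res = poisson_regression(df.vt_count, df[["fat_g", "scar_g"]])
        assert abs(res.percent_per_increment["fat_g"]) < 1.5
        assert res.pvalues["fat_g"] > 0.01

    def test_poisson_recovery_of_configured_ratio(self):
        cfg = SynthConfig(seed=9)
        df = gen_cohort_counts(cfg, 5000)
        res = poisson_regression(df.vt_count, df[["fat_g", "scar_g"]])
        assert res.percent_per_increment["fat_g"] == pytest.approx(10.0, abs=2.0)


class TestImages:
    def test_segmentation_recovers_planted_truth(self, one_heart):
        hu, lge, (ct_t, mri_t) = one_heart
        ct = classify_ct(hu)
        mri = classify_mri(lge)
        m = hu.in_mask()
        assert np.mean(ct.data[m] == ct_t.data[m]) >= 0.99
        assert np.mean(mri.data[m] == mri_t.data[m]) >= 0.99

    def test_hu_values_inside_published_bands(self, one_heart):
        hu, _, (ct_t, _) = one_heart
        fat = np.asarray(ct_t.data) > 0
        vals = np.asarray(hu.data)[fat]
        assert vals.min() >= -180.0 - 5.0
        assert np.percentile(vals, 99) <= -5.0 + 10.0

    def test_planted_masses_near_latent_targets(self, one_heart):
        _, _, (ct_t, mri_t) = one_heart
        meta = ct_t.meta
        assert mass_of(ct_t, [1, 2]) == pytest.approx(
            meta["fat_target_g"], rel=0.05
        )
        assert mass_of(mri_t, [1, 2]) == pytest.approx(
            meta["scar_target_g"], rel=0.05
        )

    def test_heart_index_bound(self, synth_config):
        with pytest.raises(ValueError):
            gen_ventricle_images(synth_config, synth_config.cohort_n)


class TestEamGenerator:
    def test_equal_voltage_means_give_null_anova(self, synth_config, one_heart):
        from fatvt.synth.config import VoltageParams

        vp = VoltageParams(1.0, 0.4, 5.0, 1.5)
        cfg = dataclasses.replace(
            synth_config,
            voltage_params={k: vp for k in synth_config.voltage_params},
        )
        pts = gen_eam_points(one_heart[2], cfg, 0)
        groups = {}
        for p in pts:
            groups.setdefault(p.region.name, []).append(p.biv)
        f, p_val = anova_unbalanced(*[g for g in groups.values() if len(g) > 1])
        assert p_val > 0.01

    def test_no_slow_sites_no_crowding(self, synth_config, one_heart):
        from fatvt.eam import isochronal_crowding

        cfg = dataclasses.replace(synth_config, dz_overall_rate=0.004,
                                  eam_fat_slowdown=1.0)
        pts = gen_eam_points(one_heart[2], cfg, 0)
        slow = [p.meta["slow_site"] for p in pts]
        xyz = np.array([p.meta["surface_xyz"] for p in pts])
        times = np.array([p.activation_time for p in pts])
        counts, dz = isochronal_crowding(times, xyz)
        if not any(slow):
            assert dz.sum() == 0

    def test_voltage_distribution_ranking(self, synth_config, one_heart):
        pts = gen_eam_points(one_heart[2], synth_config, 0)
        biv = {}
        for p in pts:
            biv.setdefault(p.region.name, []).append(p.biv)
        if "inFAT_inScar" in biv and "no_remodeling" in biv:
            assert np.mean(biv["inFAT_inScar"]) < np.mean(biv["no_remodeling"])

    def test_ablation_prefers_low_voltage(self, synth_config, one_heart):
        pts = gen_eam_points(one_heart[2], synth_config, 0)
        low = [p.ablation for p in pts if p.biv <= 0.5]
        high = [p.ablation for p in pts if p.biv > 0.5]
        assert np.mean(low) > np.mean(high)


class TestSheets:
    def test_homogeneous_all_healthy(self):
        vol = gen_2d_substrate("homogeneous", SynthConfig())
        assert (np.asarray(vol.data) == int(HybridLabel.non_injured)).all()

    def test_dense_block_planted(self):
        vol = gen_2d_substrate("dense_block", SynthConfig())
        lab = np.asarray(vol.data)
        assert (lab == int(HybridLabel.dense_scar_only)).any()

    def test_channel_geometry_matches_config(self):
        cfg = SynthConfig()
        vol = gen_2d_substrate("channel", cfg)
        lab = np.asarray(vol.data)
        c0, c1 = vol.meta["corridor_cols"]
        r0, r1 = vol.meta["wall_rows"]
        mid = (r0 + r1) // 2
        row = lab[mid]
        corridor = row[c0:c1]
        assert (corridor == vol.meta["border_label"]).all()
        width_mm = (c1 - c0) * cfg.sheet_dx_mm
        assert width_mm == pytest.approx(cfg.channel_width_mm, abs=cfg.sheet_dx_mm)
        # corridor bounded by dense tissue on both sides
        assert row[c0 - 1] >= int(HybridLabel.dense_fat_only)
        assert row[c1] >= int(HybridLabel.dense_fat_only)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            gen_2d_substrate("swirl", SynthConfig())
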