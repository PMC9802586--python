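"""Isochrone binning, circuit components, UVC windows, CV measurement."""

import numpy as np
import pytest

from fatvt.circuits import (
    COMPONENT_OF_ISOCHRONE,
    ISTHMUS_ISOCHRONES,
    circuit_window,
    classify_components,
    component_composition,
    compute_isochrones,
    measure_cv,
)
from fatvt.segmentation import CtLabel, MriLabel
from fatvt.substrate import OverlapRegion


class TestIsochrones:
    def test_linear_ramp_equal_bins(self):
        act = np.linspace(0.0, 80.0, 161)  # 0..80 ms
        iso = compute_isochrones(act)
        assert iso[np.searchsorted(act, 5.0)] == 1
        assert iso[-1] == 8
        assert iso[np.searchsorted(act, 10.0)] == 1  # edge tie -> lower bin
        assert iso[np.searchsorted(act, 10.5)] == 2

    def test_bin_populations_conserve(self, rng):
        act = rng.uniform(0, 100, size=(20, 20))
        act[0, :5] = np.nan
        iso = compute_isochrones(act)
        assert (iso > 0).sum() == np.isfinite(act).sum()
        assert set(np.unique(iso[iso > 0])) <= set(range(1, 9))

    def test_degenerate_maps_raise(self):
        with pytest.raises(ValueError):
            compute_isochrones(np.full(5, np.nan))
        with pytest.raises(ValueError):
            compute_isochrones(np.full(5, 3.0))


def test_component_table_matches_stated_mapping():
    # exhaustive: the pure index -> component map
    expected = {1: "exit", 2: "outer_loop", 3: "outer_loop", 4: "entrance",
                5: "common_pathway", 6: "common_pathway",
                7: "common_pathway", 8: "common_pathway"}
    assert COMPONENT_OF_ISOCHRONE == expected
    assert ISTHMUS_ISOCHRONES == (6, 7)
    comp = classify_components(np.arange(9))
    assert comp[0] == ""
    for k in range(1, 9):
        assert comp[k] == expected[k]


class TestWindow:
    def test_periodic_rotational_inclusion(self):
        uvc = np.array([[0.5, 0.5, 350.0], [0.5, 0.5, 60.0],
                        [0.75, 0.5, 10.0], [0.31, 0.5, 10.0]])
        mask = circuit_window((0.5, 0.5, 10.0), uvc)
        assert mask[0]           # 20 deg periodic distance
        assert not mask[1]       # 50 deg away
        assert not mask[2]       # apicobasal distance 0.25 > 0.2
        assert mask[3]           # 0.19 away, inside

    def test_window_shift_invariance(self, rng):
        uvc = np.column_stack([rng.uniform(0, 1, 200),
                               rng.uniform(0, 1, 200),
                               rng.uniform(0, 360, 200)])
        m0 = circuit_window((0.5, 0.3, 100.0), uvc)
        shifted = uvc.copy()
        shifted[:, 2] = (shifted[:, 2] + 137.0) % 360.0
        m1 = circuit_window((0.5, 0.3, (100.0 + 137.0) % 360.0), shifted)
        np.testing.assert_array_equal(m0, m1)

    def test_window_monotone_in_halfwidths(self, rng):
        uvc = np.column_stack([rng.uniform(0, 1, 500),
                               rng.uniform(0, 1, 500),
                               rng.uniform(0, 360, 500)])
        sizes = [circuit_window((0.4, 0.5, 50.0), uvc, ab_halfwidth=a,
                                rot_halfwidth_deg=r).sum()
                 for a, r in ((0.1, 18.0), (0.2, 36.0), (0.4, 72.0))]
        assert sizes == sorted(sizes)


class TestComposition:
    def test_all_non_injured_gives_zero_masses(self):
        comp = np.full((10, 10), "", dtype="<U16")
        comp[2:4] = "exit"
        comp[5:7] = "common_pathway"
        ct = np.zeros((10, 10), dtype=int)
        mri = np.zeros((10, 10), dtype=int)
        isthmus = comp == "common_pathway"
        table, region = component_composition(comp, ct, mri, 1.0, isthmus)
        assert table["fat_mass_g"].sum() == 0.0
        assert region == OverlapRegion.no_remodeling

    def test_fat_only_isthmus_classified(self):
        comp = np.full((10, 10), "common_pathway", dtype="<U16")
        ct = np.full((10, 10), int(CtLabel.admixture))
        mri = np.zeros((10, 10), dtype=int)
        _, region = component_composition(comp, ct, mri, 1.0,
                                          np.ones((10, 10), bool))
        assert region == OverlapRegion.inFAT_noScar

    def test_component_masses_sum_to_window_mass(self, rng):
        iso = rng.integers(1, 9, size=(12, 12))
        comp = classify_components(iso)
        ct = rng.integers(0, 3, size=(12, 12))
        mri = rng.integers(0, 3, size=(12, 12))
        table, _ = component_composition(comp, ct, mri, 1.0)
        fat_total = np.isin(ct, (1, 2)).sum() * 1.0 * 1.055e-3
        assert table["fat_mass_g"].sum() == pytest.approx(fat_total)
        assert table["n_voxels"].sum() == 144


class TestMeasureCv:
    def test_planar_wave_path_speed(self):
        act = np.tile(np.arange(50.0) * 2.0, (5, 1))  # 0.5 mm/ms along axis 1
        path = np.column_stack([np.full(50, 2), np.arange(50)])
        cv = measure_cv(act, path=path, spacing=1.0)
        assert cv == pytest.approx(500.0)

    def test_region_gradient_speed(self):
        act = np.tile(np.arange(50.0) * 2.0, (5, 1))
        cv = measure_cv(act, spacing=1.0)
        assert cv == pytest.approx(500.0, rel=0.02)

    def test_stationary_and_nonmonotone_raise(self):
        act = np.zeros((5, 5))
        with pytest.raises(ValueError):
            measure_cv(act)
        ramp = np.tile(np.arange(10.0), (3, 1))
        bad_path = np.column_stack([np.full(10, 1), np.arange(10)[::-1]])
        with pytest.raises(ValueError):
            measure_cv(ramp, path=bad_path)
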