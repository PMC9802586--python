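"""Shell grids, universal ventricular coordinates, segments, fibers."""

import numpy as np
import pytest

from fatvt.geometry import (
    SEGMENT_NAMES,
    ShellParams,
    aha_segment,
    anatomical_segment,
    assign_fibers,
    build_shell_grid,
    compute_uvc,
    map_tags_via_uvc,
)


def test_transmural_layer_count():
    grid = build_shell_grid(ShellParams(80, 60, 10), 1.0)
    # at the basal rim (z ~ 0) the wall is 10 mm: >= 10 voxel layers
    eq = grid.mask[:, :, 0]
    xmid = grid.mask.shape[1] // 2
    run = eq[:, xmid]
    assert run.sum() >= 2 * 10  # two wall crossings along x


def test_shell_volume_converges_to_analytic():
    params = ShellParams(60, 48, 9)
    errs = []
    for h in (2.0, 1.0):
        grid = build_shell_grid(params, h)
        vox = grid.mask.sum() * h**3
        errs.append(abs(vox - grid.analytic_shell_volume_mm3())
                    / grid.analytic_shell_volume_mm3())
    assert errs[1] < errs[0]
    assert errs[1] < 0.05


def test_degenerate_shell_raises():
    with pytest.raises(ValueError):
        ShellParams(80, 60, 0.0)
    with pytest.raises(ValueError):
        build_shell_grid(ShellParams(80, 60, 9), 4.0)  # too coarse


def test_uvc_ranges_and_anchors(small_shell, small_uvc):
    m = small_shell.mask
    for arr, lo, hi in (
        (small_uvc.apicobasal, 0.0, 1.0),
        (small_uvc.transmural, 0.0, 1.0),
        (small_uvc.rotational, 0.0, 360.0),
    ):
        vals = arr[m]
        assert np.isfinite(vals).all()
        assert vals.min() >= lo - 1e-9
        assert vals.max() <= hi + 1e-9
    # apex voxel (deepest z) has apicobasal near 0
    idx = np.argwhere(m)
    z = idx[:, 2]
    apex_vox = tuple(idx[np.argmax(z)])
    assert small_uvc.apicobasal[apex_vox] < 0.15
    # basal rim (z=0) has apicobasal near 1
    rim_vox = tuple(idx[np.argmin(z)])
    assert small_uvc.apicobasal[rim_vox] > 0.9


def test_transmural_matches_bruteforce_distances(small_shell, small_uvc):
    """Normalized endo/epi distance oracle at a handful of voxels."""
    grid = small_shell
    endo_pts = grid.coords(np.argwhere(grid.cavity))
    epi_pts = grid.coords(np.argwhere(grid.outside))
    idx = np.argwhere(grid.mask)[:: max(1, grid.mask.sum() // 30)]
    xyz = grid.coords(idx)
    from scipy.spatial import cKDTree

    d_endo, _ = cKDTree(endo_pts).query(xyz)
    d_epi, _ = cKDTree(epi_pts).query(xyz)
    expected = d_endo / (d_endo + d_epi)
    got = small_uvc.transmural[tuple(idx.T)]
    assert np.allclose(got, expected, atol=0.12)


def test_rotational_opposite_of_lateral(small_shell, small_uvc):
    m = small_shell.mask
    idx = np.argwhere(m)
    xyz = small_shell.coords(idx)
    # voxels on the -x side (opposite the lateral +x anchor) -> rot ~ 180
    sel = (np.abs(xyz[:, 1]) < 2.0) & (xyz[:, 0] < -10)
    rots = small_uvc.rotational[tuple(idx[sel].T)]
    assert np.allclose(rots, 180.0, atol=10.0)


def test_anatomical_partition_exhaustive(small_uvc, small_shell):
    seg = anatomical_segment(small_uvc)
    m = small_shell.mask
    assert set(np.unique(seg[m])) <= set(SEGMENT_NAMES)
    assert (seg[m] != "").all()
    # exhaustive sweep over the UVC unit box
    ab, rot = np.meshgrid(np.linspace(0, 0.999, 40),
                          np.linspace(0, 359.9, 72))
    s = anatomical_segment(None, apicobasal=ab, rotational=rot)
    assert set(np.unique(s)) == set(SEGMENT_NAMES)


def test_anatomical_segment_examples():
    assert anatomical_segment(None, apicobasal=np.array(0.1),
                              rotational=np.array(200.0)).item() == "apex"
    assert anatomical_segment(None, apicobasal=np.array(0.9),
                              rotational=np.array(120.0)).item() == "basal_septal"


def test_aha_17_segments_all_present(small_uvc, small_shell):
    seg = aha_segment(small_uvc)
    present = set(np.unique(seg[small_shell.mask]))
    assert present == set(range(1, 18))


def test_aha_conventions():
    # apical cap -> 17; basal anterior sector -> 1
    assert aha_segment(None, apicobasal=np.array(0.05),
                       rotational=np.array(33.0)).item() == 17
    assert aha_segment(None, apicobasal=np.array(0.9),
                       rotational=np.array(30.0)).item() == 1


def test_fibers_unit_norm_tangent_and_helix(small_shell, small_uvc):
    f = assign_fibers(small_shell, small_uvc)
    norms = np.linalg.norm(f, axis=1)
    assert np.allclose(norms, 1.0, atol=1e-9)
    # midwall voxels (+/-60 deg rule -> 0 deg helix) are circumferential:
    # no z-component
    idx = np.argwhere(small_shell.mask)
    tm = small_uvc.transmural[tuple(idx.T)]
    mid = np.abs(tm - 0.5) < 0.02
    if mid.any():
        assert np.abs(f[mid][:, 2]).max() < 0.2


def test_map_tags_identity_and_periodicity(rng):
    uvc = np.column_stack([
        rng.uniform(0, 1, 50), rng.uniform(0, 1, 50), rng.uniform(0, 360, 50)
    ])
    tags = rng.integers(0, 5, 50)
    np.testing.assert_array_equal(map_tags_via_uvc(tags, uvc, uvc), tags)
    # wrap across the 0/360 seam
    src = np.array([[0.5, 0.5, 359.0], [0.5, 0.5, 180.0]])
    tgt = np.array([[0.5, 0.5, 1.0]])
    assert map_tags_via_uvc(np.array([7, 9]), src, tgt)[0] == 7


def test_map_tags_between_resolutions_preserves_blob_mass():
    coarse = build_shell_grid(ShellParams(60, 48, 9), 2.0)
    fine = build_shell_grid(ShellParams(60, 48, 9), 1.5)
    cu, fu = compute_uvc(coarse), compute_uvc(fine)
    ci = np.argwhere(coarse.mask)
    fi = np.argwhere(fine.mask)
    cu_pts = cu.stacked(ci)
    fu_pts = fu.stacked(fi)
    # plant a blob: apicobasal < 0.4 and rotational in [90, 180]
    tags = ((cu_pts[:, 0] < 0.4) & (cu_pts[:, 2] > 90)
            & (cu_pts[:, 2] < 180)).astype(int)
    mapped = map_tags_via_uvc(tags, cu_pts, fu_pts)
    vol_src = tags.sum() * 2.0**3
    vol_tgt = mapped.sum() * 1.5**3
    assert vol_tgt == pytest.approx(vol_src, rel=0.15)


def test_map_tags_empty_source():
    with pytest.raises(ValueError):
        map_tags_via_uvc(np.array([]), np.zeros((0, 3)), np.zeros((1, 3)))
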