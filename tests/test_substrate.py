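"""Hybrid label merge and overlap-region classification."""

import numpy as np
import pytest

from fatvt.segmentation import CtLabel, MriLabel
from fatvt.substrate import (
    HybridLabel,
    OverlapRegion,
    merge_labels,
    merge_label_volumes,
    overlap_statistics,
    region_at_point,
)
from fatvt.volume import TissueVolume


def test_merge_table_total_over_all_nine_pairs():
    seen = set()
    for ct in CtLabel:
        for mri in MriLabel:
            out = merge_labels(ct, mri)
            assert isinstance(out, HybridLabel)
            seen.add(out)
    assert seen == set(HybridLabel)  # all 7 classes reachable


@pytest.mark.parametrize(
    "ct,mri,expected",
    [
        (CtLabel.admixture, MriLabel.gray_zone, HybridLabel.fibrofatty),
        (CtLabel.non_injured, MriLabel.non_injured, HybridLabel.non_injured),
        (CtLabel.dense_fat, MriLabel.dense_scar, HybridLabel.dense_fat_and_scar),
        # dense-dominance rule for the combinations left open
        (CtLabel.dense_fat, MriLabel.gray_zone, HybridLabel.dense_fat_only),
        (CtLabel.admixture, MriLabel.dense_scar, HybridLabel.dense_scar_only),
    ],
)
def test_merge_examples(ct, mri, expected):
    assert merge_labels(ct, mri) == expected


def test_merge_unknown_label_raises():
    with pytest.raises(ValueError):
        merge_labels(5, 0)


def test_merge_volumes_matches_scalar_rule(rng):
    ct = rng.integers(0, 3, size=(5, 5, 5))
    mri = rng.integers(0, 3, size=(5, 5, 5))
    vol = merge_label_volumes(
        TissueVolume(ct, (1, 1, 1)), TissueVolume(mri, (1, 1, 1))
    )
    for idx in np.ndindex(3, 3, 3):
        assert vol.data[idx] == int(merge_labels(int(ct[idx]), int(mri[idx])))


def _point_fixture(fat_frac, scar_frac, n=21):
    """Cube with given inFAT / scar volume fractions around its center."""
    ct = np.zeros((n, n, n), dtype=int)
    mri = np.zeros((n, n, n), dtype=int)
    # spread the labelled voxels uniformly so any sphere sees ~ the target
    # volume fraction
    if fat_frac > 0:
        ct.flat[:: max(int(round(1.0 / fat_frac)), 1)] = int(CtLabel.admixture)
    if scar_frac > 0:
        mri.flat[:: max(int(round(1.0 / scar_frac)), 1)] = int(
            MriLabel.gray_zone
        )
    return (TissueVolume(ct, (1, 1, 1)), TissueVolume(mri, (1, 1, 1)))


@pytest.mark.parametrize(
    "fat,scar,expected",
    [
        (0.15, 0.12, OverlapRegion.inFAT_inScar),
        (0.09, 0.09, OverlapRegion.no_remodeling),
        (0.12, 0.00, OverlapRegion.inFAT_noScar),
        (0.00, 0.30, OverlapRegion.Scar_noFat),
    ],
)
def test_region_at_point_ten_percent_rule(fat, scar, expected):
    ct, mri = _point_fixture(fat, scar)
    center = np.array([10.5, 10.5, 10.5])
    assert region_at_point(center, ct, mri, radius_mm=12.0) == expected


def test_region_threshold_degenerate_cases():
    ct, mri = _point_fixture(0.01, 0.01)
    center = np.array([10.5, 10.5, 10.5])
    # threshold 0 degenerates to any-voxel-present
    assert region_at_point(center, ct, mri, radius_mm=12.0,
                           threshold=0.0) == OverlapRegion.inFAT_inScar
    # threshold > 1 can never be met
    assert region_at_point(center, ct, mri, radius_mm=12.0,
                           threshold=1.5) == OverlapRegion.no_remodeling
    with pytest.raises(ValueError):
        region_at_point(center, ct, mri, radius_mm=0.0)


def test_overlap_statistics_copresence(small_shell, small_uvc):
    from fatvt.geometry import anatomical_segment

    seg = anatomical_segment(small_uvc)
    ct = np.zeros(small_shell.mask.shape, dtype=int)
    mri = np.zeros_like(ct)
    ct[(seg == "apex") & small_shell.mask] = int(CtLabel.admixture)
    mri[(seg == "basal_septal") & small_shell.mask] = int(MriLabel.dense_scar)
    table = overlap_statistics(
        TissueVolume(ct, small_shell.spacing, small_shell.mask),
        TissueVolume(mri, small_shell.spacing, small_shell.mask),
        small_uvc,
    )
    assert not table.loc["apex", "both_present"]
    assert table.loc["apex", "fat_mass_g"] > 0
    assert table.loc["basal_septal", "scar_mass_g"] > 0
    assert not table.loc["basal_septal", "both_present"]


def test_overlap_statistics_identical_volumes(small_shell, small_uvc, rng):
    lab = np.zeros(small_shell.mask.shape, dtype=int)
    lab[small_shell.mask] = rng.integers(0, 2, size=small_shell.mask.sum())
    ct = TissueVolume(lab, small_shell.spacing, small_shell.mask)
    mri = TissueVolume(lab.copy(), small_shell.spacing, small_shell.mask)
    table = overlap_statistics(ct, mri, small_uvc)
    for _, row in table.iterrows():
        assert row["both_present"] == (row["fat_mass_g"] > 0)


def test_planted_overlap_fraction_recovered(synth_config):
    """Generator truth: forced full overlap yields fat entirely inside scar."""
    import dataclasses

    from fatvt.synth import gen_ventricle_images

    cfg = dataclasses.replace(
        synth_config,
        overlap_fraction={k: 1.0 for k in synth_config.overlap_fraction},
    )
    _, _, (ct_t, mri_t) = gen_ventricle_images(cfg, 1)
    fat = np.asarray(ct_t.data) > 0
    scar = np.asarray(mri_t.data) > 0
    assert fat.any()
    assert (fat & ~scar).sum() == 0

    cfg0 = dataclasses.replace(
        synth_config,
        overlap_fraction={k: 0.0 for k in synth_config.overlap_fraction},
    )
    _, _, (ct_t, mri_t) = gen_ventricle_images(cfg0, 1)
    fat = np.asarray(ct_t.data) > 0
    scar = np.asarray(mri_t.data) > 0
    assert fat.any()
    assert (fat & scar).sum() == 0


def test_modality_views_partition_hybrid_classes():
    from fatvt.substrate import modality_view

    lab = np.arange(7).reshape(1, 7).astype(np.int8)
    vol = TissueVolume(lab, (1.0, 1.0))
    ct = modality_view(vol, "ct").data[0]
    mri = modality_view(vol, "mri").data[0]
    # fibrofatty (3) is admixture on CT and gray zone on MRI
    assert ct[3] == int(HybridLabel.admixture_only)
    assert mri[3] == int(HybridLabel.gray_zone_only)
    # dense fat-and-scar (6) is dense on both
    assert ct[6] == int(HybridLabel.dense_fat_only)
    assert mri[6] == int(HybridLabel.dense_scar_only)
    # single-modality lesions vanish on the other side
    assert ct[2] == 0 and ct[5] == 0
    assert mri[1] == 0 and mri[4] == 0
    with pytest.raises(ValueError):
        modality_view(vol, "pet")
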