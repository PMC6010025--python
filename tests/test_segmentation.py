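import numpy as np
import pytest
from dataclasses import replace

from hifubreast import segmentation as seg
from hifubreast.segmentation import (
    TissueProperties,
    add_skin,
    air_breast_threshold,
    apply_air_mask,
    assign_properties,
    detect_interface,
    fat_gland_threshold,
    median_filter_3x3x3,
    segment,
    segment_pipeline,
)
from hifubreast.synthbreast import reference_phantoms, synthesize_breast_mri
from hifubreast.volume import BrightnessVolume, Tissue, TissueLabelVolume


def bv(values, voxel=1.0):
    return BrightnessVolume(np.asarray(values, dtype=float), voxel_mm=voxel)


# ---------------------------------------------------------------- median filter


def test_median_constant_unchanged():
    vol = bv(np.full((6, 6, 6), 42.0))
    assert np.array_equal(median_filter_3x3x3(vol).values, vol.values)


def test_median_removes_isolated_impulse():
    vals = np.zeros((7, 7, 7))
    vals[3, 3, 3] = 1000.0
    out = median_filter_3x3x3(bv(vals))
    assert out.values[3, 3, 3] == 0.0  # median of 26 zeros and one spike
    assert out.values.max() == 0.0


def test_median_preserves_linear_ramp_interior():
    ramp = np.tile(np.arange(10.0)[:, None, None], (1, 6, 6))
    out = median_filter_3x3x3(bv(ramp))
    np.testing.assert_allclose(out.values[1:-1], ramp[1:-1])


# ------------------------------------------------------------ air/breast split


def _brute_force_valley(values):
    """Independent oracle: explicit smoothed histogram and exhaustive scan."""
    counts, edges = np.histogram(values, bins=256)
    smooth = np.convolve(counts.astype(float), np.ones(5) / 5, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    maxima = []
    for i in range(len(smooth)):
        left = smooth[i - 1] if i else -np.inf
        right = smooth[i + 1] if i + 1 < len(smooth) else -np.inf
        if smooth[i] > left and smooth[i] > right:
            maxima.append(i)
    a, b = maxima[0], maxima[1]
    valley = a + 1 + int(np.argmin(smooth[a + 1 : b]))
    return centers[valley]


def test_air_threshold_two_value_volume():
    rng = np.random.default_rng(0)
    vals = np.concatenate(
        [rng.normal(0, 3, 4000).clip(0), rng.normal(300, 3, 4000)]
    ).reshape(20, 20, 20)
    thr = air_breast_threshold(bv(vals))
    assert 10 < thr < 290
    assert thr == pytest.approx(_brute_force_valley(vals.ravel()), abs=3.0)


def test_air_threshold_gaussian_mixture():
    rng = np.random.default_rng(42)
    n = 10**6
    vals = np.concatenate(
        [rng.normal(50, 10, int(0.3 * n)), rng.normal(300, 60, int(0.7 * n))]
    ).reshape(100, 100, 100)
    thr = air_breast_threshold(bv(vals))
    # the inter-mode valley is a near-empty plateau; the lower-bin tie rule
    # places the threshold at its low edge, a few counts above the air mode
    assert 80 <= thr <= 250
    assert np.mean(vals < thr) == pytest.approx(0.3, abs=0.02)
    assert thr == pytest.approx(_brute_force_valley(vals.ravel()), abs=3.0)


def test_air_threshold_constant_volume_errors():
    with pytest.raises(ValueError, match="air/breast"):
        air_breast_threshold(bv(np.full((5, 5, 5), 7.0)))


def test_apply_air_mask_counts():
    rng = np.random.default_rng(3)
    vals = rng.uniform(0, 100, (4, 4, 4))
    out = apply_air_mask(bv(vals), 50.0)
    assert (out.values == 0).sum() == (vals < 50.0).sum()
    assert np.array_equal(out.values[vals >= 50.0], vals[vals >= 50.0])
    # extremes
    assert np.all(apply_air_mask(bv(vals), 1000.0).values == 0)
    assert np.array_equal(apply_air_mask(bv(vals), -1.0).values, vals)


# --------------------------------------------------------- interface detection


def test_interface_half_space_slab():
    vals = np.zeros((16, 16, 16))
    vals[8:, :, :] = 200.0
    iface = detect_interface(bv(vals))
    # threshold B/2; the slab face plane is marked
    assert iface[8, :, :].all()
    assert not iface[9:-1, 1:-1, 1:-1].any()


def test_interface_sphere_within_one_voxel():
    n, r = 33, 10.0
    c = n // 2
    x = np.arange(n) - c
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    dist = np.sqrt(X**2 + Y**2 + Z**2)
    vals = np.where(dist <= r, 100.0, 0.0)
    iface = detect_interface(bv(vals, voxel=1.0))
    d = dist[iface]
    assert d.size > 0
    assert d.max() <= r + 0.5
    assert d.min() >= r - 1.2


def test_interface_interior_hole_not_marked():
    vals = np.zeros((24, 24, 24))
    vals[8:16, :, :] = 150.0
    vals[11:13, 10:14, 10:14] = 0.0  # cavity sealed inside the slab
    iface = detect_interface(bv(vals))
    hole = np.zeros_like(iface)
    hole[10:14, 9:15, 9:15] = True  # cavity plus its one-voxel shell
    hole[:10] = hole[14:] = False
    assert not (iface & hole).any()


def test_interface_empty_breast_errors():
    with pytest.raises(ValueError, match="empty"):
        detect_interface(bv(np.zeros((5, 5, 5))))


# ----------------------------------------------------------------- skin growth


def test_skin_flat_slab_three_layers():
    vals = np.zeros((24, 24, 24))
    vals[:, :, 12:] = 100.0
    vol = bv(vals, voxel=0.5)
    iface = detect_interface(vol)
    out = add_skin(vol, iface, thickness_mm=1.5)
    skin = out.values == -1.0
    # 1.5 mm at 0.5 mm voxels: exactly the 3 air layers next to the face
    assert skin[:, :, 9:12].all()
    assert skin.sum() == 24 * 24 * 3


def test_skin_hemisphere_shell_volume():
    r_mm, vox = 30.0, 0.5
    nxy, nz = 160, 80
    x = (np.arange(nxy) - nxy / 2) * vox
    z = np.arange(nz) * vox
    X, Y, Z = np.meshgrid(x, x, z, indexing="ij")
    dist = np.sqrt(X**2 + Y**2 + Z**2)
    vals = np.where(dist <= r_mm, 100.0, 0.0)
    vol = bv(vals, voxel=vox)
    iface = detect_interface(vol)
    out = add_skin(vol, iface, thickness_mm=1.5)
    count = (out.values == -1.0).sum()
    analytic = 2 * np.pi * r_mm**2 * 1.5 / vox**3  # hemispherical shell
    assert count == pytest.approx(analytic, rel=0.05)


def test_skin_subvoxel_thickness_marks_one_layer():
    vals = np.zeros((12, 12, 12))
    vals[:, :, 6:] = 100.0
    vol = bv(vals, voxel=0.5)
    iface = detect_interface(vol)
    out = add_skin(vol, iface, thickness_mm=0.4)
    skin = out.values == -1.0
    assert skin[:, :, 5].all()  # adjacent air layer always marked
    assert skin.sum() == 12 * 12


def test_skin_rejects_nonpositive_thickness():
    vals = np.zeros((6, 6, 6))
    vals[:, :, 3:] = 10.0
    vol = bv(vals)
    with pytest.raises(ValueError):
        add_skin(vol, detect_interface(vol), thickness_mm=0.0)


# --------------------------------------------------------------- fat threshold


def test_fat_threshold_uniform_interior():
    rng = np.random.default_rng(7)
    vals = rng.uniform(1e-6, 1000.0, (50, 50, 40))
    thr = fat_gland_threshold(bv(vals), 0.665)
    assert thr == pytest.approx(665.0, abs=10.0)
    achieved = (vals[vals > 0] < thr).mean()
    assert abs(achieved - 0.665) <= 0.005


def test_fat_threshold_three_valued_brute_force():
    vals = np.concatenate(
        [np.full(300, 100.0), np.full(400, 300.0), np.full(300, 500.0)]
    )
    rng = np.random.default_rng(1)
    rng.shuffle(vals)
    vol = bv(vals.reshape(10, 10, 10))
    thr = fat_gland_threshold(vol, 0.665)
    # exhaustive search over every possible cut value
    cuts = [50.0, 100.0, 300.0, 500.0, 501.0]
    best = min(cuts, key=lambda c: abs((vals < c).mean() - 0.665))
    assert (vals < thr).mean() == (vals < best).mean()


def test_fat_threshold_fraction_to_one_limit():
    vals = np.arange(1.0, 217.0).reshape(6, 6, 6)
    thr = fat_gland_threshold(bv(vals), 0.999)
    assert thr > 215.0  # everything but the top value is fat


def test_fat_threshold_invalid_fraction():
    with pytest.raises(ValueError):
        fat_gland_threshold(bv(np.ones((3, 3, 3))), 1.2)


# -------------------------------------------------------------------- labeling


def test_segment_is_total_partition():
    rng = np.random.default_rng(11)
    vals = rng.choice([0.0, -1.0, 120.0, 480.0], size=(8, 8, 8))
    lab = segment(bv(vals), air_thr=50.0, fat_thr=300.0)
    assert lab.labels.shape == vals.shape
    assert set(np.unique(lab.labels)) <= {0, 1, 2, 3}


def test_segment_matches_hand_computed_toy():
    vals = np.zeros((6, 6, 6))
    vals[1, 2, 3] = -1.0
    vals[2, 2, 2] = 100.0
    vals[3, 3, 3] = 500.0
    vals[4, 4, 4] = 400.0
    lab = segment(bv(vals), air_thr=50.0, fat_thr=400.0).labels
    expected = np.zeros((6, 6, 6), dtype=np.int16)  # WATER
    expected[1, 2, 3] = int(Tissue.SKIN)
    expected[2, 2, 2] = int(Tissue.FAT)  # 100 < 400
    expected[3, 3, 3] = int(Tissue.GLAND)  # 500 >= 400
    expected[4, 4, 4] = int(Tissue.GLAND)  # 400 >= 400
    assert np.array_equal(lab, expected)


def test_raising_fat_threshold_grows_fat_only():
    rng = np.random.default_rng(13)
    vals = rng.uniform(1.0, 1000.0, (10, 10, 10))
    vol = bv(vals)
    prev_fat = None
    for thr in (200.0, 400.0, 600.0, 1200.0):
        lab = segment(vol, air_thr=0.5, fat_thr=thr).labels
        fat = lab == int(Tissue.FAT)
        if prev_fat is not None:
            assert (prev_fat & ~fat).sum() == 0  # FAT never reverts to GLAND
        prev_fat = fat
    assert prev_fat.all()  # saturation: everything interior is fat


# --------------------------------------------------------- property assignment


def test_table_property_values():
    props = TissueProperties()
    assert (
        props.density[Tissue.WATER],
        props.sound_speed[Tissue.WATER],
        props.attenuation_db_m_mhz[Tissue.WATER],
    ) == (998.2, 1482.0, 0.22)
    assert props.density[Tissue.SKIN] == 1090.0
    assert props.sound_speed[Tissue.SKIN] == 1615.0


def test_impedance_row_three_decimals():
    props = TissueProperties()
    expected = {
        Tissue.SKIN: 1.760,
        Tissue.GLAND: 1.597,
        Tissue.FAT: 1.443,
        Tissue.WATER: 1.479,
    }
    for tissue, z in expected.items():
        assert round(props.impedance(tissue) / 1e6, 3) == z


def test_fat_attenuation_at_2mhz_in_np():
    lab = TissueLabelVolume(
        np.full((2, 2, 2), int(Tissue.FAT), dtype=np.int16), voxel_mm=0.5
    )
    med = assign_properties(lab)
    # 40 dB/m/MHz * 2 MHz = 80 dB/m = 9.21 Np/m
    assert med.alpha_np(2e6)[0, 0, 0] == pytest.approx(9.21, abs=0.01)


def test_assign_properties_rejects_unknown_label():
    lab = TissueLabelVolume(np.zeros((2, 2), dtype=np.int16), voxel_mm=0.5)
    lab.labels[0, 0] = 9  # bypass constructor validation
    with pytest.raises(ValueError, match="unknown"):
        assign_properties(lab)


def test_skin_attenuation_default_is_configurable():
    props = TissueProperties()
    assert props.attenuation_db_m_mhz[Tissue.SKIN] == 60.0
    props.attenuation_db_m_mhz[Tissue.SKIN] = 30.0
    lab = TissueLabelVolume(
        np.full((2, 2), int(Tissue.SKIN), dtype=np.int16), voxel_mm=0.5
    )
    assert assign_properties(lab, props).alpha0[0, 0] == 30.0


# ------------------------------------------------------------------ full chain


def test_pipeline_deterministic_and_fat_fraction(small_recipe):
    recipe, _ = reference_phantoms()[0]
    vol = synthesize_breast_mri(recipe)
    lab1 = segment_pipeline(vol)
    lab2 = segment_pipeline(vol)
    assert np.array_equal(lab1.labels, lab2.labels)
    fat = (lab1.labels == int(Tissue.FAT)).sum()
    gland = (lab1.labels == int(Tissue.GLAND)).sum()
    assert fat + gland > 10**5
    assert abs(fat / (fat + gland) - 0.665) <= 0.005
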