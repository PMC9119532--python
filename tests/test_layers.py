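"""Layer segmentation and layer metrics.

Constructed rasters give exact expectations; generated scenes provide
ground-truth recovery checks against the generator's vector mesh and
configured parameters.
"""

import dataclasses
import logging

import numpy as np
import pytest

from ectolayers import geometry, layers, synthgen
from ectolayers.imgio import BorderPair
from ectolayers.layers import (LOWER, LOWER_IM, MARKER_POS, PARABASAL,
                               SUPERFICIAL, UPPER, UPPER_IM, LayerConfig,
                               LayerMap3, LayerMap4, NetMask)


# ---------------------------------------------------------------------------
# constructed fixtures on the 100x100 rectangle band (rows 10..109, 1 um/px)
# ---------------------------------------------------------------------------

@pytest.fixture
def rect_depth(rect_mask, rect_borders):
    return geometry.depth_field(rect_mask, rect_borders)


def grid_net(shape=(120, 100), spacing=10):
    """Closed rectangular mesh: lines along rows 10,20..110 and cols 0,10..90,99."""
    net = np.zeros(shape, dtype=bool)
    for r in range(10, 111, spacing):
        net[r, 0:100] = True
    for c in list(range(0, 100, spacing)) + [99]:
        net[10:111, c] = True
    return net


def make_layermap4(depth, boundaries):
    d = depth.depth
    m = depth.mask
    labels = np.full(d.shape, -1, dtype=np.int8)
    b1, b2, b3 = boundaries
    labels[m & (d < b1)] = SUPERFICIAL
    labels[m & (d >= b1) & (d < b2)] = UPPER_IM
    labels[m & (d >= b2) & (d < b3)] = LOWER_IM
    labels[m & (d >= b3)] = PARABASAL
    return LayerMap4(labels=labels, boundaries=boundaries)


def test_segment_net_separable_modes(rect_mask):
    channel = np.full((120, 100), 10.0)
    net_true = grid_net()
    channel[net_true] = 200.0
    net = layers.segment_net(channel, rect_mask)
    np.testing.assert_array_equal(net.mask, net_true & rect_mask.mask)


def test_segment_net_flat_channel_empty(rect_mask, caplog):
    with caplog.at_level(logging.WARNING, logger="ectolayers.layers"):
        net = layers.segment_net(np.zeros((120, 100)), rect_mask)
    assert not net.mask.any()


@pytest.fixture
def wide_band():
    """Band spanning rows 0..119 so the interior grid mesh (rows 10..110)
    sits clear of the mask boundary; 12 depth bins align with cell rows."""
    bp = BorderPair(apical=[[0, 0], [0, 99]], basal=[[120, 0], [120, 99]],
                    um_per_px=1.0)
    mask = geometry.epithelium_mask((120, 100), bp)
    return mask, geometry.depth_field(mask, bp)


def test_intactness_flat_for_closed_grid(wide_band):
    mask, depth = wide_band
    net = NetMask(grid_net() & mask.mask, 1.0)
    prof = layers.intactness_profile(net, mask, depth,
                                     cell_diameter_um=11.0, n_bins=12)
    covered = prof.values[1:11]  # bins aligned with full mesh cells
    assert covered.max() - covered.min() <= 0.05
    assert covered.mean() == pytest.approx(0.81, abs=0.05)


def test_intactness_broken_upper_half_orders_bins(wide_band):
    mask, depth = wide_band
    net_true = grid_net()
    net_true[:60, :] = False  # wipe the mesh above depth 0.5
    net = NetMask(net_true & mask.mask, 1.0)
    prof = layers.intactness_profile(net, mask, depth,
                                     cell_diameter_um=11.0, n_bins=12)
    assert prof.values[1:6].mean() < prof.values[6:11].mean()
    assert prof.values[1:5].max() < 0.1


def test_intactness_requires_enough_bins(wide_band):
    mask, depth = wide_band
    net = NetMask(grid_net() & mask.mask, 1.0)
    with pytest.raises(ValueError, match="n_bins"):
        layers.intactness_profile(net, mask, depth, 11.0, n_bins=3)


def nuclei_channel(positions, shape=(120, 100), sigma=2.0, amp=1000.0):
    canvas = np.zeros(shape)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for r, c in positions:
        canvas += amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma ** 2))
    return canvas


def test_nucleus_profile_zero_when_empty(rect_mask, rect_depth):
    dens = layers.nucleus_density_profile(np.zeros((120, 100)), rect_mask,
                                          rect_depth, n_bins=10)
    np.testing.assert_array_equal(dens, np.zeros(10))


def test_nucleus_profile_contrast(rect_mask, rect_depth):
    rng = np.random.default_rng(0)
    sparse = [(rng.integers(12, 88), rng.integers(5, 95)) for _ in range(6)]
    dense = [(rng.integers(92, 108), rng.integers(5, 95)) for _ in range(60)]
    chan = nuclei_channel(sparse + dense)
    dens = layers.nucleus_density_profile(chan, rect_mask, rect_depth, n_bins=10)
    assert dens[8:].mean() >= 5 * max(dens[:8].mean(), 1e-9)


# ---------------------------------------------------------------------------
# four-layer segmentation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def spec_example_scene():
    """Scene with layer fractions (0.23, 0.24, 0.33, 0.20)."""
    params = synthgen.SceneParams(layer_fracs=(0.23, 0.24, 0.33, 0.20), seed=13)
    image, borders, gt = synthgen.generate_scene(params)
    mask = geometry.epithelium_mask(params.image_size_px, borders)
    depth = geometry.depth_field(mask, borders)
    return params, image, borders, gt, mask, depth


def segment_scene(image, mask, depth, cell_diameter_um=15.0):
    net = layers.segment_net(image["ecadherin"], mask)
    intact = layers.intactness_profile(net, mask, depth, cell_diameter_um)
    nucdens = layers.nucleus_density_profile(image["nuclei"], mask, depth)
    return net, layers.segment_four_layers(net, intact, nucdens, depth, mask)


def test_four_layer_boundaries_recovered(spec_example_scene):
    params, image, borders, gt, mask, depth = spec_example_scene
    _, lm = segment_scene(image, mask, depth)
    for got, true in zip(lm.boundaries, (0.23, 0.47, 0.80)):
        assert got == pytest.approx(true, abs=0.05)


def test_layer_labels_are_banded(spec_example_scene):
    """Labels are a non-decreasing step function of depth down each column."""
    params, image, borders, gt, mask, depth = spec_example_scene
    _, lm = segment_scene(image, mask, depth)
    for col in (64, 256, 448):
        lab = lm.labels[:, col]
        lab = lab[lab >= 0]
        assert np.all(np.diff(lab.astype(int)) >= 0)


def test_zero_broken_fraction_collapses_upper_im(spec_example_scene, scenes):
    image, borders, gt = scenes.scene("control_like", 21,
                                      broken_fraction_upper=0.0)
    params = gt.params
    mask = geometry.epithelium_mask(params.image_size_px, borders)
    depth = geometry.depth_field(mask, borders)
    _, lm = segment_scene(image, mask, depth)
    b1, b2, _ = lm.boundaries
    assert b2 - b1 <= 0.08
    assert any("empty" in w for w in lm.warnings)


def test_all_zero_junction_channel_gives_superficial_dominance(rect_mask,
                                                               rect_depth):
    net = layers.segment_net(np.zeros((120, 100)), rect_mask)
    rng = np.random.default_rng(1)
    dense = [(rng.integers(92, 108), rng.integers(5, 95)) for _ in range(60)]
    sparse = [(rng.integers(12, 88), rng.integers(5, 95)) for _ in range(6)]
    nucdens = layers.nucleus_density_profile(nuclei_channel(dense + sparse),
                                             rect_mask, rect_depth, n_bins=50)
    lm = layers.segment_four_layers(net, None, nucdens, rect_depth, rect_mask)
    b1, b2, b3 = lm.boundaries
    assert b1 == b2 == b3
    assert np.sum(lm.labels == UPPER_IM) == 0
    assert np.sum(lm.labels == LOWER_IM) == 0
    sup = np.sum(lm.labels == SUPERFICIAL)
    para = np.sum(lm.labels == PARABASAL)
    assert sup > 0 and para > 0
    assert sup + para == rect_mask.area_px()


def test_intactness_profile_tracks_vector_mesh(scenes):
    """Raster intactness per IM zone within 0.15 of the vector-mesh closure."""
    image, borders, gt = scenes.scene("control_like", 22,
                                      broken_fraction_upper=0.6)
    params = gt.params
    mask = geometry.epithelium_mask(params.image_size_px, borders)
    depth = geometry.depth_field(mask, borders)
    net = layers.segment_net(image["ecadherin"], mask)
    prof = layers.intactness_profile(net, mask, depth, params.mesh_cell_diameter_um)
    b1, b2, b3 = gt.layer_boundary_depths
    centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
    upper = prof.values[(centers >= b1) & (centers < b2)].mean()
    lower = prof.values[(centers >= b2) & (centers < b3)].mean()
    assert upper < lower
    closure = synthgen.mesh_closure_by_zone(gt, borders)
    assert upper == pytest.approx(closure["upper_im"], abs=0.15)
    assert lower == pytest.approx(closure["lower_im"], abs=0.15)


def test_net_mask_size_close_to_true_mesh(scenes):
    image, borders, gt = scenes.scene("control_like", 7)
    params = gt.params
    mask = geometry.epithelium_mask(params.image_size_px, borders)
    depth = geometry.depth_field(mask, borders)
    net = layers.segment_net(image["ecadherin"], mask)
    b1 = gt.layer_boundary_depths[0]
    sub = mask.mask & (depth.depth >= b1)
    true_px = gt.true_ecad_coverage_pct_by_layer["combined"] / 100.0 * sub.sum()
    assert 0.9 <= net.area_px() / true_px <= 1.1


# ---------------------------------------------------------------------------
# thickness / coverage / MFI
# ---------------------------------------------------------------------------

def test_rectangle_layer_thickness_quarters(rect_borders, rect_depth):
    lm = make_layermap4(rect_depth, (0.25, 0.5, 0.75))
    thick = layers.layer_thickness_um(lm, rect_borders)
    for name in ("superficial", "upper_im", "lower_im", "parabasal"):
        assert thick[name] == pytest.approx(25.0)
    assert thick["total"] == pytest.approx(100.0)


def test_layer_thicknesses_sum_to_total(scenes):
    image, borders, gt = scenes.scene("dmpa_like", 101)
    params = gt.params
    mask = geometry.epithelium_mask(params.image_size_px, borders)
    depth = geometry.depth_field(mask, borders)
    _, lm = segment_scene(image, mask, depth)
    thick = layers.layer_thickness_um(lm, borders)
    parts = sum(thick[n] for n in ("superficial", "upper_im", "lower_im",
                                   "parabasal"))
    assert parts == pytest.approx(thick["total"], rel=0.02)


def test_coverage_half_and_empty(rect_depth):
    lm = make_layermap4(rect_depth, (0.25, 0.5, 0.75))
    half = np.zeros((120, 100), dtype=bool)
    lower_im = lm.layer_mask(LOWER_IM)
    rows, cols = np.nonzero(lower_im)
    half[rows[: len(rows) // 2], cols[: len(rows) // 2]] = True
    net = NetMask(half, 1.0)
    assert layers.ecad_area_coverage_pct(net, lm, (LOWER_IM,)) == pytest.approx(50.0)
    empty = NetMask(np.zeros((120, 100), dtype=bool), 1.0)
    assert layers.ecad_area_coverage_pct(empty, lm, "combined") == pytest.approx(0.0)


def test_coverage_recovered_within_3_points(scenes):
    image, borders, gt = scenes.scene("control_like", 7)
    params = gt.params
    mask = geometry.epithelium_mask(params.image_size_px, borders)
    depth = geometry.depth_field(mask, borders)
    net, lm = segment_scene(image, mask, depth)
    cov = layers.ecad_area_coverage_pct(net, lm, "combined")
    assert cov == pytest.approx(gt.true_ecad_coverage_pct_by_layer["combined"],
                                abs=3.0)


def test_coverage_invariant_to_intensity_rescale(scenes):
    image, borders, gt = scenes.scene("control_like", 7)
    params = gt.params
    mask = geometry.epithelium_mask(params.image_size_px, borders)
    depth = geometry.depth_field(mask, borders)
    net1, lm1 = segment_scene(image, mask, depth)
    scaled = dict(image.channels)
    scaled["ecadherin"] = image["ecadherin"] * 3.7
    from ectolayers.imgio import MultiplexImage
    image2 = MultiplexImage(scaled, image.um_per_px, image.sample_id)
    net2, lm2 = segment_scene(image2, mask, depth)
    c1 = layers.ecad_area_coverage_pct(net1, lm1, "combined")
    c2 = layers.ecad_area_coverage_pct(net2, lm2, "combined")
    assert c1 == pytest.approx(c2, abs=0.2)


def test_layer_mfi_modes(rect_mask):
    region = rect_mask.mask
    chan = np.full((120, 100), 100.0)
    assert layers.layer_mfi(chan, region) == pytest.approx(100.0)
    chan2 = np.zeros((120, 100))
    rows, cols = np.nonzero(region)
    halfsel = np.zeros_like(region)
    halfsel[rows[: len(rows) // 2], cols[: len(rows) // 2]] = True
    chan2[halfsel] = 200.0
    assert layers.layer_mfi(chan2, region, mode="all") == pytest.approx(100.0)
    assert layers.layer_mfi(chan2, region, positive=chan2 > 0,
                            mode="positive_only") == pytest.approx(200.0)
    assert np.isnan(layers.layer_mfi(chan2, region & ~region))


# ---------------------------------------------------------------------------
# marker band
# ---------------------------------------------------------------------------

def test_marker_band_recovers_configured_interval(scenes):
    image, borders, gt = scenes.scene("dmpa_like", 101)  # band [0.40, 0.96]
    params = gt.params
    mask = geometry.epithelium_mask(params.image_size_px, borders)
    depth = geometry.depth_field(mask, borders)
    lm3 = layers.segment_marker_band(image["dsg1"], mask, depth)
    assert lm3.ok
    assert lm3.boundaries[0] == pytest.approx(0.40, abs=0.05)
    assert lm3.boundaries[1] == pytest.approx(0.96, abs=0.05)


def test_all_negative_marker_fails_not_crashes(rect_mask, rect_depth):
    lm3 = layers.segment_marker_band(np.zeros((120, 100)), rect_mask, rect_depth)
    assert not lm3.ok
    # pure-noise channel (stain absent, detector noise only) must also fail
    rng = np.random.default_rng(0)
    noise = np.clip(rng.normal(0, 150, (120, 100)), 0, None)
    noise = rng.poisson(noise * 0.05) / 0.05
    lm3n = layers.segment_marker_band(noise, rect_mask, rect_depth)
    assert not lm3n.ok


def test_full_depth_band_gives_all_marker_pos(rect_mask, rect_depth,
                                              rect_borders):
    chan = np.where(rect_mask.mask, 5000.0, 0.0)
    lm3 = layers.segment_marker_band(chan, rect_mask, rect_depth)
    assert lm3.ok
    rel = layers.relative_heights_pct(lm3, rect_borders)
    assert rel == pytest.approx((0.0, 100.0, 0.0), abs=0.5)
    assert np.sum(lm3.labels == UPPER) == 0
    assert np.sum(lm3.labels == LOWER) == 0


def test_relative_heights_direct_proportion(rect_mask, rect_depth, rect_borders):
    d = rect_depth.depth
    m = rect_depth.mask
    labels = np.full(d.shape, -1, dtype=np.int8)
    labels[m & (d < 0.38)] = UPPER
    labels[m & (d >= 0.38) & (d < 0.94)] = MARKER_POS
    labels[m & (d >= 0.94)] = LOWER
    lm3 = LayerMap3(labels=labels, boundaries=(0.38, 0.94))
    rel = layers.relative_heights_pct(lm3, rect_borders)
    assert rel == pytest.approx((38.0, 56.0, 6.0), abs=1e-9)
    assert sum(rel) == pytest.approx(100.0, abs=0.5)


def test_band_mfi_per_um2_arithmetic():
    # 6000 AU over a 60,000 um^2 band -> 0.1 AU/um^2
    shape = (300, 200)
    labels = np.full(shape, MARKER_POS, dtype=np.int8)
    lm3 = LayerMap3(labels=labels, boundaries=(0.0, 1.0))
    chan = np.full(shape, 6000.0)
    mfi, density = layers.band_mfi_per_um2(chan, lm3, um_per_px=1.0)
    assert mfi == pytest.approx(6000.0)
    assert density == pytest.approx(0.1)
    # doubling the pixel pitch at fixed pixel content quarters MFI/um^2
    _, density2 = layers.band_mfi_per_um2(chan, lm3, um_per_px=2.0)
    assert density2 == pytest.approx(density / 4.0)


def test_band_mfi_recovers_configured_mean(scenes):
    image, borders, gt = scenes.scene("control_like", 7)
    params = gt.params
    mask = geometry.epithelium_mask(params.image_size_px, borders)
    depth = geometry.depth_field(mask, borders)
    lm3 = layers.segment_marker_band(image["dsg1"], mask, depth)
    mfi, _ = layers.band_mfi_per_um2(image["dsg1"], lm3, params.um_per_px)
    assert mfi == pytest.approx(gt.true_band_mfi, rel=0.05)
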