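"""Counting workflow: opening, area filter, EDT, seeding, watershed."""

import numpy as np
import pytest
from scipy import ndimage

from ophiocount import (
    CountingConfig,
    SceneConfig,
    count_pipeline,
    distance_transform,
    filter_small,
    generate_scene,
    open_mask,
    seed_markers,
    watershed_count,
)
from ophiocount.quantify import elliptical_footprint

from conftest import draw_disc


def test_variant_paired_defaults():
    disc = CountingConfig.for_variant("disc")
    full = CountingConfig.for_variant("full")
    assert (disc.kernel_size, disc.min_area) == ((2, 2), 40)
    assert (full.kernel_size, full.min_area) == ((4, 4), 120)
    assert disc.edt_min_distance == full.edt_min_distance == 55
    assert disc.connectivity == 8


def test_elliptical_footprint_shapes():
    assert elliptical_footprint((2, 2)).all()  # degenerates to the full box
    fp4 = elliptical_footprint((4, 4))
    assert fp4.sum() == 12  # corners cut off
    assert not fp4[0, 0] and fp4[0, 1]


def test_opening_removes_isolated_pixel():
    mask = np.zeros((20, 20), dtype=bool)
    mask[10, 10] = True
    assert not open_mask(mask, CountingConfig()).any()


def test_opening_idempotent_on_large_square():
    mask = np.zeros((60, 60), dtype=bool)
    mask[5:55, 5:55] = True
    once = open_mask(mask, CountingConfig())
    twice = open_mask(once, CountingConfig())
    assert np.array_equal(once, twice)
    assert once.sum() >= 0.95 * mask.sum()


def test_opening_empty_mask():
    assert not open_mask(np.zeros((10, 10), dtype=bool), CountingConfig()).any()


def test_filter_small_strict_threshold():
    mask = np.zeros((30, 30), dtype=bool)
    mask[1:14, 1:4] = True  # 39 px
    assert not filter_small(mask, 40).any()
    mask[14, 1] = True  # exactly 40 px
    assert filter_small(mask, 40).sum() == 40


def test_filter_small_keeps_large_blob_only():
    mask = np.zeros((40, 60), dtype=bool)
    mask[2:8, 2:7] = True  # 30 px
    mask[15:35, 15:25] = True  # 200 px
    out = filter_small(mask, 40)
    assert out.sum() == 200
    assert not out[2:8, 2:7].any()


def test_edt_distance_to_corner():
    mask = np.ones((5, 5), dtype=bool)
    mask[0, 0] = False
    dist = distance_transform(mask)
    assert np.isclose(dist[2, 2], np.hypot(2, 2))
    assert dist[0, 0] == 0


def test_edt_empty_mask_all_zero():
    assert not distance_transform(np.zeros((6, 6), dtype=bool)).any()


def test_edt_disc_peak_matches_radius():
    mask = draw_disc((101, 101), (50, 50), 30)
    dist = distance_transform(mask)
    assert abs(dist.max() - 30) <= 1.0  # discretization slack
    peak = np.unravel_index(dist.argmax(), dist.shape)
    assert np.hypot(peak[0] - 50, peak[1] - 50) <= 1.5


def test_seed_markers_two_separated_discs():
    mask = draw_disc((200, 360), (100, 90), 30) | draw_disc((200, 360), (100, 240), 30)
    markers = seed_markers(distance_transform(mask), 55, mask=mask)
    assert markers.max() == 2


def test_seed_markers_merged_overlapping_discs():
    mask = draw_disc((200, 200), (100, 80), 30) | draw_disc((200, 200), (100, 120), 30)
    markers = seed_markers(distance_transform(mask), 55, mask=mask)
    assert markers.max() == 1  # centres 40 px apart < suppression distance


def test_seed_markers_empty():
    assert seed_markers(np.zeros((10, 10)), 55).max() == 0


def test_watershed_three_disjoint_discs():
    mask = (
        draw_disc((300, 300), (60, 60), 25)
        | draw_disc((300, 300), (60, 220), 25)
        | draw_disc((300, 300), (220, 140), 25)
    )
    dist = distance_transform(mask)
    markers = seed_markers(dist, 55, mask=mask)
    labels, report = watershed_count(mask, markers)
    assert report.blobs_detected == 3
    assert np.array_equal(labels > 0, mask)  # labels partition the foreground
    assert sorted(np.unique(labels)) == [0, 1, 2, 3]


def test_watershed_rejects_markers_outside_mask():
    mask = draw_disc((50, 50), (25, 25), 10)
    markers = np.zeros((50, 50), dtype=np.int32)
    markers[1, 1] = 1
    with pytest.raises(ValueError, match="inside the mask"):
        watershed_count(mask, markers)


def test_watershed_splits_overlapping_discs_against_nearest_seed_oracle():
    """Two fused discs (r=60, centres 100 px apart) split into 2 along the
    saddle; plain connected-component analysis sees a single blob.  The
    split is checked against an independent nearest-seed assignment."""
    shape = (260, 360)
    c1, c2 = (130, 130), (130, 230)
    mask = draw_disc(shape, c1, 60) | draw_disc(shape, c2, 60)
    assert ndimage.label(mask, structure=np.ones((3, 3)))[1] == 1

    labels, report = count_pipeline(mask, CountingConfig.for_variant("disc"))
    assert report.blobs_detected == 2

    yy, xx = np.mgrid[: shape[0], : shape[1]]
    nearest = np.where(
        np.hypot(yy - c1[0], xx - c1[1]) <= np.hypot(yy - c2[0], xx - c2[1]), 1, 2
    )
    fg = labels > 0
    match_direct = (labels[fg] == nearest[fg]).mean()
    agreement = max(match_direct, 1.0 - match_direct)  # label order is arbitrary
    assert agreement > 0.98


def test_pipeline_recovers_scene_count():
    cfg = SceneConfig(width=640, height=640, n_stars=20)
    scene = generate_scene(cfg, seed=7)
    _, report = count_pipeline(scene.mask_disc, CountingConfig.for_variant("disc"))
    assert report.blobs_detected == 20


def test_pipeline_empty_mask():
    labels, report = count_pipeline(np.zeros((100, 100), dtype=bool))
    assert report.blobs_detected == 0
    assert not labels.any()


def test_pipeline_ignores_single_pixel_noise():
    cfg = SceneConfig(width=512, height=512, n_stars=10)
    scene = generate_scene(cfg, seed=9)
    base = count_pipeline(scene.mask_disc, CountingConfig.for_variant("disc"))[1]
    noisy = scene.mask_disc.copy()
    rng = np.random.default_rng(0)
    # keep dots clear of real blobs so they stay isolated speckle
    safe = distance_transform(~scene.mask_disc) > 3
    ys, xs = np.where(safe)
    pick = rng.choice(len(ys), size=50, replace=False)
    noisy[ys[pick], xs[pick]] = True
    noisy_report = count_pipeline(noisy, CountingConfig.for_variant("disc"))[1]
    assert noisy_report.blobs_detected == base.blobs_detected == scene.true_count


def test_probability_input_is_thresholded():
    prob = np.zeros((120, 120), dtype=float)
    prob[30:90, 30:90] = 0.9
    _, report = count_pipeline(prob, CountingConfig.for_variant("disc"), threshold=0.5)
    assert report.blobs_detected == 1


def test_min_area_monotonicity():
    """Raising the area threshold can only reduce the blob count."""
    rng = np.random.default_rng(1)
    shape = (400, 400)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(12):
        c = rng.integers(30, 370, 2)
        mask |= draw_disc(shape, tuple(c), rng.integers(3, 12))
    counts = [
        count_pipeline(mask, CountingConfig(min_area=a))[1].blobs_detected
        for a in (0, 20, 40, 120, 400)
    ]
    assert counts == sorted(counts, reverse=True)


def test_report_intermediate_bookkeeping():
    mask = draw_disc((200, 200), (100, 100), 20)
    mask[5, 5] = True  # speckle removed by opening
    _, report = count_pipeline(mask, CountingConfig.for_variant("disc"))
    assert report.blobs_detected == 1
    assert report.pixels_removed_by_opening >= 1
    assert report.n_markers == 1
    assert report.config.min_area == 40
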