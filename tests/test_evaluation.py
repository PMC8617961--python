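"""Pixel IOU, truncated count ratios, instance matching and forgiving mode."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ophiocount import (
    AnnotationSet,
    ConfusionCounts,
    CountingConfig,
    InstanceMatchReport,
    PolygonAnnotation,
    SceneConfig,
    confusion,
    count_pipeline,
    count_ratio,
    evaluate,
    forgiving_adjust,
    generate_scene,
    iou,
    match_instances,
    rasterize,
)


def square(x0, y0, x1, y1, variant="disc"):
    return PolygonAnnotation(
        vertices=((x0, y0), (x1, y0), (x1, y1), (x0, y1)), variant=variant
    )


# ---------------------------------------------------------------------------
# confusion and IOU


def test_confusion_identical_masks():
    mask = np.random.default_rng(0).random((20, 20)) > 0.5
    c = confusion(mask, mask)
    assert c.fp == c.fn == 0
    assert c.tp == mask.sum()


def test_confusion_all_foreground_vs_all_background():
    pred = np.ones((5, 5), dtype=bool)
    truth = np.zeros((5, 5), dtype=bool)
    c = confusion(pred, truth)
    assert c.fp == 25 and c.tp == c.fn == c.tn == 0


def test_confusion_enumerated_2x2():
    pred = np.array([[1, 0], [0, 0]], dtype=bool)
    truth = np.array([[1, 1], [0, 0]], dtype=bool)
    c = confusion(pred, truth)
    assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 0, 2)


def test_confusion_shape_mismatch():
    with pytest.raises(ValueError):
        confusion(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


def test_iou_formula_and_edges():
    assert iou(ConfusionCounts(tp=50, fp=25, fn=25, tn=0)) == 0.5
    assert iou(ConfusionCounts(tp=10, fp=0, fn=0, tn=5)) == 1.0
    assert iou(ConfusionCounts(tp=0, fp=3, fn=0, tn=5)) == 0.0
    with pytest.raises(ValueError):
        iou(ConfusionCounts(tp=0, fp=0, fn=0, tn=9))


@given(st.integers(0, 500), st.integers(0, 500), st.integers(1, 500))
def test_iou_symmetric_under_fp_fn_swap(fp, fn, tp):
    a = iou(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0))
    b = iou(ConfusionCounts(tp=tp, fp=fn, fn=fp, tn=0))
    assert a == b


# ---------------------------------------------------------------------------
# count ratio


@pytest.mark.parametrize(
    "detected,ground_truth,expected",
    [(393, 500, 0.786), (337, 361, 0.933), (377, 457, 0.824), (342, 362, 0.944),
     (100, 100, 1.000)],
)
def test_count_ratio_truncates_to_three_decimals(detected, ground_truth, expected):
    assert count_ratio(detected, ground_truth) == expected


def test_count_ratio_truncation_not_rounding():
    # 337/361 = 0.93351...; rounding would print 0.934
    assert count_ratio(337, 361) == 0.933
    assert count_ratio(1999, 1000) == 1.999


def test_count_ratio_zero_ground_truth():
    with pytest.raises(ValueError):
        count_ratio(5, 0)


@given(st.integers(0, 2000), st.integers(1, 2000))
def test_count_ratio_truncation_bound(detected, ground_truth):
    r = count_ratio(detected, ground_truth)
    exact = detected / ground_truth
    assert 0 <= exact - r < 1e-3


# ---------------------------------------------------------------------------
# instance matching


def _labels_from_squares(shape, squares):
    labels = np.zeros(shape, dtype=np.int32)
    for i, (x0, y0, x1, y1) in enumerate(squares, start=1):
        labels[y0 : y1 + 1, x0 : x1 + 1] = i
    return labels


def test_perfect_prediction_matches_all():
    cfg = SceneConfig(width=640, height=640, n_stars=20)
    scene = generate_scene(cfg, seed=11)
    labels, _ = count_pipeline(scene.mask_disc, CountingConfig.for_variant("disc"))
    report = match_instances(labels, scene.annotations_disc)
    assert report.n_matched == 20
    assert report.strict_fp == 0 and report.strict_fn == 0


def test_spurious_blob_is_false_positive():
    truth = AnnotationSet("m", "disc", "a", [square(10, 10, 30, 30)])
    labels = _labels_from_squares((100, 100), [(10, 10, 30, 30), (60, 60, 80, 80)])
    report = match_instances(labels, truth)
    assert report.n_matched == 1
    assert report.strict_fp == 1 and report.strict_fn == 0


def test_two_blobs_in_one_annotation_greedy_one_to_one():
    truth = AnnotationSet("m", "disc", "a", [square(10, 10, 50, 50)])
    labels = _labels_from_squares((100, 100), [(12, 12, 30, 30), (35, 35, 48, 48)])
    report = match_instances(labels, truth)
    assert report.n_matched == 1
    assert report.strict_fp == 1  # the smaller-overlap blob stays unmatched
    assert report.strict_fn == 0


def test_missed_annotation_is_false_negative():
    truth = AnnotationSet(
        "m", "disc", "a", [square(10, 10, 30, 30), square(60, 60, 80, 80)]
    )
    labels = _labels_from_squares((100, 100), [(10, 10, 30, 30)])
    report = match_instances(labels, truth)
    assert report.strict_fn == 1 and report.strict_fp == 0


# ---------------------------------------------------------------------------
# forgiving adjustment


def test_forgiving_excludes_fp_on_organism_arm():
    # full shape is a big square, disc only its center; a predicted blob on
    # the "arm" region (inside full, outside disc) is excluded in forgiving
    full = AnnotationSet("m", "full", "a", [square(10, 10, 60, 60, "full")])
    disc = AnnotationSet("m", "disc", "a", [square(30, 30, 40, 40)])
    labels = _labels_from_squares((100, 100), [(12, 12, 22, 22)])  # on the arm
    strict = match_instances(labels, disc)
    assert strict.strict_fp == 1
    adjusted = forgiving_adjust(strict, labels, disc, full, disc)
    assert adjusted.forgiving_fp == 0
    assert adjusted.strict_fp == 1  # strict totals unchanged


def test_forgiving_excludes_fn_with_invisible_disc():
    cfg = SceneConfig(width=640, height=640, n_stars=10, hide_disc=True)
    scene = generate_scene(cfg, seed=3)
    # evaluate against the FULL truth with an empty prediction: all FN;
    # exactly one organism has no visible disc and is excluded
    labels = np.zeros(scene.shape, dtype=np.int32)
    strict = match_instances(labels, scene.annotations_full)
    assert strict.strict_fn == 10
    adjusted = forgiving_adjust(
        strict, labels, scene.annotations_full,
        scene.annotations_full, scene.annotations_disc,
    )
    assert adjusted.forgiving_fn == 9


def test_forgiving_noop_without_errors():
    truth = AnnotationSet("m", "disc", "a", [square(10, 10, 30, 30)])
    labels = _labels_from_squares((100, 100), [(10, 10, 30, 30)])
    report = match_instances(labels, truth)
    full = AnnotationSet("m", "full", "a", [square(10, 10, 30, 30, "full")])
    adjusted = forgiving_adjust(report, labels, truth, full, truth)
    assert adjusted.forgiving_fp == adjusted.strict_fp == 0
    assert adjusted.forgiving_fn == adjusted.strict_fn == 0


def test_forgiving_never_exceeds_strict():
    rep = InstanceMatchReport(
        n_matched=5, fp_blobs=[1, 2, 3], fn_instances=[0, 1],
        fp_excluded=[1], fn_excluded=[0],
    )
    assert rep.forgiving_fp <= rep.strict_fp
    assert rep.forgiving_fn <= rep.strict_fn
    assert (rep.forgiving_fp, rep.forgiving_fn) == (2, 1)


def test_published_forgiving_arithmetic():
    """Exclusions applied to the strict totals reproduce the printed
    forgiving totals: 45-27=18 and 82-39=43 false positives."""
    m1 = InstanceMatchReport(
        n_matched=0, fp_blobs=list(range(45)), fn_instances=list(range(7)),
        fp_excluded=list(range(27)), fn_excluded=list(range(2)),
    )
    assert m1.forgiving_fp == 18 and m1.forgiving_fn == 5
    m2 = InstanceMatchReport(
        n_matched=0, fp_blobs=list(range(82)), fn_instances=list(range(6)),
        fp_excluded=list(range(39)), fn_excluded=list(range(4)),
    )
    assert m2.forgiving_fp == 43 and m2.forgiving_fn == 2


# ---------------------------------------------------------------------------
# evaluate


def test_evaluate_self_comparison_is_perfect():
    cfg = SceneConfig(width=640, height=640, n_stars=15)
    scene = generate_scene(cfg, seed=5)
    report = evaluate(
        scene.mask_disc, scene.annotations_disc,
        config=CountingConfig.for_variant("disc"),
    )
    assert report.iou == 1.0
    assert report.count_ratio == 1.0
    assert report.blobs_detected == report.ground_truth_count == 15


def test_evaluate_empty_prediction_all_false_negatives():
    cfg = SceneConfig(width=512, height=512, n_stars=8)
    scene = generate_scene(cfg, seed=2)
    report = evaluate(
        np.zeros(scene.shape), scene.annotations_disc,
        config=CountingConfig.for_variant("disc"),
    )
    assert report.iou == 0.0
    assert report.blobs_detected == 0
    assert report.instance_report.strict_fn == 8


def test_evaluate_includes_forgiving_when_both_variants_given():
    cfg = SceneConfig(width=512, height=512, n_stars=6)
    scene = generate_scene(cfg, seed=4)
    report = evaluate(
        scene.mask_disc, scene.annotations_disc,
        config=CountingConfig.for_variant("disc"),
        full_truth=scene.annotations_full,
        disc_truth=scene.annotations_disc,
    )
    assert report.instance_report.forgiving_fp <= report.instance_report.strict_fp


def test_evaluate_report_serializes(tmp_path):
    cfg = SceneConfig(width=512, height=512, n_stars=5)
    scene = generate_scene(cfg, seed=6)
    report = evaluate(scene.mask_disc, scene.annotations_disc)
    out = tmp_path / "report.json"
    report.write_json(out)
    import json

    loaded = json.loads(out.read_text())
    assert loaded["iou"] == 1.0
    assert loaded["blobs_detected"] == 5
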