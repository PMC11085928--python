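"""Classical segmentation: tiling, thresholds, watershed, overlap metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from infiltra import (
    SegConfig,
    StackParams,
    generate_stack,
    overlap_metrics,
    dice_loss,
    segment_layer,
    segment_stack,
    tile_image,
    reassemble_tiles,
)


def _draw_disk(image, cy, cx, r, value=1.0):
    yy, xx = np.mgrid[: image.shape[0], : image.shape[1]]
    image[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = value


# ---------------------------------------------------------------------------
# tiling


def test_tiling_2048_no_overlap():
    image = np.zeros((2048, 2048), np.float32)
    tiles = tile_image(image, 1024, 0)
    assert len(tiles) == 4
    assert sorted((t.y0, t.x0) for t in tiles) == [(0, 0), (0, 1024), (1024, 0), (1024, 1024)]


def test_tiling_pads_small_image_and_crops_back():
    image = np.random.default_rng(0).random((1000, 1000)).astype(np.float32)
    tiles = tile_image(image, 1024, 0)
    assert len(tiles) == 1
    assert tiles[0].data.shape == (1024, 1024)
    out = reassemble_tiles(tiles, image.shape)
    np.testing.assert_array_equal(out, image)


@settings(derandomize=True, deadline=None, max_examples=20)
@given(
    h=st.integers(70, 400),
    w=st.integers(70, 400),
    tile=st.sampled_from([64, 128, 200]),
    overlap=st.sampled_from([0, 16, 32]),
)
def test_tiling_round_trip(h, w, tile, overlap):
    rng = np.random.default_rng(h * 1000 + w)
    image = rng.random((h, w)).astype(np.float32)
    out = reassemble_tiles(tile_image(image, tile, overlap), image.shape)
    np.testing.assert_array_equal(out, image)


def test_tile_overlap_must_be_smaller():
    with pytest.raises(ValueError):
        tile_image(np.zeros((100, 100)), 64, 64)


# ---------------------------------------------------------------------------
# segment_layer


def test_segment_three_separated_nuclei():
    params = StackParams(n_nuclei=3, width_px=128, height_px=128, seed=2,
                         noise_sd=0.01)
    stack, truth = generate_stack(params)
    focal = int(truth.table.layer.mode()[0]) if len(truth.table) else 0
    # use the layer holding the most in-focus nuclei
    counts = truth.layer_counts
    focal = int(np.argmax(counts))
    mask = segment_layer(stack.layer(focal), SegConfig(intensity_threshold=0.3))
    assert mask.n_objects == counts[focal]


def test_blank_noise_layer_yields_nothing():
    rng = np.random.default_rng(3)
    noise = (0.03 + rng.normal(0, 0.02, (128, 128))).astype(np.float32)
    mask = segment_layer(noise, SegConfig(min_area_px=30))
    assert mask.n_objects == 0


def test_watershed_splits_touching_pair():
    image = np.zeros((96, 96), np.float32)
    _draw_disk(image, 48, 38, 9, 0.9)
    _draw_disk(image, 48, 56, 9, 0.9)  # touching: centres 18 px apart, r=9
    on = segment_layer(image, SegConfig(intensity_threshold=0.4, watershed_split=True))
    off = segment_layer(image, SegConfig(intensity_threshold=0.4, watershed_split=False))
    assert on.n_objects == 2
    assert off.n_objects == 1


def test_segmentation_deterministic(small_stack):
    _, stack, _ = small_stack
    m1 = segment_stack(stack)
    m2 = segment_stack(stack)
    for a, b in zip(m1, m2):
        np.testing.assert_array_equal(a.labels, b.labels)


def test_labels_consecutive(small_stack):
    _, stack, _ = small_stack
    for m in segment_stack(stack):
        labels = np.unique(m.labels)
        np.testing.assert_array_equal(labels, np.arange(labels.max() + 1))


def test_tiled_equals_whole_image_fixed_threshold():
    """Tile-wise thresholding with overlap must match whole-image output
    for objects away from tile borders."""
    rng = np.random.default_rng(5)
    image = (0.03 + rng.normal(0, 0.01, (300, 300))).astype(np.float32)
    for cy, cx in [(40, 40), (40, 250), (250, 40), (250, 250), (150, 150)]:
        _draw_disk(image, cy, cx, 7, 0.9)
    whole = segment_layer(image, SegConfig(intensity_threshold=0.4))
    tiled = segment_layer(image, SegConfig(intensity_threshold=0.4, tile_size_px=128,
                                           tile_overlap_px=64))
    assert tiled.n_objects == whole.n_objects == 5
    np.testing.assert_array_equal(tiled.labels > 0, whole.labels > 0)


# ---------------------------------------------------------------------------
# overlap metrics


def test_metrics_identity():
    m = np.zeros((8, 8), bool)
    m[2:5, 2:5] = True
    assert overlap_metrics(m, m) == (1.0, 1.0)


def test_metrics_disjoint():
    a = np.zeros((8, 8), bool); a[:2] = True
    b = np.zeros((8, 8), bool); b[6:] = True
    assert overlap_metrics(a, b) == (0.0, 0.0)


def test_metrics_hand_counted_case():
    # A = 2x2 block (4 px), B = 1x2 half of it: inter 2, union 4
    a = np.zeros((4, 4), bool); a[1:3, 1:3] = True
    b = np.zeros((4, 4), bool); b[1, 1:3] = True
    iou, dice = overlap_metrics(a, b)
    assert iou == pytest.approx(0.5)
    assert dice == pytest.approx(2 / 3)
    assert dice_loss(a, b) == pytest.approx(1 / 3)


def test_metrics_empty_convention():
    e = np.zeros((4, 4), bool)
    assert overlap_metrics(e, e) == (1.0, 1.0)


def test_metrics_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        overlap_metrics(np.zeros((3, 3)), np.zeros((4, 4)))


@settings(derandomize=True, deadline=None, max_examples=50)
@given(st.integers(0, 2**32 - 1))
def test_metrics_symmetry_and_ordering(seed):
    """IOU <= dice, both in [0,1], symmetric in the arguments."""
    rng = np.random.default_rng(seed)
    a = rng.random((12, 12)) > 0.6
    b = rng.random((12, 12)) > 0.6
    iou_ab, dice_ab = overlap_metrics(a, b)
    iou_ba, dice_ba = overlap_metrics(b, a)
    assert iou_ab == iou_ba and dice_ab == dice_ba
    assert 0 <= iou_ab <= dice_ab <= 1
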