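"""Focus scoring, SSIM, and cross-layer chaining/deduplication."""

import itertools

import numpy as np
import pytest
from scipy import ndimage as ndi

from infiltra import (
    LinkConfig,
    StackParams,
    build_count_profile,
    focus_score,
    generate_stack,
    link_and_assign,
    score_against_truth,
    segment_stack,
    ssim_score,
)
from infiltra.linking import NucleusRecord, _patch_similarity, extract_detections, records_to_frame


def _nucleus_patch(seed=0, size=32):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[:size, :size] - size / 2
    patch = 0.9 * ((yy / 8) ** 2 + (xx / 5) ** 2 <= 1).astype(float)
    return patch + rng.normal(0, 0.01, patch.shape)


# ---------------------------------------------------------------------------
# focus


def test_focus_constant_patch_zero():
    assert focus_score(np.full((16, 16), 0.5)) == 0.0


def test_focus_blur_reduces_score():
    sharp = _nucleus_patch()
    blurred = ndi.gaussian_filter(sharp, 2.0)
    assert focus_score(sharp) > focus_score(blurred)
    assert focus_score(sharp, "tenengrad") > focus_score(blurred, "tenengrad")


def test_focus_argmax_is_true_layer():
    params = StackParams(n_nuclei=1, width_px=96, height_px=96, seed=21,
                         noise_sd=0.01)
    stack, truth = generate_stack(params)
    row = truth.table.iloc[0]
    y, x = int(row.y_px), int(row.x_px)
    scores = [focus_score(stack.layer(l)[y - 10 : y + 10, x - 10 : x + 10])
              for l in range(stack.n_layers)]
    assert int(np.argmax(scores)) == int(row.layer)


# ---------------------------------------------------------------------------
# SSIM


def test_ssim_identity():
    p = _nucleus_patch()
    assert ssim_score(p, p) == pytest.approx(1.0)


def test_ssim_negative_for_inverted_patch():
    # period-7 sine: every 7x7 window has exactly zero mean, so the
    # (negative) structure term dominates and is not masked by luminance
    x = np.arange(35)
    p = np.tile(np.sin(2 * np.pi * x / 7), (35, 1))
    assert ssim_score(p, -p, data_range=2.0) < 0


def test_ssim_independent_noise_near_zero():
    rng = np.random.default_rng(0)
    scores = [ssim_score(rng.normal(size=(32, 32)), rng.normal(size=(32, 32)))
              for _ in range(20)]
    assert abs(float(np.mean(scores))) < 0.05


def test_ssim_window_too_large_rejected():
    with pytest.raises(ValueError, match="window"):
        ssim_score(np.zeros((5, 5)), np.zeros((5, 5)), window_px=7)


def test_ssim_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        ssim_score(np.zeros((8, 8)), np.zeros((9, 9)))


# ---------------------------------------------------------------------------
# linking


def test_single_nucleus_one_record(small_stack):
    params, stack, truth = small_stack
    records = link_and_assign(stack, segment_stack(stack))
    score = score_against_truth(records, truth)
    assert score["n_records"] == score["n_truth"]
    assert score["n_duplicate_truth"] == 0
    assert score["layer_accuracy"] >= 0.95


def test_two_distant_nuclei_same_layer_two_records():
    params = StackParams(n_nuclei=2, width_px=160, height_px=160, seed=33,
                         depth_distribution="surface", depth_params={"k_per_um": 1e6})
    stack, truth = generate_stack(params)
    records = link_and_assign(stack, segment_stack(stack))
    assert len(records) == 2
    assert all(r.assigned_layer == 0 for r in records)


def test_partition_property(small_stack):
    """Every detection belongs to exactly one record."""
    _, stack, _ = small_stack
    masks = segment_stack(stack)
    per_layer = extract_detections(stack, masks)
    n_detections = sum(len(d) for d in per_layer)
    records = link_and_assign(stack, masks)
    members = list(itertools.chain.from_iterable(r.member_detections for r in records))
    assert len(members) == n_detections
    assert len(set(members)) == n_detections
    # no double counting: records <= raw detections
    assert len(records) <= n_detections


def test_assigned_layer_is_sharpest_member(small_stack):
    _, stack, _ = small_stack
    masks = segment_stack(stack)
    per_layer = extract_detections(stack, masks)
    focus_of = {(d.layer_index, d.label): d.focus for d in itertools.chain.from_iterable(per_layer)}
    for r in link_and_assign(stack, masks):
        best = max(r.member_detections, key=lambda m: focus_of[m])
        assert focus_of[(r.assigned_layer, dict(r.member_detections).get(r.assigned_layer))] == \
            pytest.approx(focus_of[best])


# ---------------------------------------------------------------------------
# exhaustive oracle for the grouping optimiser


def _oracle_groups(per_layer, config):
    """Brute-force optimal chaining over a <=3-layer stack.

    Enumerates every combination of one-to-one matchings between
    consecutive layers (adjacent links only) and returns the grouping with
    maximal total SSIM.  Independent of the production assignment solver.
    """
    def pair_scores(layer_a, layer_b):
        out = {}
        for i, d1 in enumerate(layer_a):
            for j, d2 in enumerate(layer_b):
                dist = np.hypot(d1.centroid_xy[0] - d2.centroid_xy[0],
                                d1.centroid_xy[1] - d2.centroid_xy[1])
                if dist <= config.max_centroid_shift_px:
                    s = _patch_similarity(d1, d2, config)
                    if s >= config.ssim_threshold:
                        out[(i, j)] = s
        return out

    def all_matchings(pairs, n_a, n_b):
        edges = list(pairs.items())
        results = []

        def rec(k, used_a, used_b, chosen):
            if k == len(edges):
                results.append(list(chosen))
                return
            (i, j), s = edges[k]
            rec(k + 1, used_a, used_b, chosen)
            if i not in used_a and j not in used_b:
                rec(k + 1, used_a | {i}, used_b | {j}, chosen + [((i, j), s)])

        rec(0, frozenset(), frozenset(), [])
        return results

    layer_pairs = [pair_scores(per_layer[l], per_layer[l + 1])
                   for l in range(len(per_layer) - 1)]
    options = [all_matchings(p, len(per_layer[l]), len(per_layer[l + 1]))
               for l, p in enumerate(layer_pairs)]
    best, best_score = None, -1.0
    for combo in itertools.product(*options):
        score = sum(s for matching in combo for _, s in matching)
        if score > best_score + 1e-12:
            best, best_score = combo, score
    # build partition
    parent = {}
    for l, dets in enumerate(per_layer):
        for i, d in enumerate(dets):
            parent[(l, i)] = (l, i)

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for l, matching in enumerate(best):
        for (i, j), _ in matching:
            parent[find((l + 1, j))] = find((l, i))
    groups = {}
    for l, dets in enumerate(per_layer):
        for i, d in enumerate(dets):
            groups.setdefault(find((l, i)), set()).add((d.layer_index, d.label))
    return set(frozenset(g) for g in groups.values()), best_score


@pytest.mark.parametrize("seed", range(12))
def test_linking_matches_exhaustive_oracle(seed):
    """The assignment-based chaining equals brute-force optimal grouping."""
    params = StackParams(n_layers=3, n_nuclei=int(3 + seed % 3), width_px=128,
                         height_px=128, seed=100 + seed, blur_growth=0.8)
    stack, _ = generate_stack(params)
    masks = segment_stack(stack)
    config = LinkConfig(max_layer_gap=0)
    per_layer = extract_detections(stack, masks, config)
    oracle, oracle_score = _oracle_groups(per_layer, config)
    records = link_and_assign(stack, masks, config)
    got = set(frozenset(r.member_detections) for r in records)
    # compare on the detections the oracle saw
    seen = set(itertools.chain.from_iterable(oracle))
    got = set(frozenset(m for m in g if m in seen) for g in got)
    got.discard(frozenset())
    assert got == oracle


# ---------------------------------------------------------------------------
# count profile


def test_count_profile_empty():
    profile = build_count_profile([], 4)
    assert profile.counts.tolist() == [0, 0, 0, 0]
    assert profile.c_summ == 0


def test_count_profile_counting():
    recs = [NucleusRecord(i, layer, layer * 7.0, (0, 0), 50, 1.5, 1.0, [(layer, 1)])
            for i, layer in enumerate([0, 0, 3])]
    profile = build_count_profile(recs, 4)
    assert profile.counts.tolist() == [2, 0, 0, 1]
    assert profile.c_summ == 3


def test_count_profile_rejects_out_of_range():
    rec = NucleusRecord(0, 9, 63.0, (0, 0), 50, 1.5, 1.0, [(9, 1)])
    with pytest.raises(ValueError, match="outside"):
        build_count_profile([rec], 4)


def test_records_frame_schema(small_stack):
    _, stack, _ = small_stack
    records = link_and_assign(stack, segment_stack(stack))
    df = records_to_frame(records)
    assert list(df.columns) == ["nucleus_id", "assigned_layer", "depth_um", "x_px",
                                "y_px", "area_px", "axis_ratio", "focus",
                                "n_member_layers"]
    assert (df["depth_um"] == df["assigned_layer"] * stack.layer_spacing_um).all()
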