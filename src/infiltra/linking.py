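"""Focus scoring, SSIM matching, and assignment of nuclei to focal layers.

A nucleus is visible in several consecutive z-layers but sharp in only
one.  Detections from neighbouring layers are compared by centroid
distance and SSIM of their intensity patches; matching detections are
chained into one group per physical nucleus, and each group is assigned
to its sharpest (maximum focus score) member layer, so no nucleus is
counted twice.  Matching between consecutive layers is solved as an
optimal one-to-one assignment (maximising total SSIM), which makes the
result deterministic and, for adjacent-only links, globally optimal.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from skimage.measure import regionprops
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .io import ImageStack
from .kinetics import CountProfile
from .segmentation import LayerMask

FOCUS_MEASURES = ("laplacian_variance", "tenengrad")


@dataclasses.dataclass
class LinkConfig:
    """Cross-layer matching settings.

    Detections in consecutive layers are candidate matches when their
    centroids are within ``max_centroid_shift_px`` and the SSIM of their
    patches is at least ``ssim_threshold``.  ``max_layer_gap`` = 1 lets a
    chain bridge one missed layer.  Defaults: matching radius of about
    half a typical nucleus major axis (the centroid of one nucleus drifts
    only a pixel or two between focal planes, while a full-axis radius
    would let a touching neighbour capture the chain), SSIM window 7 px,
    threshold 0.5.
    """

    max_centroid_shift_px: float = 6.0
    ssim_threshold: float = 0.5
    ssim_window_px: int = 7
    focus_measure: str = "laplacian_variance"
    max_layer_gap: int = 1
    patch_margin_px: int = 4

    def __post_init__(self) -> None:
        if self.max_centroid_shift_px <= 0:
            raise ValueError("max_centroid_shift_px must be positive")
        if self.ssim_window_px % 2 == 0 or self.ssim_window_px < 3:
            raise ValueError("ssim_window_px must be odd and >= 3")
        if not -1 <= self.ssim_threshold <= 1:
            raise ValueError("ssim_threshold must be in [-1, 1]")
        if self.focus_measure not in FOCUS_MEASURES:
            raise ValueError(f"focus_measure must be one of {FOCUS_MEASURES}")
        if self.max_layer_gap < 0:
            raise ValueError("max_layer_gap must be non-negative")


@dataclasses.dataclass
class DetectedObject:
    """One segmented blob in one layer, before deduplication."""

    layer_index: int
    label: int
    centroid_xy: tuple[float, float]  # (x, y) px
    area_px: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    focus: float
    patch: np.ndarray
    major_px: float = 0.0
    minor_px: float = 0.0


@dataclasses.dataclass
class NucleusRecord:
    """One physical nucleus, assigned to its single in-focus layer."""

    nucleus_id: int
    assigned_layer: int
    depth_um: float
    centroid_xy: tuple[float, float]
    area_px: int
    major_minor_ratio: float
    focus: float
    member_detections: list[tuple[int, int]]  # (layer_index, label)

    @property
    def n_member_layers(self) -> int:
        return len(self.member_detections)


# ---------------------------------------------------------------------------
# focus and similarity scores


def focus_score(patch: np.ndarray, measure: str = "laplacian_variance") -> float:
    """Sharpness of an intensity patch; larger = sharper, 0 for constants.

    ``laplacian_variance`` (default) is the variance of the Laplacian
    response; ``tenengrad`` is the mean squared Sobel gradient magnitude.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or min(patch.shape) < 3:
        raise ValueError("patch must be 2-D and at least 3x3")
    if measure == "laplacian_variance":
        return float(np.var(ndi.laplace(patch)))
    if measure == "tenengrad":
        gx = ndi.sobel(patch, axis=1)
        gy = ndi.sobel(patch, axis=0)
        return float(np.mean(gx**2 + gy**2))
    raise ValueError(f"unknown focus measure {measure!r}")


def ssim_score(patch_a: np.ndarray, patch_b: np.ndarray, window_px: int = 7,
               data_range: float | None = None) -> float:
    """Mean structural similarity between two equally sized patches.

    Standard SSIM with the usual stabilising constants (K1=0.01, K2=0.03
    on the dynamic range), averaged over sliding windows.
    """
    a = np.asarray(patch_a, dtype=np.float64)
    b = np.asarray(patch_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("patches must have the same shape")
    if window_px > min(a.shape):
        raise ValueError(
            f"SSIM window ({window_px}) larger than patch {a.shape}"
        )
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo
        if data_range == 0:  # two constant patches
            return 1.0 if np.allclose(a, b) else -1.0
    return float(structural_similarity(a, b, win_size=window_px, data_range=data_range))


def _patch_similarity(d1: DetectedObject, d2: DetectedObject, config: LinkConfig) -> float:
    """SSIM of two detections' patches resized to a common window."""
    h = max(d1.patch.shape[0], d2.patch.shape[0], config.ssim_window_px)
    w = max(d1.patch.shape[1], d2.patch.shape[1], config.ssim_window_px)
    p1 = resize(d1.patch, (h, w), order=1, preserve_range=True, anti_aliasing=False)
    p2 = resize(d2.patch, (h, w), order=1, preserve_range=True, anti_aliasing=False)
    return ssim_score(p1, p2, config.ssim_window_px)


# ---------------------------------------------------------------------------
# detection extraction


def extract_detections(stack: ImageStack, masks: Sequence[LayerMask],
                       config: LinkConfig | None = None) -> list[list[DetectedObject]]:
    """Turn per-layer label masks into per-layer detection lists."""
    config = config or LinkConfig()
    if len(masks) != stack.n_layers:
        raise ValueError("need exactly one mask per layer")
    per_layer: list[list[DetectedObject]] = []
    m = config.patch_margin_px
    for mask in masks:
        image = stack.layer(mask.layer_index)
        dets = []
        for prop in regionprops(mask.labels, intensity_image=image):
            r0, c0, r1, c1 = prop.bbox
            rr0, cc0 = max(0, r0 - m), max(0, c0 - m)
            rr1 = min(image.shape[0], r1 + m)
            cc1 = min(image.shape[1], c1 + m)
            patch = np.ascontiguousarray(image[rr0:rr1, cc0:cc1], dtype=np.float32)
            cy, cx = prop.centroid
            minor = max(prop.axis_minor_length, 1.0)  # floor at one pixel
            dets.append(
                DetectedObject(
                    layer_index=mask.layer_index,
                    label=int(prop.label),
                    centroid_xy=(float(cx), float(cy)),
                    area_px=int(prop.area),
                    bbox=(r0, c0, r1, c1),
                    focus=focus_score(patch, config.focus_measure)
                    if min(patch.shape) >= 3 else 0.0,
                    patch=patch,
                    major_px=float(prop.axis_major_length),
                    minor_px=float(minor),
                )
            )
        per_layer.append(dets)
    return per_layer


# ---------------------------------------------------------------------------
# chaining and assignment


def _match_pair(groups: list[dict], dets: list[DetectedObject],
                config: LinkConfig) -> list[tuple[int, int]]:
    """Optimal one-to-one matching (max total SSIM) between open groups
    and this layer's detections; ineligible pairs are excluded."""
    if not groups or not dets:
        return []
    scores = np.full((len(groups), len(dets)), -np.inf)
    for gi, g in enumerate(groups):
        tail: DetectedObject = g["members"][-1]
        for di, d in enumerate(dets):
            dist = np.hypot(tail.centroid_xy[0] - d.centroid_xy[0],
                            tail.centroid_xy[1] - d.centroid_xy[1])
            if dist > config.max_centroid_shift_px:
                continue
            s = _patch_similarity(tail, d, config)
            if s >= config.ssim_threshold:
                scores[gi, di] = s
    if not np.any(np.isfinite(scores)):
        return []
    cost = np.where(np.isfinite(scores), -scores, 1e6)
    rows, cols = linear_sum_assignment(cost)
    return [(gi, di) for gi, di in zip(rows, cols) if np.isfinite(scores[gi, di])]


def link_and_assign(stack: ImageStack, masks: Sequence[LayerMask],
                    config: LinkConfig | None = None) -> list[NucleusRecord]:
    """Chain detections across layers and assign each chain to one layer.

    Layers are scanned in acquisition order.  Detections join the group
    whose most recent member (in the previous layer, or up to
    ``max_layer_gap`` layers back for a second pass) is within the
    matching radius and above the SSIM threshold; assignment per layer
    pair maximises total SSIM.  Every detection ends up in exactly one
    group; each group becomes a NucleusRecord assigned to its sharpest
    member (ties go to the smaller layer index).
    """
    config = config or LinkConfig()
    per_layer = extract_detections(stack, masks, config)
    groups: list[dict] = []
    for l, dets in enumerate(per_layer):
        unmatched = list(range(len(dets)))
        for gap in range(1, config.max_layer_gap + 2):
            if l - gap < 0 or not unmatched:
                break
            open_groups = [g for g in groups if g["last_layer"] == l - gap]
            cand = [dets[i] for i in unmatched]
            for gi, di in _match_pair(open_groups, cand, config):
                g = open_groups[gi]
                d = cand[di]
                g["members"].append(d)
                g["last_layer"] = l
                unmatched[di] = -1  # placeholder, filtered below
            unmatched = [i for i, d in zip(unmatched, cand) if i >= 0]
        for i in unmatched:
            groups.append({"members": [dets[i]], "last_layer": l})

    records = []
    order = sorted(range(len(groups)),
                   key=lambda gi: (groups[gi]["members"][0].layer_index,
                                   groups[gi]["members"][0].label))
    for nid, gi in enumerate(order):
        members: list[DetectedObject] = groups[gi]["members"]
        best = max(members, key=lambda d: (d.focus, -d.layer_index))
        records.append(
            NucleusRecord(
                nucleus_id=nid,
                assigned_layer=best.layer_index,
                depth_um=best.layer_index * stack.layer_spacing_um,
                centroid_xy=best.centroid_xy,
                area_px=best.area_px,
                major_minor_ratio=best.major_px / best.minor_px
                if best.minor_px > 0 else float("nan"),
                focus=best.focus,
                member_detections=[(d.layer_index, d.label) for d in members],
            )
        )
    return records


def build_count_profile(records: Sequence[NucleusRecord], n_layers: int,
                        layer_spacing_um: float = 7.0,
                        day: float | None = None) -> CountProfile:
    """Per-layer counts C_z (and total C_summ) from deduplicated records."""
    counts = np.zeros(n_layers, dtype=np.int64)
    for r in records:
        if not 0 <= r.assigned_layer < n_layers:
            raise ValueError(f"record {r.nucleus_id} assigned to layer "
                             f"{r.assigned_layer} outside [0, {n_layers})")
        counts[r.assigned_layer] += 1
    return CountProfile(counts, layer_spacing_um=layer_spacing_um, day=day)


# ---------------------------------------------------------------------------
# CSV export of in-focus objects


def records_to_frame(records: Sequence[NucleusRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "nucleus_id": r.nucleus_id,
                "assigned_layer": r.assigned_layer,
                "depth_um": r.depth_um,
                "x_px": r.centroid_xy[0],
                "y_px": r.centroid_xy[1],
                "area_px": r.area_px,
                "axis_ratio": r.major_minor_ratio,
                "focus": r.focus,
                "n_member_layers": r.n_member_layers,
            }
            for r in records
        ],
        columns=["nucleus_id", "assigned_layer", "depth_um", "x_px", "y_px",
                 "area_px", "axis_ratio", "focus", "n_member_layers"],
    )


def write_records_csv(records: Sequence[NucleusRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path
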