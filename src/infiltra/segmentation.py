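"""Per-layer nucleus segmentation and segmentation quality metrics.

The default path is classical and fully deterministic: smooth, threshold
(Otsu or fixed), fill holes, optionally split touching nuclei by a
distance-transform watershed, and filter by area.  It serves both as the
production segmenter and as the reference against which the optional
trainable segmenter (see ``infiltra.nnseg``) is compared.  Large layers
are processed in 1024 px tiles with an overlap strip so objects crossing
tile borders are not cut.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed
from skimage.feature import peak_local_max

from .io import ImageStack


@dataclasses.dataclass
class SegConfig:
    """Classical segmentation settings.

    ``intensity_threshold`` is ``"otsu"`` or an absolute intensity; the
    area filter [min_area_px, max_area_px] removes noise speckles and
    merged clumps; ``watershed_split`` separates touching nuclei using
    distance-transform peaks at least ``watershed_min_distance_px`` apart.
    """

    method: str = "classical"
    intensity_threshold: str | float = "otsu"
    threshold_scope: str = "stack"
    min_area_px: int = 30
    max_area_px: int = 8000
    watershed_split: bool = True
    watershed_min_distance_px: int = 7
    smoothing_sigma_px: float = 1.0
    tile_size_px: int = 1024
    tile_overlap_px: int = 64

    def __post_init__(self) -> None:
        if self.min_area_px >= self.max_area_px:
            raise ValueError("min_area_px must be below max_area_px")
        if self.tile_size_px < 64:
            raise ValueError("tile_size_px must be at least 64")
        if self.tile_overlap_px >= self.tile_size_px:
            raise ValueError("tile overlap must be smaller than the tile size")
        if self.method not in ("classical", "cnn"):
            raise ValueError("method must be 'classical' or 'cnn'")
        if self.threshold_scope not in ("per_layer", "stack"):
            raise ValueError("threshold_scope must be 'per_layer' or 'stack'")

    def digest(self) -> str:
        payload = repr(dataclasses.astuple(self)).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclasses.dataclass
class LayerMask:
    """Labelled nuclei of one layer (0 = background, labels 1..n consecutive)."""

    labels: np.ndarray
    layer_index: int
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


# ---------------------------------------------------------------------------
# tiling


@dataclasses.dataclass
class Tile:
    data: np.ndarray
    y0: int
    x0: int
    valid_h: int  # rows of `data` that map onto the source (rest is padding)
    valid_w: int


def tile_image(image: np.ndarray, tile_size_px: int = 1024, overlap_px: int = 64) -> list[Tile]:
    """Split an image into overlapping tiles that cover it completely.

    Border tiles are zero-padded to the full tile size; the valid extent
    is recorded so reassembly can crop the padding away exactly.
    """
    if tile_size_px <= overlap_px:
        raise ValueError("tile size must exceed the overlap")
    h, w = image.shape
    stride = tile_size_px - overlap_px
    tiles = []
    for y0 in range(0, max(h - overlap_px, 1), stride):
        for x0 in range(0, max(w - overlap_px, 1), stride):
            patch = image[y0 : y0 + tile_size_px, x0 : x0 + tile_size_px]
            vh, vw = patch.shape
            if (vh, vw) != (tile_size_px, tile_size_px):
                padded = np.zeros((tile_size_px, tile_size_px), dtype=image.dtype)
                padded[:vh, :vw] = patch
                patch = padded
            tiles.append(Tile(patch, y0, x0, vh, vw))
    return tiles


def reassemble_tiles(tiles: Sequence[Tile], shape: tuple[int, int]) -> np.ndarray:
    """Reassemble tiles into the original image (exact in unpadded regions)."""
    out = np.zeros(shape, dtype=tiles[0].data.dtype)
    for t in tiles:
        out[t.y0 : t.y0 + t.valid_h, t.x0 : t.x0 + t.valid_w] = t.data[: t.valid_h, : t.valid_w]
    return out


# ---------------------------------------------------------------------------
# classical segmentation


def _noise_floor(smoothed: np.ndarray) -> float:
    """Robust background ceiling: median + 4 sigma (sigma from the MAD).

    Otsu always splits a histogram, even of pure noise; requiring the
    threshold to clear the background noise band keeps layers without any
    real signal empty.
    """
    med = float(np.median(smoothed))
    mad = float(np.median(np.abs(smoothed - med)))
    return med + 4.0 * 1.4826 * mad


def _otsu_threshold(smoothed: np.ndarray) -> float:
    if smoothed.max() <= smoothed.min():
        return float(smoothed.max())  # nothing can exceed it
    return max(float(threshold_otsu(smoothed)), _noise_floor(smoothed))


def _foreground(image: np.ndarray, config: SegConfig) -> np.ndarray:
    smoothed = ndi.gaussian_filter(image.astype(np.float32), config.smoothing_sigma_px)
    if config.intensity_threshold == "otsu":
        thr = _otsu_threshold(smoothed)
    else:
        thr = float(config.intensity_threshold)
    return smoothed > thr


def _label_foreground(fg: np.ndarray, config: SegConfig) -> np.ndarray:
    fg = ndi.binary_fill_holes(fg)
    if config.watershed_split and fg.any():
        # smoothing the distance map suppresses spurious twin peaks inside
        # one elongated nucleus that would over-split it
        distance = ndi.gaussian_filter(ndi.distance_transform_edt(fg), 1.0)
        coords = peak_local_max(
            distance,
            min_distance=config.watershed_min_distance_px,
            labels=fg,
            exclude_border=False,
        )
        if len(coords):
            markers = np.zeros(fg.shape, dtype=np.int32)
            markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
            labels = watershed(-distance, markers, mask=fg)
        else:
            labels, _ = ndi.label(fg)
    else:
        labels, _ = ndi.label(fg)
    # area filter + consecutive relabel
    sizes = np.bincount(labels.ravel())
    keep = (sizes >= config.min_area_px) & (sizes <= config.max_area_px)
    keep[0] = False
    mapping = np.zeros(sizes.size, dtype=np.int32)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1)
    return mapping[labels]


def segment_layer(image: np.ndarray, config: SegConfig | None = None,
                  layer_index: int = 0,
                  threshold_override: float | None = None) -> LayerMask:
    """Segment nuclei in one layer with the classical deterministic path.

    Layers larger than the configured tile size are thresholded tile by
    tile (the foreground is OR-combined over the overlap strips), then
    filled/split/filtered globally, so objects crossing tile borders stay
    whole.
    """
    config = config or SegConfig()
    if threshold_override is not None:
        config = dataclasses.replace(config, intensity_threshold=float(threshold_override))
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("segment_layer expects a single-channel 2-D image")
    if image.size == 0:
        return LayerMask(np.zeros(image.shape, np.int32), layer_index, config.digest())
    h, w = image.shape
    if max(h, w) <= config.tile_size_px:
        fg = _foreground(image, config)
    else:
        # threshold per tile, keep each tile's core (half the overlap strip
        # is dropped on interior edges): smoothing edge effects never reach
        # the core, so the stitched foreground matches the whole-image one
        fg = np.zeros(image.shape, bool)
        m = config.tile_overlap_px // 2
        for t in tile_image(image, config.tile_size_px, config.tile_overlap_px):
            tfg = _foreground(t.data[: t.valid_h, : t.valid_w], config)
            y_lo = m if t.y0 > 0 else 0
            x_lo = m if t.x0 > 0 else 0
            y_hi = t.valid_h - (m if t.y0 + t.valid_h < h else 0)
            x_hi = t.valid_w - (m if t.x0 + t.valid_w < w else 0)
            fg[t.y0 + y_lo : t.y0 + y_hi, t.x0 + x_lo : t.x0 + x_hi] = \
                tfg[y_lo:y_hi, x_lo:x_hi]
    labels = _label_foreground(fg, config)
    return LayerMask(labels, layer_index, provenance=f"classical:{config.digest()}")


def segment_stack(stack: ImageStack, config: SegConfig | None = None) -> list[LayerMask]:
    """Segment every layer of a stack; one LayerMask per layer.

    With ``threshold_scope='stack'`` (default) the Otsu threshold is
    computed once from all layers pooled, which keeps layers without
    in-focus nuclei from being thresholded into noise speckles; with
    ``'per_layer'`` each layer gets its own threshold.
    """
    config = config or SegConfig()
    override = None
    if config.intensity_threshold == "otsu" and config.threshold_scope == "stack":
        smoothed = np.stack([
            ndi.gaussian_filter(stack.layer(i).astype(np.float32),
                                config.smoothing_sigma_px)
            for i in range(stack.n_layers)
        ])
        override = _otsu_threshold(smoothed)
    return [segment_layer(stack.layer(i), config, layer_index=i,
                          threshold_override=override)
            for i in range(stack.n_layers)]


# ---------------------------------------------------------------------------
# overlap metrics


def overlap_metrics(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """IOU and dice between two binary masks.

    iou = |A∩B| / |A∪B|, dice = 2|A∩B| / (|A|+|B|); both defined as 1
    when both masks are empty (nothing to find, nothing found).
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    total = np.count_nonzero(a) + np.count_nonzero(b)
    if union == 0:
        return 1.0, 1.0
    return inter / union, 2.0 * inter / total


def dice_loss(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """1 - dice; the segmentation training objective."""
    return 1.0 - overlap_metrics(mask_a, mask_b)[1]
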