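"""Reading and writing nuclei z-stacks and tabular outputs.

Stacks are held as a single float32 array of shape (n_layers, H, W) with
physical calibration attached.  On disk a stack is a multi-page TIFF (one
page per layer, page 0 = first scanned layer) or a directory of per-layer
PNG/TIFF images ordered by filename.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image


@dataclasses.dataclass
class ImageStack:
    """Ordered z-layers of a single-channel nuclei scan.

    Attributes
    ----------
    layers : np.ndarray
        Array of shape (n_layers, height, width), float32 intensities.
    layer_spacing_um : float
        Physical z step between consecutive layers, in micrometres.
    pixel_size_um : float
        Lateral pixel size, in micrometres.
    """

    layers: np.ndarray
    layer_spacing_um: float = 7.0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers)
        if self.layers.ndim != 3:
            raise ValueError(f"layers must be 3-D (z, y, x); got shape {self.layers.shape}")
        if self.layers.shape[0] < 1:
            raise ValueError("stack must contain at least one layer")
        if self.layer_spacing_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("physical calibration must be positive")

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.layers.shape

    def layer(self, index: int) -> np.ndarray:
        return self.layers[index]

    def depth_um(self, layer_index: int) -> float:
        """Depth of a layer's midpoint below the seeding surface."""
        return (layer_index + 0.5) * self.layer_spacing_um


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page float32 TIFF (page 0 = layer 0)."""
    path = Path(path)
    tifffile.imwrite(path, stack.layers.astype(np.float32))
    return path


def _read_image_file(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        return np.asarray(tifffile.imread(path))
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # RGB(A) PNG: collapse to single channel
        arr = arr[..., :3].mean(axis=-1)
    return arr


def read_stack(
    path: str | Path,
    fmt: str = "multipage_tiff",
    layer_spacing_um: float = 7.0,
    pixel_size_um: float = 1.0,
) -> ImageStack:
    """Read a z-stack from disk.

    Parameters
    ----------
    path : path
        Multi-page TIFF file (``multipage_tiff`` / ``ome_tiff``) or a
        directory of per-layer images (``png_dir``), ordered lexicographically.
    fmt : {"multipage_tiff", "ome_tiff", "png_dir"}
        Container layout.  OME-TIFF is read through the same multi-page
        path; calibration always comes from the arguments.
    """
    path = Path(path)
    if fmt in ("multipage_tiff", "ome_tiff"):
        if not path.is_file():
            raise FileNotFoundError(f"stack file not found: {path}")
        arr = np.asarray(tifffile.imread(path))
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"expected a single-channel z-stack, got shape {arr.shape}")
    elif fmt == "png_dir":
        if not path.is_dir():
            raise FileNotFoundError(f"stack directory not found: {path}")
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise ValueError(f"no layer images found in {path}")
        layers = [_read_image_file(p) for p in files]
        shapes = {l.shape for l in layers}
        if len(shapes) > 1:
            offending = [f.name for f, l in zip(files, layers) if l.shape != layers[0].shape]
            raise ValueError(f"mixed layer dimensions; offending layers: {offending}")
        arr = np.stack(layers)
    else:
        raise ValueError(f"unknown stack format: {fmt!r}")
    if arr.shape[0] == 0:
        raise ValueError("stack contains zero layers")
    return ImageStack(
        arr.astype(np.float32),
        layer_spacing_um=layer_spacing_um,
        pixel_size_um=pixel_size_um,
    )


def write_label_mask(labels: np.ndarray, path: str | Path) -> Path:
    """Write a labelled mask as 16-bit TIFF (label 0 = background)."""
    path = Path(path)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path


def stack_from_layers(
    layers: Sequence[np.ndarray], layer_spacing_um: float = 7.0, pixel_size_um: float = 1.0
) -> ImageStack:
    return ImageStack(np.stack(layers), layer_spacing_um, pixel_size_um)
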