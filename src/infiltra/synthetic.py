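"""Seeded synthetic nuclei z-stacks with exact ground truth.

Real scaffold scans are confocal z-stacks in which each nucleus appears
sharp in its own focal layer and progressively blurred and dimmer in the
layers above and below.  The generator emulates that: nuclei are random
ellipses placed at random depths, rendered into every layer after Gaussian
defocus blur whose scale grows linearly with the layer distance from the
true focal plane, with intensity attenuation 1/(1 + sigma^2), plus
additive Gaussian camera noise.  Every stack comes with an exact
ground-truth table, so segmentation, focus assignment and deduplication
can be scored against truth.

Nuclei are 2-D ellipses repeated across layers under blur rather than true
3-D ellipsoids — sufficient to exercise focus assignment, and a documented
simplification.  Depth placement follows one of three regimes matching the
kinetic models (surface settling, delayed/deep exponential, Hill-type
colonisation) so that kinetics fitting has in-distribution test data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import ImageStack
from .kinetics import CountProfile

_PSF_BASE_SIGMA_PX = 0.7  # in-focus optical blur, px

DEPTH_MODELS = ("surface", "exponential", "hill")

_DEFAULT_DEPTH_PARAMS = {
    "surface": {"k_per_um": 0.15},
    "exponential": {"k_per_um": 0.05, "z0_um": 20.0},
    "hill": {"n": 3.0, "K_um": 40.0},
}


@dataclasses.dataclass
class StackParams:
    """Parameters of one synthetic scaffold scan.

    Defaults mirror the study conditions: 14 layers at a 7 µm z step,
    nuclei of 8–14 µm major axis.  ``blur_growth`` is the defocus blur
    scale added per layer of distance from the true focal layer (px);
    ``noise_sd`` is the additive Gaussian noise on intensities in [0, 1].
    """

    n_layers: int = 14
    layer_spacing_um: float = 7.0
    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 1.0
    n_nuclei: int = 50
    major_axis_um: tuple[float, float] = (8.0, 14.0)
    minor_axis_um: tuple[float, float] = (5.0, 9.0)
    depth_distribution: str = "hill"
    depth_params: dict | None = None
    blur_growth: float = 1.0
    noise_sd: float = 0.02
    background: float = 0.03
    intensity_range: tuple[float, float] = (0.7, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("n_layers must be at least 2")
        for name in ("layer_spacing_um", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.width_px < 8 or self.height_px < 8:
            raise ValueError("frame must be at least 8x8 px")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.blur_growth < 0:
            raise ValueError("blur_growth must be non-negative")
        for rng_name in ("major_axis_um", "minor_axis_um", "intensity_range"):
            lo, hi = getattr(self, rng_name)
            if not (0 < lo <= hi):
                raise ValueError(f"{rng_name} must satisfy 0 < low <= high")
        if self.depth_distribution not in DEPTH_MODELS:
            raise ValueError(
                f"unknown depth distribution {self.depth_distribution!r}; "
                f"choose from {DEPTH_MODELS}"
            )
        max_axis_px = self.major_axis_um[1] / self.pixel_size_um
        if max_axis_px >= min(self.width_px, self.height_px):
            raise ValueError("largest nucleus does not fit in the frame")

    @property
    def resolved_depth_params(self) -> dict:
        base = dict(_DEFAULT_DEPTH_PARAMS[self.depth_distribution])
        if self.depth_params:
            base.update(self.depth_params)
        return base


@dataclasses.dataclass
class GroundTruth:
    """Exact per-nucleus truth for one generated stack."""

    table: pd.DataFrame  # id, layer, x_px, y_px, major_um, minor_um, orientation_rad
    n_layers: int

    @property
    def layer_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_layers, dtype=np.int64)
        if len(self.table):
            np.add.at(counts, self.table["layer"].to_numpy(dtype=int), 1)
        return counts

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, n_layers: int) -> "GroundTruth":
        return cls(pd.read_csv(path), n_layers)


# ---------------------------------------------------------------------------
# depth models (cumulative fraction of cells above depth z)


def depth_cdf(model: str, params: dict, z_um: np.ndarray) -> np.ndarray:
    z = np.asarray(z_um, dtype=float)
    if model == "surface":
        return 1.0 - np.exp(-params["k_per_um"] * z)
    if model == "exponential":
        return 1.0 - np.exp(-params["k_per_um"] * np.clip(z - params["z0_um"], 0.0, None))
    if model == "hill":
        n, K = params["n"], params["K_um"]
        zn = np.power(z, n)
        return zn / (K**n + zn)
    raise ValueError(f"unknown depth model {model!r}")


def depth_pmf(model: str, params: dict, n_layers: int, layer_spacing_um: float) -> np.ndarray:
    """Per-layer placement probabilities.

    The model CDF is evaluated at layer midpoints; the residual tail mass
    beyond the deepest midpoint is assigned to the deepest layer, so the
    cumulative fraction through layer i equals the model CDF at midpoint i
    exactly (except at the last layer, which absorbs the tail).
    """
    mid = (np.arange(n_layers) + 0.5) * layer_spacing_um
    cdf = depth_cdf(model, params, mid)
    pmf = np.diff(np.concatenate([[0.0], cdf]))
    pmf[-1] += 1.0 - cdf[-1]
    pmf = np.clip(pmf, 0.0, None)
    return pmf / pmf.sum()


def _largest_remainder(expected: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative expected counts to integers summing to ``total``."""
    expected = np.clip(np.asarray(expected, dtype=float), 0.0, None)
    if expected.sum() == 0:
        expected = np.ones_like(expected)
    expected = expected * (total / expected.sum())
    base = np.floor(expected).astype(np.int64)
    short = total - base.sum()
    order = np.argsort(-(expected - base), kind="stable")
    base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# rendering


def _render_ellipse(canvas: np.ndarray, cy: float, cx: float, a_px: float, b_px: float,
                    theta: float, amplitude: float) -> None:
    """Add a filled ellipse (semi-axes a >= b, px) into ``canvas`` in place."""
    h, w = canvas.shape
    r = int(np.ceil(a_px)) + 2
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a_px
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b_px
    d2 = u * u + v * v
    # soft half-pixel edge so discretisation does not create jagged borders
    edge = np.clip((1.0 - d2) / 0.15 + 0.5, 0.0, 1.0)
    canvas[y0:y1, x0:x1] += amplitude * edge


def _sample_nuclei(params: StackParams, rng: np.random.Generator) -> pd.DataFrame:
    """Sample nucleus geometry and depth; overlapping placements are retried."""
    pmf = depth_pmf(params.depth_distribution, params.resolved_depth_params,
                    params.n_layers, params.layer_spacing_um)
    rows = []
    placed: list[tuple[float, float, float]] = []  # (y, x, clearance radius)
    for i in range(params.n_nuclei):
        major = rng.uniform(*params.major_axis_um)
        minor_hi = min(params.minor_axis_um[1], major)
        minor = rng.uniform(min(params.minor_axis_um[0], minor_hi), minor_hi)
        a_px = 0.5 * major / params.pixel_size_um
        layer = int(rng.choice(params.n_layers, p=pmf))
        theta = rng.uniform(0, np.pi)
        margin = a_px + 2
        for _attempt in range(200):
            cy = rng.uniform(margin, params.height_px - margin)
            cx = rng.uniform(margin, params.width_px - margin)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (a_px + pr + 2) ** 2
                   for py, px, pr in placed):
                break
        placed.append((cy, cx, a_px))
        rows.append(
            {
                "id": i,
                "layer": layer,
                "x_px": cx,
                "y_px": cy,
                "major_um": major,
                "minor_um": minor,
                "orientation_rad": theta,
                "intensity": rng.uniform(*params.intensity_range),
            }
        )
    cols = ["id", "layer", "x_px", "y_px", "major_um", "minor_um", "orientation_rad",
            "intensity"]
    return pd.DataFrame(rows, columns=cols)


def generate_stack(params: StackParams) -> tuple[ImageStack, GroundTruth]:
    """Render a synthetic nuclei z-stack plus its exact ground truth.

    Each nucleus is rendered in focus in its true layer and re-rendered in
    every other layer with Gaussian blur of scale blur_growth * |dz| and
    intensity attenuation 1/(1 + (blur_growth*dz)^2).  The same params and
    seed always produce a bit-identical stack.
    """
    rng = np.random.default_rng(params.seed)
    nuclei = _sample_nuclei(params, rng)

    # one in-focus composite per focal layer, then blur whole composites
    composites = np.zeros((params.n_layers, params.height_px, params.width_px), np.float32)
    for row in nuclei.itertuples():
        a_px = 0.5 * row.major_um / params.pixel_size_um
        b_px = 0.5 * row.minor_um / params.pixel_size_um
        _render_ellipse(composites[row.layer], row.y_px, row.x_px, a_px, b_px,
                        row.orientation_rad, row.intensity)

    occupied = np.flatnonzero(composites.reshape(params.n_layers, -1).any(axis=1))
    layers = np.full((params.n_layers, params.height_px, params.width_px),
                     params.background, np.float32)
    for focal in occupied:
        for layer in range(params.n_layers):
            defocus = params.blur_growth * abs(layer - focal)
            sigma = float(np.hypot(_PSF_BASE_SIGMA_PX, defocus))
            attenuation = 1.0 / (1.0 + defocus**2)
            if attenuation < 1e-3:
                continue
            layers[layer] += attenuation * ndi.gaussian_filter(
                composites[focal], sigma, truncate=3.0
            )
    layers += rng.normal(0.0, params.noise_sd, size=layers.shape).astype(np.float32)
    np.clip(layers, 0.0, None, out=layers)

    truth = GroundTruth(nuclei.drop(columns=["intensity"]), params.n_layers)
    stack = ImageStack(layers, params.layer_spacing_um, params.pixel_size_um)
    return stack, truth


# ---------------------------------------------------------------------------
# segmentation training pairs


def generate_training_pairs(
    params: StackParams,
    n_pairs: int,
    augment: bool = False,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """In-focus nucleus renderings with exact binary masks.

    Each pair is one image of ``params.n_nuclei`` non-overlapping in-focus
    nuclei plus its pixel-exact mask.  With ``augment=True`` a random
    flip/rotation (applied identically to image and mask) and an intensity
    jitter (image only) are added, emulating augmentation of a hand-masked
    training set.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be at least 1")
    rng = np.random.default_rng(params.seed)
    pairs = []
    for _ in range(n_pairs):
        sub = dataclasses.replace(params, seed=int(rng.integers(2**31)), n_layers=2,
                                  depth_distribution="surface",
                                  depth_params={"k_per_um": 1e6})
        nuclei = _sample_nuclei(sub, np.random.default_rng(sub.seed))
        image = np.full((params.height_px, params.width_px), params.background, np.float32)
        mask = np.zeros_like(image)
        for row in nuclei.itertuples():
            a_px = 0.5 * row.major_um / params.pixel_size_um
            b_px = 0.5 * row.minor_um / params.pixel_size_um
            _render_ellipse(image, row.y_px, row.x_px, a_px, b_px,
                            row.orientation_rad, row.intensity)
            _render_ellipse(mask, row.y_px, row.x_px, a_px, b_px,
                            row.orientation_rad, 1.0)
        image = ndi.gaussian_filter(image, _PSF_BASE_SIGMA_PX)
        image += rng.normal(0.0, params.noise_sd, size=image.shape).astype(np.float32)
        np.clip(image, 0.0, None, out=image)
        mask = (mask >= 0.5).astype(np.uint8)
        if augment:
            k = int(rng.integers(4))
            image, mask = np.rot90(image, k).copy(), np.rot90(mask, k).copy()
            if rng.random() < 0.5:
                image, mask = image[:, ::-1].copy(), mask[:, ::-1].copy()
            image = image * float(rng.uniform(0.8, 1.2))
        pairs.append((image.astype(np.float32), mask))
    return pairs


# ---------------------------------------------------------------------------
# count scenarios for kinetics


def generate_count_scenario(
    model: str,
    model_params: dict | None,
    n_layers: int,
    total_cells: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    layer_spacing_um: float = 7.0,
    day: float | None = None,
) -> CountProfile:
    """Per-layer counts whose cumulative fraction follows a depth model.

    ``noise_sd`` is the relative jitter applied to the expected per-layer
    counts before integer rounding; counts are always non-negative and sum
    to ``total_cells`` exactly (largest-remainder rounding).
    """
    if total_cells < 1:
        raise ValueError("total_cells must be at least 1")
    if model not in DEPTH_MODELS:
        raise ValueError(f"unknown depth model {model!r}; choose from {DEPTH_MODELS}")
    params = dict(_DEFAULT_DEPTH_PARAMS[model])
    if model_params:
        params.update(model_params)
    pmf = depth_pmf(model, params, n_layers, layer_spacing_um)
    expected = pmf * total_cells
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        expected = expected * (1.0 + rng.normal(0.0, noise_sd, size=n_layers))
    counts = _largest_remainder(expected, total_cells)
    return CountProfile(counts, layer_spacing_um=layer_spacing_um, day=day)


# ---------------------------------------------------------------------------
# scoring pipeline output against ground truth


def score_against_truth(
    records: Sequence,
    truth: GroundTruth,
    max_match_dist_px: float = 10.0,
) -> dict:
    """Score deduplicated nucleus records against generator ground truth.

    Each record is matched to the nearest ground-truth nucleus within
    ``max_match_dist_px`` (greedy, nearest first).  Reported are the
    fraction of matched records assigned to their true layer, the number
    of ground-truth nuclei claimed by more than one record (duplicates),
    and the worst per-layer count error as a fraction of C_summ.
    """
    true_counts = truth.layer_counts
    n_layers = truth.n_layers
    rec_counts = np.zeros(n_layers, dtype=np.int64)
    for r in records:
        rec_counts[r.assigned_layer] += 1
    out = {
        "n_records": len(records),
        "n_truth": len(truth.table),
        "count_profile": rec_counts,
        "true_profile": true_counts,
    }
    if len(truth.table) == 0 or not records:
        out.update(n_matched=0, layer_accuracy=float("nan"), n_duplicate_truth=0,
                   max_count_error_frac=float("nan"))
        return out
    txy = truth.table[["x_px", "y_px"]].to_numpy(float)
    tlayer = truth.table["layer"].to_numpy(int)
    pairs = []
    for ri, r in enumerate(records):
        d = np.hypot(txy[:, 0] - r.centroid_xy[0], txy[:, 1] - r.centroid_xy[1])
        for ti in np.flatnonzero(d <= max_match_dist_px):
            pairs.append((d[ti], ri, ti))
    pairs.sort()
    rec_match: dict[int, int] = {}
    claimed: dict[int, int] = {}
    for _, ri, ti in pairs:
        if ri in rec_match:
            continue
        rec_match[ri] = ti
        claimed[ti] = claimed.get(ti, 0) + 1
    correct = sum(1 for ri, ti in rec_match.items()
                  if records[ri].assigned_layer == tlayer[ti])
    c_summ = max(int(true_counts.sum()), 1)
    out.update(
        n_matched=len(rec_match),
        layer_accuracy=correct / max(len(rec_match), 1),
        n_duplicate_truth=sum(1 for c in claimed.values() if c > 1),
        max_count_error_frac=float(np.max(np.abs(rec_counts - true_counts)) / c_summ),
    )
    return out
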