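"""Nuclear shape statistics: areas, axis ratios, log-normal fits, group tests.

Nuclear area and the major-to-minor axis ratio are sensitive readouts of
how cells adapt to a substrate: nuclei flatten and elongate on stiff flat
plastic and shrink/round up inside fibrous 3-D scaffolds.  Areas across a
large population are well described by a log-normal distribution, so
fits report the (mu, sigma) of log-area.  Group differences are tested
all-pairs with Tukey's honest significant difference (independent
groups) or a Friedman rank test with pairwise Wilcoxon follow-ups
(repeated measures across days).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import regionprops

SIGNIFICANCE_LEVEL = 0.05


@dataclasses.dataclass
class MorphSample:
    """Shape measurements of one experimental group (e.g. one mat, one day)."""

    group: str
    areas_um2: np.ndarray
    axis_ratios: np.ndarray | None = None
    day: float | None = None

    def __post_init__(self) -> None:
        self.areas_um2 = np.asarray(self.areas_um2, dtype=float)
        if np.any(self.areas_um2 <= 0):
            raise ValueError("areas must be positive")
        if self.axis_ratios is not None:
            self.axis_ratios = np.asarray(self.axis_ratios, dtype=float)
            if np.any(self.axis_ratios < 1):
                raise ValueError("axis ratios are major/minor and must be >= 1")


def object_shape(labels: np.ndarray, pixel_size_um: float,
                 label: int | None = None) -> dict:
    """Area, axes and orientation of a labelled object.

    Area is the pixel count scaled by pixel_size^2; axes come from the
    ellipse with the same second image moments.  A degenerate object
    (minor axis below one pixel) gets its minor axis floored at one pixel
    and is flagged.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    labels = np.asarray(labels)
    if label is not None:
        labels = (labels == label).astype(np.uint8)
    props = regionprops(labels.astype(np.int32))
    if not props:
        raise ValueError("no labelled object found")
    prop = props[0]
    if prop.area < 5:
        raise ValueError("object too small for a moment-based ellipse fit (< 5 px)")
    degenerate = prop.axis_minor_length < 1.0
    minor_px = max(prop.axis_minor_length, 1.0)
    major_px = max(prop.axis_major_length, minor_px)
    return {
        "area_um2": float(prop.area) * pixel_size_um**2,
        "major_um": major_px * pixel_size_um,
        "minor_um": minor_px * pixel_size_um,
        "axis_ratio": major_px / minor_px,
        "orientation_rad": float(prop.orientation),
        "degenerate": bool(degenerate),
    }


def fit_lognormal(values: Sequence[float]) -> tuple[float, float, float]:
    """Maximum-likelihood log-normal fit.

    Returns (mu, sigma, ks) where mu/sigma are the mean and standard
    deviation of log-values and ks is the Kolmogorov–Smirnov distance of
    the log-values from Normal(mu, sigma) — smaller is a better fit.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 10:
        raise ValueError("need at least 10 values")
    if np.any(v <= 0):
        raise ValueError("log-normal fit requires positive values")
    logv = np.log(v)
    mu = float(np.mean(logv))
    sigma = float(np.std(logv))
    if sigma == 0:
        return mu, 0.0, 0.0
    ks = float(stats.kstest(logv, "norm", args=(mu, sigma)).statistic)
    return mu, sigma, ks


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment for a family of p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def compare_groups(samples: Sequence[MorphSample],
                   mode: str = "pairwise_mean_difference",
                   metric: str = "areas_um2") -> pd.DataFrame:
    """All-pairs group comparison with family-wise error control.

    ``pairwise_mean_difference`` runs Tukey's honest significant
    difference on group means; ``paired_rank`` runs a Friedman omnibus
    rank test over matched samples followed by pairwise Wilcoxon
    signed-rank tests with Holm adjustment.  Returns one row per pair
    with the statistic (mean difference / Wilcoxon W), adjusted p-value
    and a significance flag at the 0.05 level.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    data = [np.asarray(getattr(s, metric), dtype=float) for s in samples]
    names = [s.group for s in samples]
    if any(d is None or len(d) < 2 for d in data):
        raise ValueError("every group needs at least 2 observations")
    rows = []
    if mode == "pairwise_mean_difference":
        res = stats.tukey_hsd(*data)
        for i in range(len(data)):
            for j in range(i + 1, len(data)):
                p = float(res.pvalue[i, j])
                rows.append({
                    "group_a": names[i], "group_b": names[j],
                    "statistic": float(np.mean(data[i]) - np.mean(data[j])),
                    "p_adjusted": p,
                    "significant": p < SIGNIFICANCE_LEVEL,
                })
    elif mode == "paired_rank":
        n = {len(d) for d in data}
        if len(n) != 1:
            raise ValueError("paired mode requires equal-length matched samples")
        omnibus = stats.friedmanchisquare(*data) if len(data) > 2 else None
        pairs, praw = [], []
        for i in range(len(data)):
            for j in range(i + 1, len(data)):
                diff = data[i] - data[j]
                if np.allclose(diff, 0):
                    stat, p = 0.0, 1.0
                else:
                    w = stats.wilcoxon(data[i], data[j])
                    stat, p = float(w.statistic), float(w.pvalue)
                pairs.append((i, j, stat))
                praw.append(p)
        padj = _holm(np.asarray(praw))
        for (i, j, stat), p in zip(pairs, padj):
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "statistic": stat,
                "p_adjusted": float(p),
                "significant": float(p) < SIGNIFICANCE_LEVEL
                and (omnibus is None or omnibus.pvalue < SIGNIFICANCE_LEVEL),
            })
    else:
        raise ValueError("mode must be 'pairwise_mean_difference' or 'paired_rank'")
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic",
                                       "p_adjusted", "significant"])
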