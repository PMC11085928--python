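"""Migration kinetics: conversion curves, model fits, and migration activity.

The depth census of a scaffold at one time point is a count profile
C_z (cells per layer) with total C_summ.  Borrowing the conversion-curve
formalism of reaction kinetics, the conversion value

    alpha(z) = (1/C_summ) * sum_{z' <= z} C_z'

is the fraction of all detected cells lying at or above depth z.  Three
regimes are modelled:

* ``surface_exponential``  alpha(z) = 1 - exp(-k z)           (cells settle on top)
* ``depth_exponential``    alpha(z) = 1 - exp(-k (z - z0)_+)  (mass shifted deeper)
* ``hill``                 alpha(z) = z^n / (K^n + z^n)       (sigmoidal colonisation)

Migration activity evaluates (alpha / z(alpha)^2) * (C_summ / t_d) at
alpha = 0.1 ... 0.9 in 10% increments, where z(alpha) inverts the
conversion curve and C_summ/t_d is the proliferation rate over the
observation interval; the slope of a straight-line fit through the nine
activity points is the single-number migration summary (1/z^2)*(C_summ/t_d).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

ALPHA_STEPS = np.round(np.arange(0.1, 0.95, 0.1), 10)  # 0.1 ... 0.9


@dataclasses.dataclass
class CountProfile:
    """Cells per layer at one time point.

    ``counts[i]`` is the number of nuclei assigned to layer i; layer 0 is
    the seeding surface.  ``day`` tags the observation time in days.
    """

    counts: np.ndarray
    layer_spacing_um: float = 7.0
    day: float | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)
        if self.layer_spacing_um <= 0:
            raise ValueError("layer_spacing_um must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.counts)

    @property
    def c_summ(self) -> int:
        """Total cells in the material (paper notation C_summ)."""
        return int(self.counts.sum())

    @property
    def depths_um(self) -> np.ndarray:
        """Layer midpoints in µm below the seeding surface."""
        return (np.arange(self.n_layers) + 0.5) * self.layer_spacing_um


@dataclasses.dataclass
class ConversionCurve:
    """Cumulative conversion alpha(z) plus the per-layer fraction C_z/C_summ."""

    z_um: np.ndarray
    alpha: np.ndarray
    fraction: np.ndarray | None = None  # per-layer C_z / C_summ, if known
    day: float | None = None

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.z_um.shape != self.alpha.shape:
            raise ValueError("z and alpha must have the same length")
        if np.any(np.diff(self.z_um) <= 0):
            raise ValueError("z must be strictly increasing")
        if np.any(np.diff(self.alpha) < -1e-12):
            raise ValueError("alpha must be non-decreasing")


@dataclasses.dataclass
class KineticFit:
    model: str
    params: dict[str, float]
    residual: float
    converged: bool
    message: str = ""

    def predict(self, z: np.ndarray) -> np.ndarray:
        return MODEL_FORMS[self.model](np.asarray(z, dtype=float), **self.params)


@dataclasses.dataclass
class MigrationActivity:
    """The (alpha/z^2)*(C_summ/t_d) transform evaluated at 10% alpha steps."""

    alpha_steps: np.ndarray
    z_at_alpha_um: np.ndarray
    rate_cells_per_day: float
    activity: np.ndarray
    slope: float
    intercept: float
    flagged: np.ndarray  # True where z(alpha) fell on a flat segment


# ---------------------------------------------------------------------------
# conversion curves


def conversion_curve(profile: CountProfile) -> ConversionCurve:
    """Cumulative conversion alpha(z) from a count profile.

    alpha at layer i is the fraction of C_summ found in layers 0..i; z is
    the layer midpoint in µm.  The per-layer fraction C_z/C_summ is kept
    alongside (the two are often conflated; both are exposed).
    """
    if profile.c_summ == 0:
        raise ValueError("empty profile: C_summ = 0, conversion undefined")
    frac = profile.counts / profile.c_summ
    alpha = np.cumsum(frac)
    alpha[-1] = 1.0  # guard against float round-off
    return ConversionCurve(profile.depths_um, alpha, fraction=frac, day=profile.day)


# ---------------------------------------------------------------------------
# kinetic model fitting


def _surface_exponential(z: np.ndarray, k: float) -> np.ndarray:
    return 1.0 - np.exp(-k * z)


def _depth_exponential(z: np.ndarray, k: float, z0: float) -> np.ndarray:
    return 1.0 - np.exp(-k * np.clip(z - z0, 0.0, None))


def _hill(z: np.ndarray, n: float, K: float) -> np.ndarray:
    zn = np.power(np.clip(z, 0.0, None), n)
    return zn / (np.power(K, n) + zn)


MODEL_FORMS: dict[str, Callable[..., np.ndarray]] = {
    "surface_exponential": _surface_exponential,
    "depth_exponential": _depth_exponential,
    "hill": _hill,
}


def _initial_guess(model: str, z: np.ndarray, alpha: np.ndarray) -> tuple[list[float], tuple]:
    zmed = float(np.median(z))
    if model == "surface_exponential":
        return [1.0 / max(zmed, 1e-9)], ([1e-9], [np.inf])
    if model == "depth_exponential":
        return [1.0 / max(zmed, 1e-9), 0.25 * zmed], ([1e-9, 0.0], [np.inf, float(z[-1])])
    if model == "hill":
        return [2.0, zmed], ([1e-3, 1e-6], [50.0, np.inf])
    raise ValueError(f"unknown kinetic model: {model!r}")


def fit_conversion_model(curve: ConversionCurve, model: str) -> KineticFit:
    """Least-squares fit of one kinetic model to a conversion curve.

    Returns the fitted parameters and the root-mean-square residual; on
    failure the ``converged`` flag is False and the message explains why —
    a non-converged fit is never reported silently as a good one.
    """
    if model not in MODEL_FORMS:
        raise ValueError(f"unknown kinetic model: {model!r}; choose from {sorted(MODEL_FORMS)}")
    z, alpha = curve.z_um, curve.alpha
    if len(z) < 4:
        raise ValueError("need at least 4 points to fit a conversion model")
    if np.any(alpha < -1e-9) or np.any(alpha > 1 + 1e-9):
        raise ValueError("alpha values must lie in [0, 1]")
    p0, bounds = _initial_guess(model, z, alpha)
    form = MODEL_FORMS[model]
    names = list(form.__code__.co_varnames[1 : form.__code__.co_argcount])
    try:
        popt, _ = optimize.curve_fit(
            form, z, alpha, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        return KineticFit(model, dict(zip(names, p0)), np.inf, False, f"fit failed: {exc}")
    resid = float(np.sqrt(np.mean((form(z, *popt) - alpha) ** 2)))
    if not np.all(np.isfinite(popt)):
        return KineticFit(model, dict(zip(names, popt)), resid, False, "non-finite parameters")
    return KineticFit(model, dict(zip(names, map(float, popt))), resid, True)


def select_conversion_model(
    curve: ConversionCurve, models: Sequence[str] = ("surface_exponential", "depth_exponential", "hill")
) -> KineticFit:
    """Fit every candidate model and return the best one.

    Comparison uses an AIC-style score (residual-based with a penalty per
    free parameter): ``depth_exponential`` nests ``surface_exponential``,
    so ranking raw residuals alone would never pick the simpler model.
    """
    fits = [fit_conversion_model(curve, m) for m in models]
    ok = [f for f in fits if f.converged]
    if not ok:
        return min(fits, key=lambda f: f.residual)
    n = len(curve.z_um)

    def aic(f: KineticFit) -> float:
        rss = f.residual**2 * n
        return n * np.log(rss / n + 1e-12) + 2 * len(f.params)

    return min(ok, key=aic)


# ---------------------------------------------------------------------------
# proliferation rate


def proliferation_rate(
    profiles_by_day: Sequence[CountProfile],
    intervals: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Proliferation rate C_summ/t_d per observation interval.

    ``intervals`` maps interval names to durations in days (defaults
    t_1 = 1, t_2 = 3, t_3 = 3: seeding→day 1, day 1→4, day 4→7); the rate
    for an interval is C_summ at the interval's end divided by its length.
    Profiles must carry a ``day`` tag; intervals are matched to profiles in
    increasing day order.
    """
    if intervals is None:
        intervals = {"t_1": 1.0, "t_2": 3.0, "t_3": 3.0}
    if any(t <= 0 for t in intervals.values()):
        raise ValueError("interval durations must be positive")
    tagged = [p for p in profiles_by_day if p.day is not None]
    if len(tagged) < 2:
        raise ValueError("need profiles for at least two days, each tagged with a day")
    tagged.sort(key=lambda p: p.day)
    names = list(intervals)
    if len(tagged) < len(names):
        missing = names[len(tagged):]
        raise ValueError(f"missing end-of-interval profile(s) for: {', '.join(missing)}")
    # interval ends are the last len(intervals) observations in day order
    ends = tagged[-len(names):]
    return {name: p.c_summ / intervals[name] for name, p in zip(names, ends)}


# ---------------------------------------------------------------------------
# migration activity


def invert_conversion(curve: ConversionCurve, alpha_targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """z(alpha) by monotone piecewise-linear interpolation.

    The curve is anchored at (z=0, alpha=0).  A flat segment spanning a
    requested alpha is resolved at the segment's midpoint and flagged.
    """
    z = np.concatenate([[0.0], curve.z_um])
    a = np.concatenate([[0.0], curve.alpha])
    if alpha_targets.min() < a[0] - 1e-12 or alpha_targets.max() > a[-1] + 1e-12:
        raise ValueError("requested alpha outside the curve's range")
    z_out = np.empty_like(alpha_targets, dtype=float)
    flagged = np.zeros_like(alpha_targets, dtype=bool)
    for i, at in enumerate(alpha_targets):
        lo = np.searchsorted(a, at, side="left")
        hi = np.searchsorted(a, at, side="right")
        if hi - lo > 1:  # alpha value repeated: flat segment
            z_out[i] = 0.5 * (z[lo] + z[hi - 1])
            flagged[i] = True
        else:
            z_out[i] = np.interp(at, a, z)
            # a requested alpha strictly inside a zero-slope run
            j = min(lo, len(a) - 1)
            if j > 0 and a[j] - a[j - 1] <= 1e-15 and not np.isclose(at, a[j]):
                flagged[i] = True
    return z_out, flagged


def migration_activity_curve(
    curve: ConversionCurve,
    rate_cells_per_day: float,
    alpha_steps: np.ndarray | None = None,
) -> MigrationActivity:
    """Evaluate (alpha/z^2)*(C_summ/t_d) at 10% alpha increments and fit a line.

    The slope of the ordinary least-squares line through the activity
    points is the migration-activity tangent (1/z^2)*(C_summ/t_d): large
    when the cell mass sits shallow (small z at every alpha), small when
    the same conversion is only reached deep in the scaffold.
    """
    if rate_cells_per_day < 0:
        raise ValueError("rate must be non-negative")
    steps = ALPHA_STEPS if alpha_steps is None else np.asarray(alpha_steps, dtype=float)
    if len(steps) < 2 or np.any(np.diff(steps) <= 0):
        raise ValueError("alpha steps must be strictly increasing, with at least 2 points")
    z_at, flagged = invert_conversion(curve, steps)
    if np.any(z_at <= 0):
        raise ValueError("conversion curve yields non-positive depth at a requested alpha")
    activity = steps / np.square(z_at) * rate_cells_per_day
    slope, intercept = np.polyfit(steps, activity, 1)
    return MigrationActivity(
        alpha_steps=steps,
        z_at_alpha_um=z_at,
        rate_cells_per_day=float(rate_cells_per_day),
        activity=activity,
        slope=float(slope),
        intercept=float(intercept),
        flagged=flagged,
    )


def activity_share(activity: MigrationActivity, cell_fraction: float) -> float:
    """Fraction of total migration activity carried by cells up to ``cell_fraction``.

    Trapezoidal area under activity(alpha) for alpha <= cell_fraction,
    relative to the total area over the evaluated alpha range.  E.g. a
    share(0.5) of 0.75 means half of the cells account for three quarters
    of the migration activity.
    """
    if not 0 < cell_fraction <= 1:
        raise ValueError("cell_fraction must be in (0, 1]")
    a, y = activity.alpha_steps, activity.activity
    if len(a) < 2:
        raise ValueError("need at least 2 activity points")
    upper = min(cell_fraction, a[-1])
    if upper <= a[0]:
        return 0.0
    total = np.trapezoid(y, a)
    if total <= 0:
        raise ValueError("total activity area is non-positive")
    # integrate up to `upper`, interpolating the final partial segment
    grid = a[a <= upper]
    yy = y[: len(grid)]
    if upper > grid[-1]:
        grid = np.append(grid, upper)
        yy = np.append(yy, np.interp(upper, a, y))
    return float(np.trapezoid(yy, grid) / total)


# ---------------------------------------------------------------------------
# tabular I/O


def profiles_to_frame(profiles: Iterable[CountProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for layer, c in enumerate(p.counts):
            rows.append({"day": p.day, "layer": layer, "count": int(c)})
    return pd.DataFrame(rows, columns=["day", "layer", "count"])


def write_profiles_csv(profiles: Iterable[CountProfile], path: str | Path) -> Path:
    path = Path(path)
    profiles_to_frame(profiles).to_csv(path, index=False)
    return path


def read_profiles_csv(path: str | Path, layer_spacing_um: float = 7.0) -> list[CountProfile]:
    """Read count profiles from CSV with columns day,layer,count."""
    df = pd.read_csv(path)
    required = {"day", "layer", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"profile CSV must have columns {sorted(required)}")
    out = []
    for day, grp in df.groupby("day", dropna=False, sort=True):
        grp = grp.sort_values("layer")
        n_layers = int(grp["layer"].max()) + 1
        counts = np.zeros(n_layers, dtype=np.int64)
        counts[grp["layer"].to_numpy(dtype=int)] = grp["count"].to_numpy(dtype=int)
        out.append(
            CountProfile(counts, layer_spacing_um=layer_spacing_um,
                         day=None if pd.isna(day) else float(day))
        )
    return out


def fit_to_json(fit: KineticFit, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(fit), indent=2))
    return path


def activity_to_frame(activity: MigrationActivity) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "alpha": activity.alpha_steps,
            "z_um": activity.z_at_alpha_um,
            "activity": activity.activity,
            "flagged": activity.flagged,
        }
    )
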