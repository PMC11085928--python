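"""Plots mirroring the standard migration figures: profile, conversion, activity."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .kinetics import ConversionCurve, CountProfile, KineticFit, MigrationActivity
import numpy as np


def plot_profile(profiles: Sequence[CountProfile], path: str | Path) -> Path:
    """Cells per layer (C_z) against depth, one line per day."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for p in profiles:
        label = f"day {p.day:g}" if p.day is not None else None
        ax.plot(p.depths_um, p.counts, "o-", label=label)
    ax.set_xlabel("depth z (µm)")
    ax.set_ylabel("cells per layer $C_z$")
    if any(p.day is not None for p in profiles):
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_conversion(curve: ConversionCurve, path: str | Path,
                    fit: KineticFit | None = None) -> Path:
    """Conversion curve alpha(z) with an optional fitted model overlay."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.z_um, curve.alpha, "o-", color="crimson", label=r"$\alpha(z)$")
    if curve.fraction is not None:
        ax.plot(curve.z_um, curve.fraction, "s--", color="grey",
                label=r"$C_z/C_{summ}$")
    if fit is not None and fit.converged:
        zz = np.linspace(0, curve.z_um[-1], 200)
        ax.plot(zz, fit.predict(zz), ":", label=f"{fit.model} fit")
    ax.set_xlabel("depth z (µm)")
    ax.set_ylabel("conversion")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_activity(activities: Sequence[MigrationActivity], path: str | Path,
                  labels: Sequence[str] | None = None) -> Path:
    """Migration activity (alpha/z^2)(C_summ/t_d) versus alpha, with linear fits."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, act in enumerate(activities):
        label = labels[i] if labels else None
        line, = ax.plot(act.alpha_steps, act.activity, "o", label=label)
        ax.plot(act.alpha_steps, act.slope * act.alpha_steps + act.intercept,
                "-", color=line.get_color(), alpha=0.6)
    ax.set_xlabel(r"conversion $\alpha$")
    ax.set_ylabel(r"$(\alpha/z^2)\,(C_{summ}/t_d)$")
    if labels:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
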