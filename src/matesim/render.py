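"""Deterministic rendering of simulation snapshots.

Three views are provided, mirroring the standard figures of this kind of
study: the membrane colored by normalized u2 with the polarisome marked, a
filled contour plot of an extracellular field with the membranes overlaid,
and a quantitative cross-section profile exported as a table.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from matesim.simulation import SimulationResult


def _nearest_snapshot(result: SimulationResult, time_s: float) -> float:
    if not result.snapshots:
        raise ValueError("result holds no field snapshots "
                         "(set snapshot_times in the config)")
    ts = np.array(sorted(result.snapshots))
    t = float(ts[np.argmin(np.abs(ts - time_s))])
    if abs(t - time_s) > 1e-6:
        warnings.warn(f"no snapshot at t={time_s}s; using nearest t={t}s")
    return t


def _snapshot_exterior(result: SimulationResult, snap: dict) -> np.ndarray:
    phis = [snap[f"phi_{c}"] for c in result.cell_ids]
    ext = np.ones_like(phis[0], dtype=bool)
    for p in phis:
        ext &= p > 0
    return ext


def render_u2_polarization(result: SimulationResult, time_s: float,
                           path: str | Path | None = None,
                           ax: plt.Axes | None = None) -> plt.Axes:
    """Membranes colored by u2/max(u2) with a dot at each polarisome."""
    t = _nearest_snapshot(result, time_s)
    snap = result.snapshots[t]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    for cid in result.cell_ids:
        pts = snap[f"curve_{cid}"]
        u2 = snap[f"u2_{cid}"]
        u2n = u2 / max(u2.max(), 1e-12)
        closed = np.vstack((pts, pts[:1]))
        ax.plot(closed[:, 0], closed[:, 1], color="0.8", lw=0.5, zorder=1)
        sc = ax.scatter(pts[:, 0], pts[:, 1], c=u2n, s=4, cmap="viridis",
                        vmin=0, vmax=1, zorder=2)
        if u2.max() > 2.0 * max(u2.mean(), 1e-12):
            tip = pts[int(np.argmax(u2))]
            ax.plot(*tip, "ko", ms=5, zorder=3)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"u2 polarization, t = {t:g} s")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def render_field_contour(result: SimulationResult, time_s: float,
                         species: str = "f_alpha",
                         path: str | Path | None = None,
                         ax: plt.Axes | None = None) -> plt.Axes:
    """Filled contour of an extracellular field with membranes overlaid."""
    t = _nearest_snapshot(result, time_s)
    snap = result.snapshots[t]
    if species not in snap:
        raise KeyError(f"snapshot has no field {species!r}; has {sorted(snap)}")
    cfg = result.config
    grid = cfg.grid()
    vals = np.where(_snapshot_exterior(result, snap), snap[species], np.nan)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    X, Y = grid.meshgrid()
    cs = ax.contourf(X, Y, vals, levels=20, cmap="Greys")
    ax.figure.colorbar(cs, ax=ax, label=species)
    for cid in result.cell_ids:
        pts = snap[f"curve_{cid}"]
        closed = np.vstack((pts, pts[:1]))
        ax.plot(closed[:, 0], closed[:, 1], "r-", lw=1)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"{species}, t = {t:g} s")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def cross_section_profile(result: SimulationResult, time_s: float,
                          p0: tuple[float, float], p1: tuple[float, float],
                          species: str = "f_alpha",
                          path: str | Path | None = None) -> pd.DataFrame:
    """Field profile along the segment p0 -> p1 at a snapshot time.

    Sampled at grid-spacing steps; points inside a cell body carry NaN (the
    cell excludes ligand), matching the troughs seen in published profiles.
    Columns: arclength, x, y, concentration, time_s.
    """
    t = _nearest_snapshot(result, time_s)
    snap = result.snapshots[t]
    cfg = result.config
    grid = cfg.grid()
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.hypot(*(p1 - p0)))
    n = max(2, int(round(length / grid.h)) + 1)
    s = np.linspace(0.0, length, n)
    pts = p0 + (s / length)[:, None] * (p1 - p0)
    ext = _snapshot_exterior(result, snap).astype(float)
    conc = grid.interp(snap[species], pts, weights=ext)
    inside = grid.interp(ext, pts) < 0.5
    conc = np.where(inside, np.nan, conc)
    df = pd.DataFrame({
        "arclength": s,
        "x": pts[:, 0],
        "y": pts[:, 1],
        "concentration": conc,
        "time_s": t,
    })
    if path is not None:
        df.to_csv(path, index=False)
    return df
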