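"""Post-run statistics over event logs and trajectories.

All functions here are pure: they read DataFrames produced by a run (or
scripted logs) and return arrays/frames, never mutating run outputs.
Axial coordinates are arc length along the tube from the distal tip (um).
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["death_histogram", "radial_heatmap", "angular_uniformity",
           "motion_vector_field", "event_rate_series"]


def death_histogram(events: pd.DataFrame,
                    bin_edges: Sequence[float]) -> np.ndarray:
    """Counts of apoptosis events by axial position, half-open bins.

    ``events`` may be a full event log (apoptosis rows are selected) or a
    pre-filtered frame with an ``axial`` column.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    deaths = events[events.kind == "apoptosis"] if "kind" in events else events
    ax = deaths.axial.to_numpy()
    counts, _ = np.histogram(ax, bins=edges)
    return counts


def radial_heatmap(events: pd.DataFrame, geometry,
                   axial_edges: Sequence[float],
                   n_angular: int = 8) -> np.ndarray:
    """2D (axial x angular) death-count grid around the tube.

    The angular coordinate is the angle of the event position around the
    local centreline (reference +y), so "rows" of the grid are rings of the
    tube wall.
    """
    deaths = events[events.kind == "apoptosis"] if "kind" in events else events
    if len(deaths) == 0:
        return np.zeros((len(axial_edges) - 1, n_angular), dtype=int)
    pos = deaths[["x", "y", "z"]].to_numpy()
    ax = geometry.axial(pos)
    ang = geometry.radial_angle(pos)
    ang_edges = np.linspace(-np.pi, np.pi, n_angular + 1)
    grid, _, _ = np.histogram2d(np.atleast_1d(ax), np.atleast_1d(ang),
                                bins=[np.asarray(axial_edges, dtype=float),
                                      ang_edges])
    return grid.astype(int)


def angular_uniformity(grid: np.ndarray) -> Tuple[float, float]:
    """Chi-square test of uniformity of the angular marginal of a death
    grid; returns (statistic, p-value)."""
    marginal = np.asarray(grid).sum(axis=0)
    if marginal.sum() == 0:
        raise ValueError("empty grid")
    stat, p = stats.chisquare(marginal)
    return float(stat), float(p)


def motion_vector_field(trajectory: pd.DataFrame,
                        edges: Sequence[Sequence[float]]):
    """Mean displacement-per-unit-time vector on a spatial grid.

    Per-cell displacements between consecutive frames are attributed to the
    grid cell of their midpoint.  ``edges`` is (x_edges, y_edges, z_edges).
    Returns ``(field, counts)``: field has shape (nx, ny, nz, 3) in um/s
    (NaN where no data), counts the number of contributing displacements.
    """
    if trajectory.t.nunique() < 2:
        raise ValueError("need at least two frames")
    df = trajectory.sort_values(["cell", "t"])
    same = df.cell.to_numpy()[1:] == df.cell.to_numpy()[:-1]
    p0 = df[["x", "y", "z"]].to_numpy()[:-1][same]
    p1 = df[["x", "y", "z"]].to_numpy()[1:][same]
    dt = (df.t.to_numpy()[1:] - df.t.to_numpy()[:-1])[same]
    ok = dt > 0
    p0, p1, dt = p0[ok], p1[ok], dt[ok]
    vel = (p1 - p0) / dt[:, None]
    mid = 0.5 * (p0 + p1)

    ex, ey, ez = (np.asarray(e, dtype=float) for e in edges)
    shape = (len(ex) - 1, len(ey) - 1, len(ez) - 1)
    ix = np.digitize(mid[:, 0], ex) - 1
    iy = np.digitize(mid[:, 1], ey) - 1
    iz = np.digitize(mid[:, 2], ez) - 1
    inside = ((ix >= 0) & (ix < shape[0]) & (iy >= 0) & (iy < shape[1])
              & (iz >= 0) & (iz < shape[2]))
    ix, iy, iz, vel = ix[inside], iy[inside], iz[inside], vel[inside]
    flat = np.ravel_multi_index((ix, iy, iz), shape)
    counts = np.bincount(flat, minlength=np.prod(shape))
    field = np.full((np.prod(shape), 3), np.nan)
    for axis in range(3):
        sums = np.bincount(flat, weights=vel[:, axis],
                           minlength=np.prod(shape))
        nz = counts > 0
        field[nz, axis] = sums[nz] / counts[nz]
    return field.reshape(shape + (3,)), counts.reshape(shape)


def event_rate_series(events: pd.DataFrame, window: float,
                      t_end: Optional[float] = None,
                      kinds: Sequence[str] = ("division", "apoptosis",
                                              "fertilization")) -> pd.DataFrame:
    """Event rates (per hour) in consecutive windows of ``window`` seconds.

    The integral of each rate column times the window length recovers the
    total event count of that kind.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t_end = (float(events.t.max()) if t_end is None and len(events)
             else (t_end or window))
    edges = np.arange(0.0, t_end + window, window)
    if len(edges) < 2:
        edges = np.array([0.0, window])
    out = {"t": 0.5 * (edges[:-1] + edges[1:])}
    for kind in kinds:
        sel = events[events.kind == kind] if len(events) else events
        counts, _ = (np.histogram(sel.t.to_numpy(), bins=edges)
                     if len(events) else (np.zeros(len(edges) - 1), None))
        out[f"{kind}_per_h"] = counts / (window / 3600.0)
    return pd.DataFrame(out)
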