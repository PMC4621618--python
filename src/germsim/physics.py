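"""Brownian dynamics of cell particles: contact forces and the integrator.

Cells are spheres with no momentum (overdamped, high-friction regime) and no
long-range interactions; the only force is harmonic repulsion when two cell
boundaries overlap (spring constant ``k`` = 36 pN/um), including contacts
with the static wall particles of the gonad.  Positions advance by

    x' = x + dt * F * beta + sqrt(2 * kB * T * dt * beta) * r

per axis, with ``r`` a standard normal deviate and ``beta = gamma / m`` the
per-mass damping scale (see PhysicsParams for the calibration of ``gamma``).
The division axis of each cell is a unit orientation vector that performs
its own rotational diffusion.

Units throughout: um, s, pg, pN; kB = 1.380649e-5 pN*um/K, so kB*T at 298 K
is 4.114e-3 pN*um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

BOLTZMANN = 1.380649e-5  # pN*um / K

__all__ = ["PhysicsParams", "Cell", "cell_mass", "overlap_force",
           "pair_contact_forces", "bd_position_step", "orientation_step",
           "wall_force", "NeighborList", "BOLTZMANN"]


@dataclass
class PhysicsParams:
    """Physical constants and integrator settings.

    ``gamma`` sets the damping scale ``beta = gamma / m`` appearing in the
    position update.  The default is calibrated so that an unforced cell of
    radius 2 um moves a small fraction of its radius (~0.3%, 3D RMS
    ~0.006 um) per 0.3 s, which keeps the explicit contact relaxation time
    1/(2*k*beta) comfortably above the adaptive timestep; in the overdamped
    quasi-static regime the emergent flow is set by growth and removal, not
    by the mobility.  Setting ``damping_mode="inverse_gamma"`` instead uses
    ``beta = 1/gamma`` (friction-coefficient reading of the same equation).
    """

    temperature: float = 298.0          # K
    gamma: float = 0.2                  # pg*um/(pN*s); beta = gamma/m
    damping_mode: str = "gamma_over_m"  # or "inverse_gamma"
    kB: float = BOLTZMANN               # pN*um/K
    density: float = 1.3                # pg/um^3
    spring_k: float = 36.0              # pN/um
    dt_max: float = 3.0                 # s, hard cap on the BD timestep
    hybrid_interval: float = 0.3        # s, physical<->executable update period
    d_rot: float = 1.0e-4               # 1/s, rotational diffusion of the axis
    drift_fraction: float = 0.1         # max drift per step, fraction of r_min

    def __post_init__(self):
        for name in ("temperature", "gamma", "kB", "density", "spring_k",
                     "dt_max", "hybrid_interval", "d_rot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.damping_mode not in ("gamma_over_m", "inverse_gamma"):
            raise ValueError(f"bad damping_mode {self.damping_mode!r}")

    def beta(self, mass):
        """Damping scale beta (um/(pN*s)) for cells of the given mass."""
        if self.damping_mode == "gamma_over_m":
            return self.gamma / np.asarray(mass, dtype=float)
        return np.full_like(np.asarray(mass, dtype=float), 1.0 / self.gamma)

    @property
    def kBT(self) -> float:
        return self.kB * self.temperature


def cell_mass(radius, density: float = 1.3):
    """Mass of a spherical cell, (4/3)*pi*r^3*rho (pg)."""
    radius = np.asarray(radius, dtype=float)
    if np.any(radius < 0):
        raise ValueError("negative radius")
    out = (4.0 / 3.0) * np.pi * radius ** 3 * density
    return float(out) if out.ndim == 0 else out


@dataclass
class Cell:
    """A germ cell: particle state plus its signaling network state.

    The exchange type used by single-cell operations (division, apoptosis)
    and tests; the simulator keeps the population in struct-of-arrays form
    and converts at event boundaries.
    """

    position: np.ndarray
    radius: float
    orientation: np.ndarray
    qn_state: tuple
    lineage_id: int
    birth_time: float = 0.0
    division_threshold: float = np.inf
    density: float = 1.3
    time_in_pachytene: float = 0.0
    time_in_ras_zone: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        norm = np.linalg.norm(self.orientation)
        if norm < 1e-12:
            raise ValueError("orientation must be a non-zero vector")
        self.orientation = self.orientation / norm

    @property
    def mass(self) -> float:
        """Mass is always consistent with the current radius and density."""
        return cell_mass(self.radius, self.density)


def overlap_force(a: Cell, b: Cell, k: float = 36.0,
                  fallback_axis: Optional[np.ndarray] = None) -> np.ndarray:
    """Harmonic repulsion on ``a`` from overlap with ``b`` (pN).

    Zero when the boundaries do not overlap; otherwise magnitude
    ``k * ((r_a + r_b) - |x_a - x_b|)`` directed from b toward a.  The force
    on ``b`` is the exact negation.  Coincident centres repel along
    ``fallback_axis`` (default: a's orientation, else +x) deterministically.
    """
    d = a.position - b.position
    dist = float(np.linalg.norm(d))
    delta = (a.radius + b.radius) - dist
    if delta <= 0.0:
        return np.zeros(3)
    if dist < 1e-12:
        axis = fallback_axis if fallback_axis is not None else a.orientation
        axis = np.asarray(axis, dtype=float)
        if np.linalg.norm(axis) < 1e-12:
            axis = np.array([1.0, 0.0, 0.0])
        return k * delta * axis / np.linalg.norm(axis)
    return k * delta * d / dist


def pair_contact_forces(positions: np.ndarray, radii: np.ndarray,
                        pairs: np.ndarray, k: float,
                        fallback_axes: Optional[np.ndarray] = None):
    """Vectorised harmonic contact forces for candidate pairs.

    ``pairs`` is an (n_pairs, 2) integer array of candidate contacts (a
    superset of actual overlaps is fine).  Returns ``(forces, magnitudes)``:
    per-cell total force (n, 3) and per-cell sum of contact-force magnitudes
    (n,), the latter feeding the pressure estimate.
    """
    n = positions.shape[0]
    forces = np.zeros((n, 3))
    mags = np.zeros(n)
    if len(pairs) == 0:
        return forces, mags
    i, j = pairs[:, 0], pairs[:, 1]
    d = positions[i] - positions[j]
    dist = np.sqrt(np.einsum("ij,ij->i", d, d))
    delta = radii[i] + radii[j] - dist
    hit = delta > 0.0
    if not np.any(hit):
        return forces, mags
    i, j, d, dist, delta = i[hit], j[hit], d[hit], dist[hit], delta[hit]
    coincident = dist < 1e-12
    if np.any(coincident):
        axes = (fallback_axes[i[coincident]] if fallback_axes is not None
                else np.tile([1.0, 0.0, 0.0], (int(coincident.sum()), 1)))
        d[coincident] = axes
        dist[coincident] = np.linalg.norm(axes, axis=1)
    f = (k * delta / dist)[:, None] * d
    fmag = k * delta
    for axis in range(3):
        forces[:, axis] += np.bincount(i, weights=f[:, axis], minlength=n)
        forces[:, axis] -= np.bincount(j, weights=f[:, axis], minlength=n)
    mags += np.bincount(i, weights=fmag, minlength=n)
    mags += np.bincount(j, weights=fmag, minlength=n)
    return forces, mags


def wall_contact_forces(positions: np.ndarray, radii: np.ndarray,
                        wall_positions: np.ndarray, wall_radius: float,
                        wall_pairs: np.ndarray, k: float):
    """Forces from static wall particles (walls never move).

    ``wall_pairs`` is (n_pairs, 2): cell index, wall-particle index.
    """
    n = positions.shape[0]
    forces = np.zeros((n, 3))
    mags = np.zeros(n)
    if len(wall_pairs) == 0:
        return forces, mags
    i, w = wall_pairs[:, 0], wall_pairs[:, 1]
    d = positions[i] - wall_positions[w]
    dist = np.sqrt(np.einsum("ij,ij->i", d, d))
    delta = radii[i] + wall_radius - dist
    hit = delta > 0.0
    if not np.any(hit):
        return forces, mags
    i, d, dist, delta = i[hit], d[hit], dist[hit], delta[hit]
    dist = np.maximum(dist, 1e-12)
    f = (k * delta / dist)[:, None] * d
    for axis in range(3):
        forces[:, axis] += np.bincount(i, weights=f[:, axis], minlength=n)
    mags += np.bincount(i, weights=k * delta, minlength=n)
    return forces, mags


def wall_force(cell: Cell, geometry, k: float = 36.0) -> np.ndarray:
    """Total harmonic force on one cell from every wall particle in range."""
    wall = geometry.wall_positions
    d = cell.position[None, :] - wall
    dist = np.linalg.norm(d, axis=1)
    delta = cell.radius + geometry.wall_radius - dist
    hit = delta > 0.0
    if not np.any(hit):
        return np.zeros(3)
    dist = np.maximum(dist[hit], 1e-12)
    return ((k * delta[hit] / dist)[:, None] * d[hit]).sum(axis=0)


def bd_position_step(positions: np.ndarray, forces: np.ndarray,
                     masses: np.ndarray, params: PhysicsParams, dt: float,
                     noise: np.ndarray) -> np.ndarray:
    """One Brownian-dynamics position update (vectorised over cells).

    Implements ``x' = x + dt*F*beta + sqrt(2*kB*T*dt*beta) * r`` per axis;
    there is no velocity state.
    """
    if dt <= 0.0 or dt > params.dt_max:
        raise ValueError(f"dt={dt} outside (0, {params.dt_max}]")
    beta = np.atleast_1d(params.beta(masses))[:, None]
    drift = dt * forces * beta
    sigma = np.sqrt(2.0 * params.kBT * dt * beta)
    return positions + drift + sigma * noise


def orientation_step(orientations: np.ndarray, params: PhysicsParams,
                     dt: float, rng: np.random.Generator) -> np.ndarray:
    """Rotational diffusion of division axes: isotropic Gaussian kick with
    per-axis variance ``2*D_rot*dt``, then renormalisation."""
    o = np.atleast_2d(np.asarray(orientations, dtype=float))
    norms = np.linalg.norm(o, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero orientation vector")
    if params.d_rot > 0.0:
        kick = rng.normal(0.0, np.sqrt(2.0 * params.d_rot * dt), size=o.shape)
        o = o + kick
    o = o / np.linalg.norm(o, axis=1)[:, None]
    return o if np.asarray(orientations).ndim > 1 else o[0]


class NeighborList:
    """Verlet-style neighbour lists over cells and static wall particles.

    Candidate pairs are collected with a KD-tree at cutoff
    ``max contact distance + skin`` and stay valid until any cell has moved
    ``skin/2``; forces computed from the candidate set equal the all-pairs
    result exactly (the list is a superset of possible contacts).
    """

    def __init__(self, wall_positions: np.ndarray, wall_radius: float,
                 skin: float = 0.8):
        self.skin = skin
        self.wall_radius = wall_radius
        self._wall_tree = cKDTree(wall_positions)
        self.pairs = np.empty((0, 2), dtype=np.int64)
        self.wall_pairs = np.empty((0, 2), dtype=np.int64)
        self._ref_positions: Optional[np.ndarray] = None
        self._ref_radii: Optional[np.ndarray] = None
        self._built_rmax = 0.0

    def needs_rebuild(self, positions: np.ndarray, radii: np.ndarray) -> bool:
        if self._ref_positions is None:
            return True
        if positions.shape != self._ref_positions.shape:
            return True
        if np.any(radii > self._ref_radii + 0.25):   # growth allowance
            return True
        disp = np.linalg.norm(positions - self._ref_positions, axis=1)
        return bool(disp.max(initial=0.0) > 0.5 * self.skin)

    def rebuild(self, positions: np.ndarray, radii: np.ndarray) -> None:
        """Rebuild candidate pairs with per-cell cutoffs.

        A mixed population (small mitotic cells, tube-filling oocytes) makes
        a single global cutoff wasteful, so cells above ``big_threshold``
        collect their candidates individually while the rest share one
        small-cell cutoff.  The union remains a strict superset of every
        possible contact until the next rebuild.
        """
        n = positions.shape[0]
        if n == 0:
            self.pairs = np.empty((0, 2), dtype=np.int64)
            self.wall_pairs = np.empty((0, 2), dtype=np.int64)
            self._ref_positions = positions.copy()
            self._ref_radii = radii.copy()
            self._built_rmax = 0.0
            return
        grow = 0.25                      # radius-growth allowance
        r_allow = radii + grow
        big_threshold = 3.2
        big = radii > big_threshold
        small_max = float(r_allow[~big].max(initial=big_threshold + grow))

        tree = cKDTree(positions)
        raw = tree.query_pairs(2.0 * small_max + self.skin,
                               output_type="ndarray")
        pair_set = {(int(a), int(b)) for a, b in raw}
        for i in np.nonzero(big)[0]:
            r_i = r_allow[i] + float(r_allow.max()) + self.skin
            for j in tree.query_ball_point(positions[i], r_i):
                if j == i:
                    continue
                pair_set.add((min(int(i), j), max(int(i), j)))
        if pair_set:
            arr = np.array(sorted(pair_set), dtype=np.int64)
        else:
            arr = np.empty((0, 2), dtype=np.int64)
        self.pairs = arr

        wl = self._wall_tree.query_ball_point(
            positions, r_allow + self.wall_radius + self.skin)
        ci, wi = [], []
        for c, lst in enumerate(wl):
            ci.extend([c] * len(lst))
            wi.extend(sorted(lst))
        self.wall_pairs = (np.stack([ci, wi], axis=1).astype(np.int64)
                           if ci else np.empty((0, 2), dtype=np.int64))
        self._ref_positions = positions.copy()
        self._ref_radii = radii.copy()
        self._built_rmax = float(r_allow.max())
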