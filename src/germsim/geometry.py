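"""Rigid U-shaped gonad geometry with static wall particles.

The tube is three analytic pieces joined smoothly in the x-z plane:

* a distal arm: cylinder of radius ``radius`` along +x from the distal tip
  (x = 0) to the bend start (x = ``distal_length``);
* a half-torus bend of centreline radius ``bend_radius`` turning 180 deg;
* a proximal arm: cylinder running back along -x, capped at the proximal
  end (where the uterus would attach).

A rachis -- the shared syncytial core -- is an inner coaxial cylinder
spanning the distal arm only; together with the outer wall it confines
distal cells to a monolayer shell.  Every surface (outer tube, caps,
rachis) is tiled deterministically with static wall particles; cells
interact with them through the same harmonic contact force as with each
other, which is what physically enforces containment.

The *axial coordinate* of a point is the arc length of its nearest
centreline point, measured from the distal tip pole (axial 0); it is the
common x-axis of death histograms, zone definitions and flow fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import yaml

__all__ = ["GonadGeometry", "build_gonad_geometry"]


@dataclass
class GonadGeometry:
    distal_length: float          # um, distal arm (tip to bend start)
    radius: float                 # um, tube radius
    rachis_radius: float          # um, inner core radius (distal arm only)
    bend_radius: float            # um, centreline radius of the half-torus
    proximal_length: float        # um, proximal arm
    wall_radius: float = 0.65     # um, static wall-particle radius
    wall_spacing: float = 0.65    # um, tiling pitch (<= wall_radius: no tunnelling)

    wall_positions: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.rachis_radius >= self.radius:
            raise ValueError("rachis radius must be smaller than tube radius")
        for name in ("distal_length", "radius", "bend_radius",
                     "proximal_length", "wall_radius", "wall_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.wall_positions = self._tile_walls()

    # ------------------------------------------------------------------
    # centreline
    @property
    def bend_start(self) -> float:
        return self.distal_length

    @property
    def bend_length(self) -> float:
        return float(np.pi * self.bend_radius)

    @property
    def total_length(self) -> float:
        return self.distal_length + self.bend_length + self.proximal_length

    @property
    def bend_center(self) -> np.ndarray:
        return np.array([self.distal_length, 0.0, self.bend_radius])

    @property
    def proximal_z(self) -> float:
        return 2.0 * self.bend_radius

    @property
    def proximal_cap_x(self) -> float:
        return self.distal_length - self.proximal_length

    def centerline_point(self, s: Union[float, np.ndarray]) -> np.ndarray:
        """Point(s) on the centreline at arc length ``s`` from the tip."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.zeros(s.shape + (3,))
        Ld, Rb = self.distal_length, self.bend_radius
        distal = s <= Ld
        out[distal, 0] = s[distal]
        in_bend = (s > Ld) & (s <= Ld + self.bend_length)
        theta = (s[in_bend] - Ld) / Rb
        out[in_bend, 0] = Ld + Rb * np.sin(theta)
        out[in_bend, 2] = Rb * (1.0 - np.cos(theta))
        prox = s > Ld + self.bend_length
        out[prox, 0] = Ld - (s[prox] - Ld - self.bend_length)
        out[prox, 2] = self.proximal_z
        return out if out.shape[0] > 1 else out[0]

    def project(self, points: np.ndarray):
        """Project points onto the centreline.

        Returns ``(s, dist, radial_unit, tangent)``: arc length of the
        nearest centreline point, distance to it, the outward radial unit
        vector and the centreline tangent there.  Vectorised over the
        leading axis.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        n = p.shape[0]
        Ld, Rb = self.distal_length, self.bend_radius
        cand_s = np.empty((3, n))
        cand_d = np.full((3, n), np.inf)

        # distal arm segment
        t = np.clip(p[:, 0], 0.0, Ld)
        q = np.stack([t, np.zeros(n), np.zeros(n)], axis=1)
        cand_s[0] = t
        cand_d[0] = np.linalg.norm(p - q, axis=1)

        # bend arc
        wx = p[:, 0] - Ld
        wz = p[:, 2] - Rb
        theta = np.arctan2(wx, -wz)
        theta = np.clip(theta, 0.0, np.pi)
        qb = np.stack([Ld + Rb * np.sin(theta), np.zeros(n),
                       Rb * (1.0 - np.cos(theta))], axis=1)
        cand_s[1] = Ld + Rb * theta
        cand_d[1] = np.linalg.norm(p - qb, axis=1)

        # proximal arm segment
        t2 = np.clip(Ld - p[:, 0], 0.0, self.proximal_length)
        q2 = np.stack([Ld - t2, np.zeros(n), np.full(n, self.proximal_z)],
                      axis=1)
        cand_s[2] = Ld + self.bend_length + t2
        cand_d[2] = np.linalg.norm(p - q2, axis=1)

        best = np.argmin(cand_d, axis=0)
        s = cand_s[best, np.arange(n)]
        d = cand_d[best, np.arange(n)]
        q_near = self.centerline_point(s).reshape(n, 3)
        offset = p - q_near
        with np.errstate(invalid="ignore"):
            radial = np.where(d[:, None] > 1e-12, offset / np.maximum(d, 1e-12)[:, None], 0.0)
        tangent = self._tangent(s)
        return s, d, radial, tangent

    def _tangent(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(s)
        Ld, Rb = self.distal_length, self.bend_radius
        out = np.zeros(s.shape + (3,))
        distal = s <= Ld
        out[distal, 0] = 1.0
        in_bend = (s > Ld) & (s <= Ld + self.bend_length)
        theta = (s[in_bend] - Ld) / Rb
        out[in_bend, 0] = np.cos(theta)
        out[in_bend, 2] = np.sin(theta)
        prox = s > Ld + self.bend_length
        out[prox, 0] = -1.0
        return out

    # convenience scalars -------------------------------------------------
    def axial(self, points: np.ndarray) -> np.ndarray:
        """Arc-length coordinate along the tube, 0 at the distal tip pole."""
        s, _, _, _ = self.project(points)
        return s

    def radial_distance(self, points: np.ndarray) -> np.ndarray:
        _, d, _, _ = self.project(points)
        return d

    def radial_angle(self, points: np.ndarray) -> np.ndarray:
        """Angle of a point around the local centreline, in (-pi, pi].

        The reference direction is +y (perpendicular to the bend plane
        everywhere), so angles are comparable along the whole tube.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        s, d, radial, tangent = self.project(p)
        n1 = np.array([0.0, 1.0, 0.0])
        n2 = np.cross(tangent, np.broadcast_to(n1, tangent.shape))
        offset = radial * d[:, None]
        return np.arctan2((offset * n2).sum(axis=1), offset[:, 1])

    def inside_lumen(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """True where a point lies within the tube (centre-based test)."""
        s, d, _, _ = self.project(np.atleast_2d(points))
        ok = d <= self.radius - margin
        ok &= s <= self.total_length + self.radius
        return ok

    # ------------------------------------------------------------------
    # wall tiling
    def _ring(self, center, axis_u, axis_v, rho, n):
        ang = 2.0 * np.pi * np.arange(n) / n
        return (center[None, :] + rho * np.cos(ang)[:, None] * axis_u[None, :]
                + rho * np.sin(ang)[:, None] * axis_v[None, :])

    def _tile_walls(self) -> np.ndarray:
        h = self.wall_spacing
        R = self.radius
        pts = []
        ey = np.array([0.0, 1.0, 0.0])

        # outer surface: rings perpendicular to the centreline
        n_rings = int(np.ceil(self.total_length / h)) + 1
        svals = np.linspace(0.0, self.total_length, n_rings)
        n_around = max(3, int(np.ceil(2.0 * np.pi * R / h)))
        centers = np.atleast_2d(self.centerline_point(svals))
        tangents = self._tangent(svals)
        for c, t in zip(centers, tangents):
            u = ey
            v = np.cross(t, u)
            v /= np.linalg.norm(v)
            pts.append(self._ring(c, u, v, R, n_around))

        # rachis: inner coaxial cylinder spanning the distal arm only
        n_rx = int(np.ceil(self.distal_length / h)) + 1
        n_ar = max(3, int(np.ceil(2.0 * np.pi * self.rachis_radius / h)))
        for x in np.linspace(0.0, self.distal_length, n_rx):
            pts.append(self._ring(np.array([x, 0.0, 0.0]), ey,
                                  np.array([0.0, 0.0, 1.0]),
                                  self.rachis_radius, n_ar))

        # end caps: disks at the distal tip plane and the proximal cap
        for cx, cz, normal_sign in ((0.0, 0.0, -1.0),
                                    (self.proximal_cap_x, self.proximal_z, 1.0)):
            rhos = np.arange(h, R, h)
            pts.append(np.array([[cx, 0.0, cz]]))
            for rho in rhos:
                n_c = max(3, int(np.ceil(2.0 * np.pi * rho / h)))
                pts.append(self._ring(np.array([cx, 0.0, cz]), ey,
                                      np.array([0.0, 0.0, 1.0]), rho, n_c))
        return np.concatenate(pts, axis=0)

    # ------------------------------------------------------------------
    # structured-text dump / reload (parameters, not particles)
    def to_yaml(self, path: Union[str, Path]) -> None:
        doc = {"gonad_geometry": 1}
        for k in ("distal_length", "radius", "rachis_radius", "bend_radius",
                  "proximal_length", "wall_radius", "wall_spacing"):
            doc[k] = float(getattr(self, k))
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "GonadGeometry":
        doc = yaml.safe_load(Path(path).read_text())
        if doc.get("gonad_geometry") != 1:
            raise ValueError("not a gonad_geometry version 1 document")
        doc.pop("gonad_geometry")
        return cls(**doc)


def build_gonad_geometry(distal_length: float = 120.0, radius: float = 10.0,
                         rachis_radius: float = 4.4, bend_radius: float = 15.0,
                         proximal_length: float = 100.0,
                         wall_radius: float = 0.65,
                         wall_spacing: float = 0.65) -> GonadGeometry:
    """Build a gonad with deterministic wall tiling.

    Defaults are the full-scale tube: the RAS-activating region then spans
    axial 100 um to the bend at 120 um.
    """
    return GonadGeometry(distal_length=distal_length, radius=radius,
                         rachis_radius=rachis_radius, bend_radius=bend_radius,
                         proximal_length=proximal_length,
                         wall_radius=wall_radius, wall_spacing=wall_spacing)
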