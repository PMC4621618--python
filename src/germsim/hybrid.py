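"""The hybrid interface layer and scheduler.

Each germ cell couples a physical particle to one qualitative-network state.
Every hybrid interval (0.3 s by default; the desk-scale presets decimate to
the 3 s timestep cap) the system performs, in order:

1. Brownian-dynamics substeps advance positions and division axes with an
   adaptive timestep (largest drift displacement limited to a fraction of
   the smallest cell radius, capped at ``dt_max``);
2. one synchronous QN step for every cell;
3. cell development on a frozen decision snapshot, ordered
   growth -> apoptosis -> division -> fertilization, so same-frame events
   cannot cascade;
4. the executable update writes ligand-zone membership (or timers, in the
   timed-RAS variant) into each cell's QN inputs.

Ligand zones are axis-aligned cuboids (half-open: inclusive at the min
corner, exclusive at the max): DELTA at the distal tip, a RAS-activating
growth-factor region before the bend, and the sperm (MSP) region at the
proximal end.  Growth is linear in radius and arrested while the contact
pressure on a cell (sum of contact-force magnitudes over its surface area)
exceeds a threshold -- the negative feedback that keeps a loss-of-apoptosis
gonad from rupturing.  The first ``fertilization_cap`` oocytes that reach
the maturation state inside the sperm region are removed (fertilised);
afterwards the tube blocks.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .geometry import GonadGeometry, build_gonad_geometry
from .germline import FATE_VARIABLES, build_germline_qn
from .physics import (Cell, NeighborList, PhysicsParams, cell_mass,
                      bd_position_step, orientation_step, pair_contact_forces,
                      wall_contact_forces)
from .qn.core import qn_step_batch

__all__ = [
    "Zone", "SimConfig", "System", "SimulationError", "zone_contains",
    "per_step_probability", "growth_update", "divide_cell",
    "apoptosis_update", "fertilization_update", "executable_update",
    "system_step", "preset", "PRESETS", "zone_transit_experiment",
    "write_trajectory_xyz", "write_events_ndjson",
]

# fate codes used internally (order matters: index = progression stage)
F_UNDEF, F_MIT, F_PACH, F_DIP, F_DIAK, F_MAT = -1, 0, 1, 2, 3, 4
FATE_NAMES = {F_UNDEF: "undefined", F_MIT: "mitosis", F_PACH: "pachytene",
              F_DIP: "diplotene", F_DIAK: "diakinesis", F_MAT: "maturation"}


class SimulationError(RuntimeError):
    """An invariant violation inside the simulation loop, with frame context."""


@dataclass(frozen=True)
class Zone:
    """Axis-aligned cuboid ligand region writing one QN input variable."""

    lo: tuple
    hi: tuple
    variable: str
    value: int = 1

    def __post_init__(self):
        if not all(a < b for a, b in zip(self.lo, self.hi)):
            raise ValueError("zone must satisfy lo < hi per axis")


def zone_contains(zone: Zone, x: np.ndarray) -> np.ndarray:
    """Half-open membership test: inclusive at lo, exclusive at hi."""
    x = np.asarray(x, dtype=float)
    lo = np.asarray(zone.lo)
    hi = np.asarray(zone.hi)
    inside = (x >= lo) & (x < hi)
    return inside.all(axis=-1)


def per_step_probability(P: float, period: float, dt: float) -> float:
    """Per-timestep probability consistent with probability ``P`` per
    ``period`` under a memoryless hazard: ``1 - (1-P)**(dt/period)``."""
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must be in [0, 1]")
    if period <= 0 or dt <= 0:
        raise ValueError("period and dt must be positive")
    return 1.0 - (1.0 - P) ** (dt / period)


@dataclass
class SimConfig:
    """All rates, thresholds, scenario switches and the seed for one run.

    Defaults are the full-scale wild-type scenario (21-day run in the
    full-size gonad); use :func:`preset` for the desk-scale variants.
    """

    scenario: str = "wildtype"
    seed: int = 0
    duration: float = 21 * 86400.0          # s
    apoptosis_enabled: bool = True
    death_mode: str = "single_step"         # or "multistep"
    death_gate: str = "mapk"                # or "fate" (pro-apoptotic CED3)
    ras_mode: str = "zone"                  # or "timed"

    geometry: dict = field(default_factory=dict)  # build_gonad_geometry kwargs
    physics: PhysicsParams = field(default_factory=PhysicsParams)
    zones: list = field(default_factory=list)     # Zone instances

    # growth & division
    growth_period: float = 72000.0          # s (~20 h) newborn -> division size
    division_threshold_mean: float = 1.9    # um
    division_threshold_sd: float = 0.19     # um (10% of mean)
    oocyte_growth_rate: float = 4.0e-5      # um/s, post-RAS oocyte growth
    oocyte_max_radius: float = 7.5          # um, oocytes fill the tube, then stop
    pressure_threshold: float = 4.0         # pN/um^2, growth arrest

    # death
    death_probability: float = 0.5          # single-step P over death_period
    death_period: float = 313200.0          # s
    shrink_probability: float = 0.5         # multistep shrink P over period
    shrink_period: float = 36000.0          # s
    shrink_quantum: float = 0.12            # um removed per shrink event
    min_radius: float = 0.95                # um, death threshold size
    death_time_scaling: bool = False        # scale hazard with time in zone
    death_time_scale_ref: float = 36000.0   # s, hazard doubling reference

    # fertilization & timed-RAS
    fertilization_cap: int = 150
    ras_delay: float = 180000.0             # s in pachytene before RAS pulse

    # initial condition & output
    init: str = "founder"                   # or "steady"
    founder_state: str = "zeros"            # or "random"
    seed_fill_fraction: float = 0.92        # packing of the steady seeding
    trajectory_interval: float = 600.0      # s between trajectory frames

    def __post_init__(self):
        if self.death_mode not in ("single_step", "multistep"):
            raise ValueError(f"bad death_mode {self.death_mode!r}")
        if self.ras_mode not in ("zone", "timed"):
            raise ValueError(f"bad ras_mode {self.ras_mode!r}")
        if self.death_gate not in ("mapk", "fate"):
            raise ValueError(f"bad death_gate {self.death_gate!r}")
        if not 0.0 <= self.death_probability <= 1.0:
            raise ValueError("death_probability outside [0, 1]")
        if self.fertilization_cap < 0 or self.duration <= 0:
            raise ValueError("cap must be >= 0 and duration > 0")
        self.zones = [z if isinstance(z, Zone)
                      else Zone(tuple(z["lo"]), tuple(z["hi"]), z["variable"],
                                int(z.get("value", 1)))
                      for z in self.zones]

    # derived rates ----------------------------------------------------
    @property
    def birth_radius(self) -> float:
        return self.division_threshold_mean * 2.0 ** (-1.0 / 3.0)

    @property
    def mitotic_growth_rate(self) -> float:
        """Linear radius growth rate taking a newborn to the mean division
        threshold over ``growth_period``."""
        return (self.division_threshold_mean - self.birth_radius) / self.growth_period

    def build_geometry(self) -> GonadGeometry:
        return build_gonad_geometry(**self.geometry)

    def zone_for(self, variable: str) -> Optional[Zone]:
        for z in self.zones:
            if z.variable == variable:
                return z
        return None

    # serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["physics"] = asdict(self.physics)
        doc["zones"] = [{"lo": list(z.lo), "hi": list(z.hi),
                         "variable": z.variable, "value": z.value}
                        for z in self.zones]
        return doc

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump({"germsim_config": 1,
                                              **self.to_dict()},
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if doc.pop("germsim_config", None) != 1:
            raise ValueError("not a germsim_config version 1 document")
        phys = doc.pop("physics", {})
        cfg = cls(**doc)
        cfg.physics = PhysicsParams(**phys)
        return cfg

    def content_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
# scenario presets

def _full_zones() -> list:
    return [
        Zone((-10.0, -10.0, -10.0), (20.0, 10.0, 10.0), "DELTA"),
        Zone((100.0, -10.0, -10.0), (120.0, 10.0, 10.0), "RASinput"),
        Zone((20.0, -10.0, 20.0), (30.0, 10.0, 40.0), "MSP"),
    ]


def _mini_zones() -> list:
    return [
        Zone((-9.7, -9.7, -9.7), (12.0, 9.7, 9.7), "DELTA"),
        Zone((50.0, -9.7, -9.7), (70.0, 9.7, 9.7), "RASinput"),
        Zone((25.0, -9.7, 12.3), (35.0, 9.7, 31.7), "MSP"),
    ]


def _tiny_zones() -> list:
    return [
        Zone((-8.7, -8.7, -8.7), (8.0, 8.7, 8.7), "DELTA"),
        Zone((20.0, -8.7, -8.7), (30.0, 8.7, 8.7), "RASinput"),
        Zone((6.0, -8.7, 11.3), (14.0, 8.7, 28.7), "MSP"),
    ]


def _full_base(**over) -> SimConfig:
    kw = dict(
        geometry=dict(distal_length=120.0, radius=10.0, rachis_radius=4.4,
                      bend_radius=15.0, proximal_length=100.0,
                      wall_radius=0.5, wall_spacing=0.5),
        zones=_full_zones(),
        physics=PhysicsParams(hybrid_interval=0.3),
    )
    kw.update(over)
    return SimConfig(**kw)


def _mini_base(**over) -> SimConfig:
    """Desk-scale gonad: same mechanisms, shortened arms, ~10^2 cells,
    hybrid updates decimated to the 3 s timestep cap."""
    kw = dict(
        scenario="mini_wildtype",
        duration=2 * 86400.0,
        init="steady",
        geometry=dict(distal_length=70.0, radius=9.6, rachis_radius=2.4,
                      bend_radius=11.0, proximal_length=45.0,
                      wall_radius=0.65, wall_spacing=0.65),
        zones=_mini_zones(),
        physics=PhysicsParams(hybrid_interval=3.0),
        division_threshold_mean=2.6,
        division_threshold_sd=0.26,
        oocyte_growth_rate=5.0e-5,
        oocyte_max_radius=6.5,
        death_period=48000.0,
        shrink_period=10000.0,
        shrink_quantum=0.15,
        min_radius=1.3,
        ras_delay=90000.0,
    )
    kw.update(over)
    return SimConfig(**kw)


def _tiny_base(**over) -> SimConfig:
    """Miniature fixture scenario for fast tests: short arms, quick growth."""
    kw = dict(
        scenario="tiny",
        duration=43200.0,
        init="steady",
        geometry=dict(distal_length=30.0, radius=8.6, rachis_radius=1.6,
                      bend_radius=10.0, proximal_length=24.0,
                      wall_radius=0.65, wall_spacing=0.65),
        zones=_tiny_zones(),
        physics=PhysicsParams(hybrid_interval=3.0),
        growth_period=7200.0,
        division_threshold_mean=2.6,
        division_threshold_sd=0.26,
        oocyte_growth_rate=4.0e-5,
        oocyte_max_radius=5.5,
        death_period=14400.0,
        shrink_period=3000.0,
        shrink_quantum=0.15,
        min_radius=1.3,
        ras_delay=7200.0,
    )
    kw.update(over)
    return SimConfig(**kw)


PRESETS = {
    "wildtype": lambda: _full_base(scenario="wildtype"),
    "multistep_death": lambda: _full_base(scenario="multistep_death",
                                          death_mode="multistep"),
    "ced_off": lambda: _full_base(scenario="ced_off", apoptosis_enabled=False),
    "ced_single_step": lambda: _full_base(scenario="ced_single_step",
                                          apoptosis_enabled=False,
                                          death_mode="single_step"),
    "timed_ras": lambda: _full_base(scenario="timed_ras", ras_mode="timed"),
    "mini_wildtype": lambda: _mini_base(),
    "mini_multistep": lambda: _mini_base(scenario="mini_multistep",
                                         death_mode="multistep"),
    "mini_ced": lambda: _mini_base(scenario="mini_ced",
                                   apoptosis_enabled=False),
    "mini_timed": lambda: _mini_base(scenario="mini_timed", ras_mode="timed"),
    "tiny": lambda: _tiny_base(),
    "tiny_ced": lambda: _tiny_base(scenario="tiny_ced",
                                   apoptosis_enabled=False),
}


def preset(name: str, **overrides) -> SimConfig:
    """Build a named scenario preset, optionally overriding fields."""
    try:
        cfg = PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ----------------------------------------------------------------------
# single-cell operations (exchange-type API used by the system and tests)

def growth_update(cell: Cell, dt: float, pressure: float, config: SimConfig,
                  kind: str = "mitotic") -> float:
    """Linear radius growth, arrested above the pressure threshold.

    Oocytes (``kind="oocyte"``) additionally stop at ``oocyte_max_radius``
    (a full-grown oocyte fills the tube)."""
    if pressure > config.pressure_threshold:
        return cell.radius
    if kind == "oocyte" and cell.radius >= config.oocyte_max_radius:
        return cell.radius
    rate = (config.mitotic_growth_rate if kind == "mitotic"
            else config.oocyte_growth_rate)
    cell.radius = cell.radius + rate * dt
    return cell.radius


def divide_cell(parent: Cell, rng: np.random.Generator, config: SimConfig,
                new_ids: Tuple[int, int] = (-1, -2)) -> Tuple[Cell, Cell]:
    """Replace a parent with two equal-volume daughters.

    Daughter radius is ``r_p * 2**(-1/3)`` (volume conservation); centres
    are displaced ``+/- r_d`` along the parent's orientation through the
    parent's centre; each daughter copies the parent QN state, starts with
    the parent's orientation, and draws a fresh jittered division threshold.
    """
    r_d = parent.radius * 2.0 ** (-1.0 / 3.0)
    daughters = []
    for sgn, nid in zip((+1.0, -1.0), new_ids):
        thr = _draw_threshold(rng, config)
        daughters.append(Cell(
            position=parent.position + sgn * r_d * parent.orientation,
            radius=r_d,
            orientation=parent.orientation.copy(),
            qn_state=tuple(parent.qn_state),
            lineage_id=nid,
            birth_time=parent.birth_time,
            division_threshold=thr,
            density=parent.density,
        ))
    return daughters[0], daughters[1]


def _draw_threshold(rng: np.random.Generator, config: SimConfig) -> float:
    thr = rng.normal(config.division_threshold_mean,
                     config.division_threshold_sd)
    lo = config.division_threshold_mean - 2 * config.division_threshold_sd
    hi = config.division_threshold_mean + 2 * config.division_threshold_sd
    return float(np.clip(thr, lo, hi))


def apoptosis_update(cell: Cell, config: SimConfig, dt: float,
                     rng: np.random.Generator, spec=None) -> str:
    """Stochastic death update for one RAS-active cell.

    Returns ``"alive"``, ``"shrunk"`` or ``"dead"``.  With apoptosis
    disabled (ced scenario) the cell always survives.  Calling it on a cell
    whose network is not RAS/pro-apoptotic active is an error when a spec
    is supplied for the check.
    """
    if not config.apoptosis_enabled:
        return "alive"
    if spec is not None and not _death_eligible_state(cell.qn_state, config,
                                                     spec):
        raise ValueError("apoptosis_update called on an ineligible cell")
    if config.death_mode == "single_step":
        p = per_step_probability(config.death_probability,
                                 config.death_period, dt)
        p = _scaled(p, cell.time_in_ras_zone, config)
        return "dead" if rng.random() < p else "alive"
    p = per_step_probability(config.shrink_probability, config.shrink_period,
                             dt)
    p = _scaled(p, cell.time_in_ras_zone, config)
    if rng.random() < p:
        cell.radius = cell.radius - config.shrink_quantum
        if cell.radius <= config.min_radius:
            return "dead"
        return "shrunk"
    return "alive"


def _scaled(p: float, t_ras: float, config: SimConfig) -> float:
    if not config.death_time_scaling:
        return p
    return float(min(1.0, p * (1.0 + t_ras / config.death_time_scale_ref)))


def _death_eligible_state(state, config: SimConfig, spec) -> bool:
    col = "MAPK" if config.death_gate == "mapk" else "CED3"
    return bool(state[spec.index(col)])


def executable_update(cell: Cell, zones: Sequence[Zone], config: SimConfig,
                      clock: float, spec, geometry=None) -> tuple:
    """Write the interface inputs of one cell's QN from its position/timers.

    Zone mode: each ligand input is 1 inside its cuboid and 0 outside.
    Timed mode: ``RASinput`` is pulsed on the update where accumulated
    pachytene time crosses ``ras_delay`` and ``RASdown`` switches on at bend
    entry; DELTA and MSP still follow their zones.
    """
    state = list(cell.qn_state)
    for z in zones:
        if config.ras_mode == "timed" and z.variable == "RASinput":
            continue
        state[spec.index(z.variable)] = (z.value if
                                         bool(zone_contains(z, cell.position))
                                         else 0)
    if config.ras_mode == "zone":
        state[spec.index("RASdown")] = 0
    else:
        dt = config.physics.hybrid_interval
        crossed = (cell.time_in_pachytene >= config.ras_delay
                   and cell.time_in_pachytene - dt < config.ras_delay)
        state[spec.index("RASinput")] = 1 if crossed else 0
        if geometry is not None:
            axial = float(geometry.axial(cell.position[None, :])[0])
            state[spec.index("RASdown")] = (
                1 if axial >= geometry.bend_start else 0)
    cell.qn_state = tuple(state)
    return cell.qn_state


# ----------------------------------------------------------------------
# the system

class System:
    """Living cells + geometry + zones + clock + event log (one run)."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.geometry = config.build_geometry()
        self.spec = build_germline_qn(
            "timed_ras" if config.ras_mode == "timed" else "zone_ras")
        self.rng = np.random.default_rng(config.seed)
        self.clock = 0.0
        self.fert_count = 0
        self.events: List[dict] = []
        self.registry: Dict[int, dict] = {}
        self._next_id = 0
        self._frames: List[pd.DataFrame] = []
        self._next_frame_time = 0.0

        m = self.spec.m
        self.pos = np.empty((0, 3))
        self.radius = np.empty(0)
        self.orientation = np.empty((0, 3))
        self.states = np.empty((0, m), dtype=np.int16)
        self.ids = np.empty(0, dtype=np.int64)
        self.birth = np.empty(0)
        self.thr = np.empty(0)
        self.t_pach = np.empty(0)
        self.t_ras = np.empty(0)
        self.entered_ras = np.empty(0, dtype=bool)
        self.ever_matured = np.empty(0, dtype=bool)
        self.pressure = np.empty(0)

        self._idx = {name: self.spec.index(name)
                     for name in ("DELTA", "RASinput", "MSP", "RASdown",
                                  "MAPK", "CED3")}
        self._fate_idx = [self.spec.index(n) for n in FATE_VARIABLES]
        self.neighbors = NeighborList(self.geometry.wall_positions,
                                      self.geometry.wall_radius,
                                      skin=0.8)
        if config.init == "steady":
            self._seed_steady()
        else:
            self._seed_founder()
        self._apply_zone_inputs()
        self._sample_frame()

    # -- population plumbing -------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.ids)

    @property
    def masses(self) -> np.ndarray:
        return cell_mass(self.radius, self.config.physics.density)

    def _new_ids(self, k: int) -> np.ndarray:
        out = np.arange(self._next_id, self._next_id + k, dtype=np.int64)
        self._next_id += k
        return out

    def _append(self, pos, radius, orientation, states, ids, birth, thr,
                parents=None, generation=None):
        k = len(ids)
        self.pos = np.vstack([self.pos, pos])
        self.radius = np.concatenate([self.radius, radius])
        self.orientation = np.vstack([self.orientation, orientation])
        self.states = np.vstack([self.states, states.astype(np.int16)])
        self.ids = np.concatenate([self.ids, ids])
        self.birth = np.concatenate([self.birth, birth])
        self.thr = np.concatenate([self.thr, thr])
        self.t_pach = np.concatenate([self.t_pach, np.zeros(k)])
        self.t_ras = np.concatenate([self.t_ras, np.zeros(k)])
        self.entered_ras = np.concatenate([self.entered_ras,
                                           np.zeros(k, dtype=bool)])
        self.ever_matured = np.concatenate([self.ever_matured,
                                            np.zeros(k, dtype=bool)])
        self.pressure = np.concatenate([self.pressure, np.zeros(k)])
        for j, cid in enumerate(ids):
            parent = None if parents is None else parents[j]
            gen = 0 if generation is None else generation[j]
            self.registry[int(cid)] = dict(
                birth=float(birth[j]), parent=parent, generation=gen,
                end=None, cause=None, entered_ras=False, matured=False)

    def _remove(self, idx: np.ndarray, cause: str, mechanism: str = ""):
        idx = np.asarray(sorted(set(int(i) for i in idx)), dtype=np.int64)
        if len(idx) == 0:
            return
        axials = self.geometry.axial(self.pos[idx])
        axials = np.atleast_1d(axials)
        for j, i in enumerate(idx):
            cid = int(self.ids[i])
            rec = self.registry[cid]
            rec["end"] = self.clock
            rec["cause"] = cause
            rec["entered_ras"] = bool(self.entered_ras[i])
            rec["matured"] = bool(self.ever_matured[i])
            self.events.append(dict(
                t=self.clock, kind=cause, cell=cid, parent=rec["parent"],
                x=float(self.pos[i, 0]), y=float(self.pos[i, 1]),
                z=float(self.pos[i, 2]), axial=float(axials[j]),
                radius=float(self.radius[i]), mechanism=mechanism))
        keep = np.ones(self.n_cells, dtype=bool)
        keep[idx] = False
        for name in ("radius", "ids", "birth", "thr", "t_pach", "t_ras",
                     "entered_ras", "ever_matured", "pressure"):
            setattr(self, name, getattr(self, name)[keep])
        self.pos = self.pos[keep]
        self.orientation = self.orientation[keep]
        self.states = self.states[keep]

    # -- initial conditions --------------------------------------------
    def _random_unit(self, k: int) -> np.ndarray:
        v = self.rng.normal(size=(k, 3))
        return v / np.linalg.norm(v, axis=1)[:, None]

    def _seed_founder(self):
        g = self.geometry
        rho = 0.5 * (g.rachis_radius + g.radius)
        pos = np.array([[2.0, 0.0, rho]])
        if self.config.founder_state == "random":
            state = np.array([[self.rng.integers(0, v.nmax + 1)
                               for v in self.spec.variables]], dtype=np.int16)
        else:
            state = np.zeros((1, self.spec.m), dtype=np.int16)
        ids = self._new_ids(1)
        self._append(pos, np.array([self.config.birth_radius]),
                     self._random_unit(1), state, ids, np.zeros(1),
                     np.array([_draw_threshold(self.rng, self.config)]))
        self._log_birth(ids, parents=[None])

    def _chain_states(self) -> Dict[str, np.ndarray]:
        """Terminal QN state per gonad compartment (steady-flow seeding)."""
        from .germline import compartment_environments
        from .stability import compartment_chain
        reports = compartment_chain(self.spec, compartment_environments())
        out = {}
        for rep in reports:
            out[rep.name] = np.array(rep.terminal_states[0], dtype=np.int16)
        return out

    def _seed_steady(self):
        g = self.geometry
        cfg = self.config
        chain = self._chain_states()
        delta_zone = cfg.zone_for("DELTA")
        ras_zone = cfg.zone_for("RASinput")
        ras_lo = ras_zone.lo[0] if ras_zone else g.bend_start
        delta_hi = delta_zone.hi[0] if delta_zone else 10.0

        pos_list, rad_list, state_list = [], [], []
        # distal arm: monolayer shell rings between rachis and outer wall
        rho = 0.5 * (g.rachis_radius + g.radius)
        r_seed = 0.5 * (cfg.birth_radius + cfg.division_threshold_mean)
        pitch = 2.0 * r_seed * cfg.seed_fill_fraction
        x = r_seed
        while x < g.distal_length - 0.5 * r_seed:
            n_around = max(3, int(math.floor(2 * np.pi * rho / pitch)))
            ang = 2 * np.pi * (np.arange(n_around) +
                               self.rng.uniform(0, 1)) / n_around
            for a in ang:
                pos_list.append([x, rho * np.cos(a), rho * np.sin(a)])
                rad_list.append(self.rng.uniform(cfg.birth_radius,
                                                 cfg.division_threshold_mean))
                if x < delta_hi:
                    state_list.append(chain["distal_tip"])
                elif x < ras_lo:
                    state_list.append(chain["meiotic_entry"])
                else:
                    state_list.append(chain["ras_zone"])
            x += pitch
        # bend + proximal arm: single file of oocytes along the centreline,
        # seeded backward from the proximal cap (largest oocytes proximal,
        # so the maturation queue is populated from the start)
        r_min_ooc = cfg.division_threshold_mean * 1.05
        r_ooc = min(0.45 * (g.radius + g.rachis_radius), 0.9 * g.radius)
        s = g.total_length - r_ooc
        while s > g.bend_start + r_min_ooc:
            q = np.atleast_2d(self.geometry.centerline_point(s))[0]
            pos_list.append(list(q + self.rng.normal(0, 0.05, size=3)))
            rad_list.append(r_ooc)
            state_list.append(chain["bend"])
            r_next = max(r_ooc / 1.04, r_min_ooc)
            s -= (r_ooc + r_next) * 0.98
            r_ooc = r_next

        n = len(pos_list)
        ids = self._new_ids(n)
        self._append(np.array(pos_list), np.array(rad_list),
                     self._random_unit(n),
                     np.array(state_list, dtype=np.int16), ids,
                     np.zeros(n),
                     np.array([_draw_threshold(self.rng, self.config)
                               for _ in range(n)]))
        self._log_birth(ids, parents=[None] * n)

    def _log_birth(self, ids, parents):
        for cid, parent in zip(ids, parents):
            i = int(np.nonzero(self.ids == cid)[0][0])
            self.events.append(dict(
                t=self.clock, kind="birth", cell=int(cid), parent=parent,
                x=float(self.pos[i, 0]), y=float(self.pos[i, 1]),
                z=float(self.pos[i, 2]),
                axial=float(np.atleast_1d(
                    self.geometry.axial(self.pos[i][None, :]))[0]),
                radius=float(self.radius[i]), mechanism=""))

    # -- per-interval machinery ----------------------------------------
    def _forces(self):
        k = self.config.physics.spring_k
        if self.neighbors.needs_rebuild(self.pos, self.radius):
            self.neighbors.rebuild(self.pos, self.radius)
        f_cc, m_cc = pair_contact_forces(self.pos, self.radius,
                                         self.neighbors.pairs, k,
                                         fallback_axes=self.orientation)
        f_w, m_w = wall_contact_forces(self.pos, self.radius,
                                       self.geometry.wall_positions,
                                       self.geometry.wall_radius,
                                       self.neighbors.wall_pairs, k)
        return f_cc + f_w, m_cc + m_w

    def _bd_interval(self, interval: float):
        phys = self.config.physics
        remaining = interval
        masses = self.masses
        while remaining > 1e-9:
            forces, mags = self._forces()
            if self.n_cells:
                beta = phys.beta(masses)
                drift_speed = np.sqrt(
                    np.einsum("ij,ij->i", forces, forces)) * beta
                vmax = float(drift_speed.max(initial=0.0))
                r_min = float(self.radius.min())
                dt = phys.dt_max if vmax <= 1e-12 else min(
                    phys.dt_max, phys.drift_fraction * r_min / vmax)
                dt = min(dt, remaining)
                noise = self.rng.normal(size=(self.n_cells, 3))
                self.pos = bd_position_step(self.pos, forces, masses,
                                            phys, dt, noise)
                self.orientation = orientation_step(self.orientation, phys,
                                                    dt, self.rng)
                self.pressure = mags / (4.0 * np.pi * self.radius ** 2)
            else:
                dt = remaining
            remaining -= dt

    def _fate_codes(self) -> np.ndarray:
        codes = np.full(self.n_cells, F_UNDEF, dtype=np.int8)
        # ascending priority: later stages overwrite earlier ones
        for code, idx in zip((F_MIT, F_PACH, F_DIP, F_DIAK, F_MAT),
                             self._fate_idx):
            codes[self.states[:, idx] > 0] = code
        return codes

    def _development(self, interval: float):
        cfg = self.config
        fates = self._fate_codes()
        self.ever_matured |= fates == F_MAT

        births = deaths = ferts = 0
        n_before = self.n_cells

        # growth (linear, pressure-gated; oocytes stop at their size cap)
        ok = self.pressure <= cfg.pressure_threshold
        mit = (fates == F_MIT) & ok
        ooc = ((fates == F_DIAK) | (fates == F_MAT)) & ok \
            & (self.radius < cfg.oocyte_max_radius)
        self.radius[mit] += cfg.mitotic_growth_rate * interval
        self.radius[ooc] += cfg.oocyte_growth_rate * interval

        # apoptosis
        dead_idx: List[int] = []
        if cfg.apoptosis_enabled:
            gate = self._idx["MAPK" if cfg.death_gate == "mapk" else "CED3"]
            eligible = self.states[:, gate] > 0
            if np.any(eligible):
                idx = np.nonzero(eligible)[0]
                u = self.rng.random(len(idx))
                if cfg.death_mode == "single_step":
                    p = per_step_probability(cfg.death_probability,
                                             cfg.death_period, interval)
                    p = self._scaled_vec(p, idx)
                    dead_idx = list(idx[u < p])
                else:
                    p = per_step_probability(cfg.shrink_probability,
                                             cfg.shrink_period, interval)
                    p = self._scaled_vec(p, idx)
                    shrunk = idx[u < p]
                    self.radius[shrunk] -= cfg.shrink_quantum
                    dead_idx = list(shrunk[self.radius[shrunk]
                                           <= cfg.min_radius])
        if dead_idx:
            deaths = len(dead_idx)
            self._remove(np.array(dead_idx), "apoptosis",
                         mechanism=cfg.death_mode)
            fates = self._fate_codes()

        # division (mitotic fate, radius past its jittered threshold);
        # descending index order so earlier removals don't shift later ones
        div_idx = np.nonzero((fates == F_MIT) & (self.radius >= self.thr))[0]
        for i in sorted((int(i) for i in div_idx), reverse=True):
            self._divide_index(i)
            births += 2
        if len(div_idx):
            fates = self._fate_codes()

        # fertilization: matured oocytes inside the sperm region, up to cap
        msp_zone = cfg.zone_for("MSP")
        if msp_zone is not None and self.fert_count < cfg.fertilization_cap:
            mat = np.nonzero((fates == F_MAT) &
                             zone_contains(msp_zone, self.pos))[0]
            room = cfg.fertilization_cap - self.fert_count
            take = mat[:room]
            if len(take):
                ferts = len(take)
                self.fert_count += ferts
                self._remove(take, "fertilization")

        n_after = self.n_cells
        if n_after != n_before + births - births // 2 - deaths - ferts:
            # births adds 2 daughters and removes 1 parent per division
            raise SimulationError(
                f"bookkeeping violated at t={self.clock}: {n_before} "
                f"+{births} -{deaths} -{ferts} != {n_after}")

    def _scaled_vec(self, p: float, idx: np.ndarray):
        if not self.config.death_time_scaling:
            return p
        scale = 1.0 + self.t_ras[idx] / self.config.death_time_scale_ref
        return np.minimum(1.0, p * scale)

    def _divide_index(self, i: int):
        cfg = self.config
        parent_id = int(self.ids[i])
        rec = self.registry[parent_id]
        ids = self._new_ids(2)
        r_d = self.radius[i] * 2.0 ** (-1.0 / 3.0)
        axis = self.orientation[i]
        pos = np.stack([self.pos[i] + r_d * axis, self.pos[i] - r_d * axis])
        state = np.stack([self.states[i], self.states[i]])
        thr = np.array([_draw_threshold(self.rng, cfg),
                        _draw_threshold(self.rng, cfg)])
        axial = float(np.atleast_1d(
            self.geometry.axial(self.pos[i][None, :]))[0])
        # log division on the parent, then replace it by the daughters
        rec["end"] = self.clock
        rec["cause"] = "division"
        rec["entered_ras"] = bool(self.entered_ras[i])
        rec["matured"] = bool(self.ever_matured[i])
        self.events.append(dict(
            t=self.clock, kind="division", cell=parent_id,
            parent=rec["parent"], x=float(self.pos[i, 0]),
            y=float(self.pos[i, 1]), z=float(self.pos[i, 2]), axial=axial,
            radius=float(self.radius[i]), mechanism=""))
        keep = np.ones(self.n_cells, dtype=bool)
        keep[i] = False
        for name in ("radius", "ids", "birth", "thr", "t_pach", "t_ras",
                     "entered_ras", "ever_matured", "pressure"):
            setattr(self, name, getattr(self, name)[keep])
        self.pos = self.pos[keep]
        self.orientation = self.orientation[keep]
        self.states = self.states[keep]
        self._append(pos, np.array([r_d, r_d]),
                     np.stack([axis, axis]), state, ids,
                     np.full(2, self.clock), thr,
                     parents=[parent_id, parent_id],
                     generation=[rec["generation"] + 1] * 2)
        for cid, p in zip(ids, pos):
            self.events.append(dict(
                t=self.clock, kind="birth", cell=int(cid), parent=parent_id,
                x=float(p[0]), y=float(p[1]), z=float(p[2]),
                axial=float(np.atleast_1d(
                    self.geometry.axial(p[None, :]))[0]),
                radius=r_d, mechanism=""))

    def _apply_zone_inputs(self):
        cfg = self.config
        if self.n_cells == 0:
            return
        for z in cfg.zones:
            if cfg.ras_mode == "timed" and z.variable == "RASinput":
                continue
            inside = zone_contains(z, self.pos)
            self.states[:, self._idx[z.variable]] = np.where(inside,
                                                             z.value, 0)
        ras_zone = cfg.zone_for("RASinput")
        interval = cfg.physics.hybrid_interval
        fates = self._fate_codes()
        self.t_pach[fates == F_PACH] += interval
        if cfg.ras_mode == "zone":
            # no timed downregulation signal in the spatial-ligand variant:
            # RAS decays because the zone input vanishes past the bend
            self.states[:, self._idx["RASdown"]] = 0
            if ras_zone is not None:
                in_ras = zone_contains(ras_zone, self.pos)
                self.entered_ras |= in_ras
                self.t_ras[in_ras] += interval
        else:
            crossed = ((self.t_pach >= cfg.ras_delay) &
                       (self.t_pach - interval < cfg.ras_delay))
            self.states[:, self._idx["RASinput"]] = crossed.astype(np.int16)
            axial = self.geometry.axial(self.pos)
            self.states[:, self._idx["RASdown"]] = (
                np.atleast_1d(axial) >= self.geometry.bend_start
            ).astype(np.int16)
            ras_on = self.states[:, self.spec.index("RAS")] > 0
            self.entered_ras |= ras_on
            self.t_ras[ras_on] += interval

    def _sample_frame(self):
        if self.clock + 1e-9 < self._next_frame_time:
            return
        self._next_frame_time = self.clock + self.config.trajectory_interval
        if self.n_cells == 0:
            return
        fates = self._fate_codes()
        self._frames.append(pd.DataFrame({
            "t": self.clock, "cell": self.ids,
            "x": self.pos[:, 0], "y": self.pos[:, 1], "z": self.pos[:, 2],
            "radius": self.radius,
            "fate": [FATE_NAMES[int(c)] for c in fates]}))

    # -- public stepping -------------------------------------------------
    def step(self):
        """Advance one hybrid interval (physics, QN, development, interface)."""
        interval = self.config.physics.hybrid_interval
        self._bd_interval(interval)
        if self.n_cells:
            self.states = qn_step_batch(self.spec, self.states)
        self._development(interval)
        self._apply_zone_inputs()
        self.clock += interval
        self._sample_frame()
        return self

    def run(self, duration: Optional[float] = None,
            progress: bool = False):
        """Run for ``duration`` seconds of simulated time (default: the
        configured run duration)."""
        duration = self.config.duration if duration is None else duration
        t_end = self.clock + duration
        interval = self.config.physics.hybrid_interval
        n_steps = int(round((t_end - self.clock) / interval))
        for k in range(n_steps):
            self.step()
            if progress and k % 2000 == 0:
                print(f"  t={self.clock / 3600.0:8.2f} h  cells={self.n_cells}"
                      f"  ferts={self.fert_count}", flush=True)
        return self

    # -- outputs ---------------------------------------------------------
    def events_dataframe(self) -> pd.DataFrame:
        cols = ["t", "kind", "cell", "parent", "x", "y", "z", "axial",
                "radius", "mechanism"]
        if not self.events:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(self.events)[cols]

    def trajectory_dataframe(self) -> pd.DataFrame:
        if not self._frames:
            return pd.DataFrame(columns=["t", "cell", "x", "y", "z",
                                         "radius", "fate"])
        return pd.concat(self._frames, ignore_index=True)

    def registry_dataframe(self) -> pd.DataFrame:
        rows = []
        for cid, rec in self.registry.items():
            i = np.nonzero(self.ids == cid)[0]
            alive = len(i) > 0
            rows.append(dict(
                cell=cid, parent=rec["parent"], generation=rec["generation"],
                birth=rec["birth"],
                end=rec["end"] if rec["end"] is not None else self.clock,
                cause=rec["cause"] if rec["cause"] else "censored",
                entered_ras=(bool(self.entered_ras[i[0]]) if alive
                             else rec["entered_ras"]),
                matured=(bool(self.ever_matured[i[0]]) if alive
                         else rec["matured"])))
        return pd.DataFrame(rows)

    def ras_outcomes(self) -> dict:
        """Fate resolution of cells that entered the RAS-activation region.

        ``fraction_died`` is deaths / (deaths + maturations) among entrants
        whose fate has resolved (died by apoptosis, or reached maturation).
        """
        reg = self.registry_dataframe()
        entered = reg[reg.entered_ras]
        died = int((entered.cause == "apoptosis").sum())
        matured = int(((entered.cause == "fertilization") |
                       entered.matured).sum())
        resolved = died + matured
        return dict(entered=int(len(entered)), died=died, matured=matured,
                    resolved=resolved,
                    fraction_died=died / resolved if resolved else float("nan"))

    def cells(self) -> List[Cell]:
        """Exchange-type view of the living population."""
        out = []
        for i in range(self.n_cells):
            out.append(Cell(
                position=self.pos[i].copy(), radius=float(self.radius[i]),
                orientation=self.orientation[i].copy(),
                qn_state=tuple(int(x) for x in self.states[i]),
                lineage_id=int(self.ids[i]),
                birth_time=float(self.birth[i]),
                division_threshold=float(self.thr[i]),
                density=self.config.physics.density,
                time_in_pachytene=float(self.t_pach[i]),
                time_in_ras_zone=float(self.t_ras[i])))
        return out

    def manifest(self) -> dict:
        from . import __version__
        return dict(config_hash=self.config.content_hash(),
                    scenario=self.config.scenario, seed=self.config.seed,
                    version=__version__, clock=self.clock,
                    n_cells=self.n_cells, fertilizations=self.fert_count)


def system_step(system: System, rng=None) -> System:
    """Advance the system one hybrid interval (functional-style wrapper)."""
    return system.step()


def fertilization_update(system: System) -> int:
    """Remove matured oocytes in the sperm region up to the cap; returns the
    number fertilised in this call."""
    before = system.fert_count
    cfg = system.config
    msp_zone = cfg.zone_for("MSP")
    if msp_zone is None or system.fert_count >= cfg.fertilization_cap:
        return 0
    fates = system._fate_codes()
    mat = np.nonzero((fates == F_MAT) &
                     zone_contains(msp_zone, system.pos))[0]
    take = mat[:cfg.fertilization_cap - system.fert_count]
    if len(take):
        system.fert_count += len(take)
        system._remove(take, "fertilization")
    return system.fert_count - before


# ----------------------------------------------------------------------
# scripted steady-flow column through the RAS zone

def zone_transit_experiment(config: SimConfig, n_cells: int = 600,
                            zone_length: float = 20.0,
                            cell_diameter: float = 2.0,
                            transit_time: float = 360000.0,
                            dt: float = 60.0,
                            seed: int = 0,
                            shrink_steps: Optional[int] = None) -> dict:
    """Scripted packed column of cells flowing through the RAS region.

    Cells are injected at the distal edge of the zone and advance in single
    file at constant packing (a death leaves a gap that is absorbed by the
    cells behind it), which is the steady-flow abstraction of the gonad's
    packed tube.  Each cell in the zone receives the configured death
    machinery every ``dt``; cells that cross the far edge have survived.

    Returns death axial positions (relative to the zone start), survivor
    count, and the realised death fraction.
    """
    rng = np.random.default_rng(seed)
    slots = zone_length / cell_diameter
    injection_interval = transit_time / slots
    single = config.death_mode == "single_step"
    p_step = per_step_probability(
        config.death_probability if single else config.shrink_probability,
        config.death_period if single else config.shrink_period, dt)
    if shrink_steps is None:
        shrink_steps = max(1, int(math.ceil(
            (config.division_threshold_mean - config.min_radius)
            / config.shrink_quantum)))

    x: List[float] = []           # positions, ordered back -> front
    quanta: List[int] = []        # shrink events accumulated (multistep)
    ghost: List[bool] = []        # pusher cells keeping flow after the last
    injected = 0                  # real injection (immune to death, uncounted)
    deaths: List[float] = []
    survivors = 0
    t = 0.0
    next_inject = 0.0
    while injected < n_cells or any(not g for g in ghost):
        if t + 1e-9 >= next_inject:
            # push a cell into the back of the column; the push is absorbed
            # by the first gap ahead of it (constant packing)
            x.insert(0, 0.5 * cell_diameter)
            quanta.insert(0, 0)
            ghost.insert(0, injected >= n_cells)
            for i in range(1, len(x)):
                x[i] = max(x[i], x[i - 1] + cell_diameter)
            injected += 0 if ghost[0] else 1
            next_inject += injection_interval
        # exits at the proximal (bend) edge
        while x and x[-1] >= zone_length + 0.5 * cell_diameter:
            if not ghost[-1]:
                survivors += 1
            x.pop()
            quanta.pop()
            ghost.pop()
        # death machinery for real cells inside the zone
        if config.apoptosis_enabled and x:
            arr = np.array(x)
            real = ~np.array(ghost)
            in_zone = real & (arr < zone_length)
            u = rng.random(len(arr))
            hit = in_zone & (u < p_step)
            kill = []
            if single:
                kill = list(np.nonzero(hit)[0])
            else:
                for i in np.nonzero(hit)[0]:
                    quanta[i] += 1
                    if quanta[i] >= shrink_steps:
                        kill.append(i)
            for i in sorted(kill, reverse=True):
                deaths.append(x[i])
                del x[i]
                del quanta[i]
                del ghost[i]
        t += dt
        if t > 1e10:  # pragma: no cover - runaway guard
            raise SimulationError("zone transit experiment did not drain")
    n_total = survivors + len(deaths)
    return dict(deaths=np.array(deaths), survivors=survivors,
                n=n_total, fraction_died=len(deaths) / max(n_total, 1))


# ----------------------------------------------------------------------
# writers

def write_trajectory_xyz(traj: pd.DataFrame, path: Union[str, Path]) -> None:
    """Per-frame XYZ-with-comment records (id, position, radius, fate)."""
    with open(path, "w") as fh:
        for t, frame in traj.groupby("t", sort=True):
            fh.write(f"{len(frame)}\n")
            fh.write(f"t={t:.3f} s  columns=id,x,y,z,radius,fate\n")
            for row in frame.itertuples(index=False):
                fh.write(f"{row.cell} {row.x:.4f} {row.y:.4f} {row.z:.4f} "
                         f"{row.radius:.4f} {row.fate}\n")


def write_events_ndjson(events: pd.DataFrame, path: Union[str, Path]) -> None:
    """Line-delimited structured event records."""
    events.to_json(path, orient="records", lines=True)
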