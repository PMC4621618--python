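"""Interface-layer operations and whole-system behaviour on tiny runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from germsim.hybrid import (SimConfig, System, Zone, apoptosis_update,
                            divide_cell, executable_update,
                            fertilization_update, growth_update,
                            per_step_probability, preset, zone_contains)
from germsim.lineage import LineageTree
from germsim.physics import Cell


def make_cell(pos=(0, 0, 0), r=2.0, state=None, spec=None, **kw):
    if state is None and spec is not None:
        state = (0,) * spec.m
    return Cell(position=np.array(pos, dtype=float), radius=r,
                orientation=np.array([1.0, 0.0, 0.0]),
                qn_state=tuple(state or ()), lineage_id=0, **kw)


# -- zones ------------------------------------------------------------------

def test_zone_half_open_convention():
    z = Zone((0, 0, 0), (1, 1, 1), "DELTA")
    assert zone_contains(z, np.array([0.0, 0.0, 0.0]))
    assert not zone_contains(z, np.array([1.0, 1.0, 1.0]))
    assert not zone_contains(z, np.array([0.5, 1.0, 0.5]))


def test_zone_matches_coordinatewise_oracle(rng):
    z = Zone((-1, 0, 2), (4, 3, 5), "MSP")
    pts = rng.uniform(-2, 6, (1000, 3))
    got = zone_contains(z, pts)
    want = np.array([all(lo <= c < hi for c, lo, hi in
                         zip(p, z.lo, z.hi)) for p in pts])
    assert np.array_equal(got, want)


def test_zone_validation():
    with pytest.raises(ValueError):
        Zone((0, 0, 0), (1, -1, 1), "DELTA")


# -- probability conversion -------------------------------------------------

def test_per_step_probability_limits():
    assert per_step_probability(0.0, 100.0, 7.0) == 0.0
    assert per_step_probability(0.4, 100.0, 100.0) == pytest.approx(0.4)
    with pytest.raises(ValueError):
        per_step_probability(1.5, 100.0, 1.0)
    with pytest.raises(ValueError):
        per_step_probability(0.5, -1.0, 1.0)


def test_per_step_probability_compounds_exactly(rng):
    """Compounding the per-step hazard over period/dt steps recovers the
    configured period probability to 1e-9 (20 random parameter sets)."""
    for _ in range(20):
        P = float(rng.uniform(0.05, 0.95))
        period = float(rng.uniform(10.0, 1e5))
        n = int(rng.integers(2, 50))
        dt = period / n
        p = per_step_probability(P, period, dt)
        survive = (1.0 - p) ** n
        assert abs((1.0 - survive) - P) < 1e-9


# -- growth -----------------------------------------------------------------

def test_growth_arrested_above_pressure_threshold():
    cfg = preset("tiny")
    cell = make_cell(r=2.0)
    r = growth_update(cell, 1000.0, pressure=cfg.pressure_threshold + 1.0,
                      config=cfg)
    assert r == 2.0


def test_growth_is_linear_and_additive():
    cfg = preset("tiny")
    a, b = make_cell(r=2.0), make_cell(r=2.0)
    growth_update(a, 500.0, 0.0, cfg)
    growth_update(a, 500.0, 0.0, cfg)
    growth_update(b, 1000.0, 0.0, cfg)
    assert a.radius == pytest.approx(b.radius, abs=1e-12)


def test_growth_rate_reaches_threshold_in_one_period():
    """A newborn mitotic cell grows to the mean division threshold over the
    configured growth period (~20 h at full scale)."""
    cfg = preset("wildtype")
    assert cfg.growth_period == pytest.approx(72000.0)   # ~20 h
    cell = make_cell(r=cfg.birth_radius)
    growth_update(cell, cfg.growth_period, 0.0, cfg)
    assert cell.radius == pytest.approx(cfg.division_threshold_mean, rel=1e-9)


# -- division ---------------------------------------------------------------

def test_daughter_radius_preserves_volume():
    cfg = preset("tiny")
    rng = np.random.default_rng(0)
    parent = make_cell(r=1.0)
    d1, d2 = divide_cell(parent, rng, cfg)
    assert d1.radius == pytest.approx(2.0 ** (-1.0 / 3.0), abs=1e-12)
    for _ in range(1000):
        r = float(np.random.default_rng(_).uniform(0.5, 4.0))
        parent = make_cell(r=r)
        d1, d2 = divide_cell(parent, rng, cfg)
        vol = lambda rr: rr ** 3
        assert abs(vol(d1.radius) + vol(d2.radius) - vol(r)) / vol(r) < 1e-12


def test_daughters_copy_parent_network_state():
    cfg = preset("tiny")
    rng = np.random.default_rng(0)
    parent = make_cell(r=2.0, state=(1, 0, 1, 1, 0))
    d1, d2 = divide_cell(parent, rng, cfg)
    assert d1.qn_state == parent.qn_state
    assert d2.qn_state == parent.qn_state


def test_daughters_displaced_along_orientation():
    cfg = preset("tiny")
    rng = np.random.default_rng(0)
    parent = make_cell(pos=(5.0, 1.0, -2.0), r=2.0)
    parent.orientation = np.array([0.0, 1.0, 0.0])
    d1, d2 = divide_cell(parent, rng, cfg)
    r_d = 2.0 * 2 ** (-1.0 / 3.0)
    assert np.allclose(d1.position, [5.0, 1.0 + r_d, -2.0])
    assert np.allclose(d2.position, [5.0, 1.0 - r_d, -2.0])
    assert np.allclose(0.5 * (d1.position + d2.position), parent.position)


def test_division_thresholds_are_jittered():
    cfg = preset("tiny")
    rng = np.random.default_rng(0)
    thr = {divide_cell(make_cell(r=2.0), rng, cfg)[0].division_threshold
           for _ in range(20)}
    assert len(thr) > 10
    assert all(abs(t - cfg.division_threshold_mean)
               <= 2 * cfg.division_threshold_sd + 1e-12 for t in thr)


# -- apoptosis --------------------------------------------------------------

def test_ced_scenario_never_dies(germline_spec, rng):
    cfg = preset("tiny_ced")
    cell = make_cell(spec=germline_spec)
    for _ in range(200):
        assert apoptosis_update(cell, cfg, 3.0, rng) == "alive"


def test_multistep_shrinks_to_death(germline_spec):
    cfg = preset("tiny", death_mode="multistep")
    state = [0] * germline_spec.m
    state[germline_spec.index("MAPK")] = 1
    cell = make_cell(r=cfg.min_radius + cfg.shrink_quantum, state=state)
    rng = np.random.default_rng(0)
    outcomes = set()
    for _ in range(2000):
        out = apoptosis_update(cell, cfg, 3.0, rng, spec=germline_spec)
        outcomes.add(out)
        if out == "dead":
            break
        assert out == "alive"           # one shrink from death -> dead
    assert outcomes == {"alive", "dead"}


def test_apoptosis_on_ineligible_cell_is_an_error(germline_spec, rng):
    cfg = preset("tiny")
    cell = make_cell(spec=germline_spec)        # MAPK inactive
    with pytest.raises(ValueError):
        apoptosis_update(cell, cfg, 3.0, rng, spec=germline_spec)


# -- executable update ------------------------------------------------------

def test_zone_mode_sets_and_clears_ligand_inputs(germline_spec):
    cfg = preset("tiny")
    delta = cfg.zone_for("DELTA")
    cell = make_cell(pos=(2.0, 0.0, 4.0), spec=germline_spec)
    state = executable_update(cell, cfg.zones, cfg, 0.0, germline_spec)
    assert state[germline_spec.index("DELTA")] == 1
    cell.position = np.array([40.0, 0.0, 4.0])  # outside every zone
    state = executable_update(cell, cfg.zones, cfg, 0.0, germline_spec)
    for name in ("DELTA", "RASinput", "MSP", "RASdown"):
        assert state[germline_spec.index(name)] == 0


def test_timed_mode_pulses_ras_after_pachytene_delay(germline_timed_spec):
    """A stationary cell in pachytene triggers the RAS pulse on the hybrid
    update where its pachytene timer crosses the configured delay."""
    cfg = preset("tiny", ras_mode="timed")
    spec = germline_timed_spec
    dt = cfg.physics.hybrid_interval
    cell = make_cell(pos=(15.0, 0.0, 4.0), spec=spec)
    cell.time_in_pachytene = cfg.ras_delay - dt / 2
    state = executable_update(cell, cfg.zones, cfg, 0.0, spec)
    assert state[spec.index("RASinput")] == 0
    cell.time_in_pachytene += dt             # crosses the delay now
    state = executable_update(cell, cfg.zones, cfg, 0.0, spec)
    assert state[spec.index("RASinput")] == 1
    cell.time_in_pachytene += dt             # pulse is one update long
    state = executable_update(cell, cfg.zones, cfg, 0.0, spec)
    assert state[spec.index("RASinput")] == 0


def test_timed_mode_sets_rasdown_past_bend(germline_timed_spec):
    cfg = preset("tiny", ras_mode="timed")
    geom = cfg.build_geometry()
    spec = germline_timed_spec
    cell = make_cell(pos=(29.0, 0.0, 4.0), spec=spec)   # distal arm
    state = executable_update(cell, cfg.zones, cfg, 0.0, spec, geometry=geom)
    assert state[spec.index("RASdown")] == 0
    cell.position = np.array([31.0, 0.0, 8.0])          # in the bend
    state = executable_update(cell, cfg.zones, cfg, 0.0, spec, geometry=geom)
    assert state[spec.index("RASdown")] == 1


# -- fertilization ----------------------------------------------------------

def _system_with_oocyte_in_sperm_zone():
    cfg = preset("tiny", init="founder", apoptosis_enabled=False)
    system = System(cfg)
    # teleport the founder into the sperm region with a matured state
    msp = cfg.zone_for("MSP")
    center = 0.5 * (np.array(msp.lo) + np.array(msp.hi))
    system.pos[0] = center
    s = np.zeros(system.spec.m, dtype=np.int16)
    s[system.spec.index("MATURATION")] = 1
    s[system.spec.index("DIAKINESIS")] = 1
    system.states[0] = s
    return system


def test_matured_oocyte_in_sperm_zone_is_fertilized():
    system = _system_with_oocyte_in_sperm_zone()
    n = fertilization_update(system)
    assert n == 1
    assert system.fert_count == 1
    assert system.n_cells == 0
    ev = system.events_dataframe()
    assert (ev.kind == "fertilization").sum() == 1


def test_fertilization_stops_at_cap():
    system = _system_with_oocyte_in_sperm_zone()
    system.fert_count = system.config.fertilization_cap
    assert fertilization_update(system) == 0
    assert system.n_cells == 1              # tube blocked, oocyte remains


# -- whole-system behaviour -------------------------------------------------

def test_empty_system_steps_cleanly():
    cfg = preset("tiny", init="founder")
    system = System(cfg)
    system._remove(np.array([0]), "apoptosis")
    t0 = system.clock
    n_events = len(system.events)
    system.step()
    assert system.clock == pytest.approx(t0 + cfg.physics.hybrid_interval)
    assert system.n_cells == 0
    assert len(system.events) == n_events


def test_identical_seeds_give_identical_event_logs():
    runs = []
    for _ in range(2):
        system = System(preset("tiny", seed=42, duration=7200.0))
        system.run()
        runs.append(system.events_dataframe())
    pd.testing.assert_frame_equal(runs[0], runs[1])


def test_no_lifecycle_means_constant_population():
    """With apoptosis off, no growth and the cap reached, the cell count
    never changes: physics alone conserves cells."""
    cfg = preset("tiny", apoptosis_enabled=False, duration=900.0)
    cfg.growth_period = 1e12
    cfg.oocyte_growth_rate = 0.0
    system = System(cfg)
    system.thr[:] = 100.0               # no seeded cell is past threshold
    system.fert_count = cfg.fertilization_cap
    n0 = system.n_cells
    system.run()
    assert system.n_cells == n0
    ev = system.events_dataframe()
    assert set(ev.kind) == {"birth"}       # only the seeding records


def test_bookkeeping_conservation_every_frame(tiny_run):
    """births - deaths - fertilizations equals the change in living cells
    over the whole run (per-frame enforcement is built into the stepper)."""
    ev = tiny_run.events_dataframe()
    seeds = (ev.kind == "birth") & ev.parent.isna()
    births = ((ev.kind == "birth") & ~ev.parent.isna()).sum()
    divisions = (ev.kind == "division").sum()
    deaths = (ev.kind == "apoptosis").sum()
    ferts = (ev.kind == "fertilization").sum()
    assert tiny_run.n_cells == (seeds.sum() + births - divisions
                                - deaths - ferts)


def test_cells_view_round_trip(tiny_run):
    cells = tiny_run.cells()
    assert len(cells) == tiny_run.n_cells
    c = cells[0]
    assert c.radius == pytest.approx(float(tiny_run.radius[0]))
    assert c.qn_state == tuple(int(x) for x in tiny_run.states[0])
    assert np.isclose(np.linalg.norm(c.orientation), 1.0)


def test_fate_progression_is_ordered(tiny_run):
    """Per cell, decoded fates advance along
    mitosis -> pachytene -> diplotene -> diakinesis -> maturation:
    no stage is skipped except that diplotene may be hidden by the priority
    decode when a cell jitters across the growth-factor boundary and latches
    diakinesis within one frame interval (the transient boundary-diakinesis
    property of the spatial-ligand variant); and once a cell is committed
    (diplotene or later), its decoded fate never regresses."""
    order = {"mitosis": 0, "pachytene": 1, "diplotene": 2,
             "diakinesis": 3, "maturation": 4}
    traj = tiny_run.trajectory_dataframe()
    traj = traj[traj.fate != "undefined"]
    checked = 0
    for cell, frame in traj.groupby("cell"):
        codes = frame.sort_values("t").fate.map(order).to_numpy()
        runmax = np.maximum.accumulate(codes)
        stages = np.unique(runmax)
        for a, b in zip(stages, stages[1:]):
            assert (b - a == 1) or (a, b) == (1, 3), \
                f"cell {cell} skipped a fate stage: {stages}"
        committed = codes[runmax >= 2]
        assert np.all(np.diff(committed) >= 0), \
            f"cell {cell} regressed after commitment"
        checked += 1
    assert checked > 50


def test_containment_throughout_run(tiny_run):
    """No cell centre ever leaves the tube lumen."""
    traj = tiny_run.trajectory_dataframe()
    pos = traj[["x", "y", "z"]].to_numpy()
    d = tiny_run.geometry.radial_distance(pos)
    assert float(d.max()) <= tiny_run.geometry.radius


def test_doubling_mitosis_rate_does_not_rupture_containment():
    """Robustness to division rate: halving the growth period (double
    mitosis rate) still keeps every cell inside the tube."""
    cfg = preset("tiny", seed=5, duration=4 * 3600.0)
    cfg.growth_period = cfg.growth_period / 2.0
    system = System(cfg)
    system.run()
    traj = system.trajectory_dataframe()
    d = system.geometry.radial_distance(traj[["x", "y", "z"]].to_numpy())
    assert float(d.max()) <= system.geometry.radius


def test_loss_of_apoptosis_packs_small_oocytes_proximally():
    """Aged-animal comparison (sperm exhausted, so fertilisation has
    ceased): without apoptosis, continued mitotic flux forces extra, smaller
    cells through the bend, so at matched late times the death-defective
    gonad shows a smaller median past-the-bend cell radius than wild type
    and more than one cell per axial slice (the multiple-rows morphology).
    Only the ordering is asserted, not absolute sizes."""
    stats = {}
    for scenario in ("tiny", "tiny_ced"):
        cfg = preset(scenario, seed=9, duration=10 * 3600.0,
                     fertilization_cap=0)
        system = System(cfg)
        system.run()
        ax = system.geometry.axial(system.pos)
        past_bend = ax > system.geometry.bend_start
        assert past_bend.sum() > 3
        radii = system.radius[past_bend]
        slices = np.floor(ax[past_bend] / 6.0)
        per_slice = pd.Series(slices).value_counts()
        stats[scenario] = dict(mean_r=float(radii.mean()),
                               n=int(past_bend.sum()),
                               max_per_slice=int(per_slice.max()))
    # the extra, smaller cells forced through the bend pull the mean down
    assert stats["tiny_ced"]["mean_r"] < stats["tiny"]["mean_r"]
    assert stats["tiny_ced"]["n"] > stats["tiny"]["n"]
    assert stats["tiny_ced"]["max_per_slice"] > 1


def test_single_founder_lineage_has_single_root():
    system = System(preset("tiny", init="founder", seed=2,
                           duration=3 * 3600.0))
    system.run()
    tree = LineageTree.from_events(system.events_dataframe(),
                                   run_end=system.clock)
    assert len(tree.roots) == 1
    for cid, node in tree.nodes.items():
        if node.parent is not None:
            assert node.generation == tree.nodes[node.parent].generation + 1
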