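"""Contact forces, the BD integrator, orientation diffusion."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from germsim.geometry import build_gonad_geometry
from germsim.physics import (BOLTZMANN, Cell, NeighborList, PhysicsParams,
                             bd_position_step, cell_mass, orientation_step,
                             overlap_force, pair_contact_forces, wall_force)


def make_cell(pos, r=1.0, orient=(1, 0, 0)):
    return Cell(position=np.array(pos, dtype=float), radius=r,
                orientation=np.array(orient, dtype=float), qn_state=(),
                lineage_id=0)


# -- cell_mass --------------------------------------------------------------

def test_cell_mass_values():
    assert cell_mass(0.0) == 0.0
    assert cell_mass(1.0, 1.3) == pytest.approx(5.4454, abs=1e-4)
    assert cell_mass(2.0, 1.3) == pytest.approx(8 * cell_mass(1.0, 1.3))
    with pytest.raises(ValueError):
        cell_mass(-1.0)


# -- overlap force ----------------------------------------------------------

def test_no_force_without_overlap():
    a, b = make_cell([0, 0, 0]), make_cell([2.5, 0, 0])
    assert np.allclose(overlap_force(a, b), 0.0)


def test_force_magnitude_is_k_delta():
    """delta = 0.5 um at k = 36 pN/um gives 18 pN, directed b -> a."""
    a, b = make_cell([0, 0, 0]), make_cell([1.5, 0, 0])
    f = overlap_force(a, b, k=36.0)
    assert np.allclose(f, [-18.0, 0.0, 0.0])


def test_newtons_third_law_on_random_pairs(rng):
    for _ in range(1000):
        pa, pb = rng.uniform(-2, 2, 3), rng.uniform(-2, 2, 3)
        ra, rb = rng.uniform(0.5, 2), rng.uniform(0.5, 2)
        a, b = make_cell(pa, ra), make_cell(pb, rb)
        assert np.allclose(overlap_force(a, b), -overlap_force(b, a))


def test_coincident_centers_deterministic_fallback():
    a = make_cell([0, 0, 0], r=1, orient=(0, 0, 1))
    b = make_cell([0, 0, 0], r=1)
    f = overlap_force(a, b, k=36.0)
    assert np.allclose(f, [0, 0, 72.0])     # along a's orientation, k*2r


def test_pair_forces_match_all_pairs_oracle(rng):
    """Vectorised candidate-pair forces equal the brute-force double loop
    exactly, including per-cell pressure magnitudes."""
    n = 40
    pos = rng.uniform(0, 10, (n, 3))
    rad = rng.uniform(0.5, 1.5, n)
    pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    f, mags = pair_contact_forces(pos, rad, pairs, k=36.0)
    f_ref = np.zeros((n, 3))
    m_ref = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            fij = overlap_force(make_cell(pos[i], rad[i]),
                                make_cell(pos[j], rad[j]), k=36.0)
            f_ref[i] += fij
            m_ref[i] += np.linalg.norm(fij)
    assert np.allclose(f, f_ref, atol=1e-9)
    assert np.allclose(mags, m_ref, atol=1e-9)


def test_neighbor_list_forces_are_exact(rng):
    """Forces from the Verlet/KD-tree candidate list equal the all-pairs
    oracle (the list is a superset of contacts, never an approximation)."""
    geom = build_gonad_geometry(distal_length=20, radius=6, rachis_radius=2,
                                bend_radius=6, proximal_length=10,
                                wall_radius=1.0, wall_spacing=1.0)
    n = 30
    pos = np.column_stack([rng.uniform(0, 20, n), rng.uniform(-3, 3, n),
                           rng.uniform(-3, 3, n)])
    rad = rng.uniform(0.8, 1.6, n)
    nl = NeighborList(geom.wall_positions, geom.wall_radius, skin=0.8)
    nl.rebuild(pos, rad)
    f, _ = pair_contact_forces(pos, rad, nl.pairs, k=36.0)
    all_pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    f_ref, _ = pair_contact_forces(pos, rad, all_pairs, k=36.0)
    assert np.allclose(f, f_ref, atol=1e-9)


# -- BD integrator ----------------------------------------------------------

def test_zero_force_zero_temperature_is_static():
    params = PhysicsParams(temperature=0.0)
    pos = np.zeros((5, 3))
    out = bd_position_step(pos, np.zeros((5, 3)), np.ones(5) * 10, params,
                           1.0, np.random.default_rng(0).normal(size=(5, 3)))
    assert np.allclose(out, pos)


def test_deterministic_drift_term():
    """With zero noise, displacement is exactly dt * F * (gamma/m)."""
    params = PhysicsParams(gamma=0.5)
    F = np.array([[2.0, -1.0, 0.5]])
    m = np.array([10.0])
    out = bd_position_step(np.zeros((1, 3)), F, m, params, 2.0,
                           np.zeros((1, 3)))
    assert np.allclose(out, 2.0 * F * (0.5 / 10.0))


def test_invalid_dt_rejected():
    params = PhysicsParams()
    with pytest.raises(ValueError):
        bd_position_step(np.zeros((1, 3)), np.zeros((1, 3)), np.ones(1),
                         params, 0.0, np.zeros((1, 3)))
    with pytest.raises(ValueError):
        bd_position_step(np.zeros((1, 3)), np.zeros((1, 3)), np.ones(1),
                         params, 99.0, np.zeros((1, 3)))


def test_noise_variance_matches_fluctuation_dissipation(rng):
    """Per-axis displacement variance of force-free steps equals
    2*kB*T*dt*(gamma/m) within 3 standard errors at 1e5 samples."""
    params = PhysicsParams(gamma=0.5)
    n = 100_000
    dt = 0.3
    m = np.full(n, 20.0)
    noise = rng.normal(size=(n, 3))
    out = bd_position_step(np.zeros((n, 3)), np.zeros((n, 3)), m, params,
                           dt, noise)
    expected = 2.0 * BOLTZMANN * 298.0 * dt * (0.5 / 20.0)
    for axis in range(3):
        var = out[:, axis].var()
        se = expected * np.sqrt(2.0 / (n - 1))
        assert abs(var - expected) < 3 * se


def test_inverse_gamma_damping_mode():
    params = PhysicsParams(gamma=4.0, damping_mode="inverse_gamma")
    assert np.allclose(params.beta(np.array([7.0, 70.0])), 0.25)


# -- orientation diffusion --------------------------------------------------

def test_orientation_frozen_without_rotational_diffusion(rng):
    params = PhysicsParams(d_rot=0.0)
    o = np.array([[0.0, 0.0, 1.0]])
    assert np.allclose(orientation_step(o, params, 1.0, rng), o)


def test_orientation_stays_normalized(rng):
    params = PhysicsParams(d_rot=1e-3)
    o = rng.normal(size=(10_000, 3))
    o /= np.linalg.norm(o, axis=1)[:, None]
    out = orientation_step(o, params, 5.0, rng)
    assert np.allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-12)


def test_orientation_randomizes_toward_uniform(rng):
    """After many diffusion steps an initially aligned population is
    isotropic: the 3D Rayleigh statistic 3*n*|mean|^2 ~ chi2(3) does not
    reject uniformity at p > 0.01 (n = 1e4)."""
    params = PhysicsParams(d_rot=1e-2)
    n = 10_000
    o = np.tile([0.0, 0.0, 1.0], (n, 1))
    for _ in range(200):
        o = orientation_step(o, params, 10.0, rng)
    stat = 3.0 * n * float((o.mean(axis=0) ** 2).sum())
    p = stats.chi2(3).sf(stat)
    assert p > 0.01


def test_zero_orientation_rejected(rng):
    with pytest.raises(ValueError):
        orientation_step(np.zeros((1, 3)), PhysicsParams(), 1.0, rng)


# -- walls ------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_geom():
    return build_gonad_geometry(distal_length=20, radius=6, rachis_radius=2,
                                bend_radius=6, proximal_length=10,
                                wall_radius=0.8, wall_spacing=0.8)


def test_wall_force_zero_in_mid_lumen(small_geom):
    cell = make_cell([10.0, 0.0, 4.0], r=1.0)
    assert np.allclose(wall_force(cell, small_geom), 0.0)


def test_wall_force_pushes_inward(small_geom):
    """A cell overlapping the outer wall feels a net inward radial force
    equal to the brute pairwise sum."""
    cell = make_cell([10.0, 0.0, 5.7], r=1.0)
    f = wall_force(cell, small_geom, k=36.0)
    # direct pairwise oracle
    d = cell.position[None, :] - small_geom.wall_positions
    dist = np.linalg.norm(d, axis=1)
    delta = cell.radius + small_geom.wall_radius - dist
    hit = delta > 0
    f_ref = ((36.0 * delta[hit] / dist[hit])[:, None] * d[hit]).sum(axis=0)
    assert hit.sum() > 0
    assert np.allclose(f, f_ref)
    assert f[2] < 0.0     # inward (toward the axis)


def test_outward_forced_cell_stays_contained(small_geom):
    """A cell pushed radially outward in the distal arm cannot cross the
    wall over 10^4 BD steps."""
    params = PhysicsParams()
    rng = np.random.default_rng(3)
    pos = np.array([[10.0, 0.0, 4.0]])
    rad = np.array([1.0])
    mass = np.array([cell_mass(1.0)])
    push = np.array([[0.0, 0.0, 5.0]])    # constant outward force, pN
    cell = make_cell(pos[0], 1.0)
    for _ in range(10_000):
        cell.position = pos[0]
        f = push[0] + wall_force(cell, small_geom)
        pos = bd_position_step(pos, f[None, :], mass, params, 0.5,
                               rng.normal(size=(1, 3)))
        assert small_geom.radial_distance(pos)[0] < small_geom.radius
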