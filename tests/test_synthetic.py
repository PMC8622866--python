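"""System construction, Brownian aggregation dynamics, and fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zincagg import (
    SimParams,
    build_system,
    connectivity_length,
    composition_timeseries,
    make_coordination_fixture,
    make_partition,
    simulate,
    uniform_bind_prob,
)
from zincagg.core import PlacementError, FixtureError
from zincagg.pbc import min_image_dist
from zincagg.presets import SYSTEM_PRESETS
from zincagg.synth import DEFAULT_DIFFUSION


def unit_centers(topo, frame):
    unit_ids = topo.atom_unit_ids()
    return np.array([frame.coords[unit_ids == u].mean(axis=0)
                     for u in range(topo.n_units)])


def test_system2_preset_respects_minimum_separation():
    """19 dimers in the 15 nm box keep pairwise minimum-image centre
    distances >= 2.4 nm at construction."""
    params = SYSTEM_PRESETS["system2"].sim_params(seed=4)
    assert (params.n_dimer, params.min_separation, params.box_edge) == (19, 2.4, 15.0)
    topo, frame, _ = build_system(params)
    assert topo.n_units == 19
    c = unit_centers(topo, frame)
    for i in range(len(c)):
        d = min_image_dist(c[i + 1:], c[i], params.box_edge)
        assert np.all(d >= params.min_separation - 1e-9)


def test_all_presets_match_study_table():
    expect = {
        "system1": (1, 0, 19, 0, 3.1, 100),
        "system2": (19, 0, 0, 0, 2.4, 200),
        "system3": (0, 20, 0, 0, 2.7, 100),
        "system4": (9, 0, 0, 0, 4.1, 100),
        "system5": (19, 0, 0, 20, 2.4, 100),
        "system6": (1, 19, 0, 20, 3.1, 150),
    }
    for name, row in expect.items():
        p = SYSTEM_PRESETS[name]
        assert (p.n_dimer, p.n_monomer_free, p.n_monomer_zn, p.n_zinc_free,
                p.min_separation, p.duration_ns) == row
        assert p.box_edge == 15.0


def test_empty_system_rejected():
    with pytest.raises(ValueError, match="empty"):
        build_system(SimParams())


def test_same_seed_same_coordinates():
    params = SimParams(n_dimer=5, n_monomer_free=3, seed=42)
    _, f1, _ = build_system(params)
    _, f2, _ = build_system(params)
    assert np.array_equal(f1.coords, f2.coords)


def test_infeasible_packing_reports_attempts():
    params = SimParams(n_monomer_free=40, min_separation=7.4,
                       max_placement_attempts=2000, seed=0)
    with pytest.raises(PlacementError, match="attempts"):
        build_system(params)


# ---------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------

def test_simulation_is_deterministic():
    params = SimParams(n_dimer=6, min_separation=2.4, seed=9, n_steps=100)
    topo, frame, layout = build_system(params)
    t1 = simulate(topo, frame, params, layout)
    t2 = simulate(topo, frame, params, layout)
    for a, b in zip(t1.frames, t2.frames):
        assert np.array_equal(a.coords, b.coords)


def test_no_binding_ends_all_singletons():
    """bind_prob = 0 with frozen diffusion: composition stays N singletons
    and L_c equals N."""
    params = SimParams(
        n_monomer_free=12, min_separation=2.4, seed=1, n_steps=60,
        bind_prob=uniform_bind_prob(0.0),
        diffusion_coeff={k: 1e-12 for k in DEFAULT_DIFFUSION})
    topo, frame, layout = build_system(params)
    traj = simulate(topo, frame, params, layout)
    final = composition_timeseries(traj, cutoff=0.45)[-1]
    assert final.sizes == tuple([1] * 12)
    assert connectivity_length(final) == 12


def test_certain_binding_dense_box_collapses_to_one_cluster():
    """bind_prob = 1 in a dense box for a long run: one cluster of all
    units, L_c = sqrt(N)."""
    params = SimParams(n_dimer=12, min_separation=1.9, box_edge=8.0,
                       seed=3, n_steps=1500, emit_stride=250,
                       bind_prob=uniform_bind_prob(1.0))
    topo, frame, layout = build_system(params)
    traj = simulate(topo, frame, params, layout)
    final = composition_timeseries(traj, cutoff=0.45)[-1]
    assert final.sizes == (12,)
    assert connectivity_length(final) == pytest.approx(np.sqrt(12))


def test_mass_conservation_over_time():
    params = SimParams(n_dimer=8, n_monomer_free=4, min_separation=2.0,
                       seed=6, n_steps=300, emit_stride=30)
    topo, frame, layout = build_system(params)
    traj = simulate(topo, frame, params, layout)
    series = composition_timeseries(traj, cutoff=0.45)
    assert {c.n_units for c in series} == {12}


def test_step_variance_matches_diffusion_coefficient():
    """For non-binding units the per-axis step variance is 2*D*dt
    (checked within 5% over >= 1e5 samples)."""
    D = 1.5e-4
    dt = 100.0
    params = SimParams(
        n_monomer_free=10, min_separation=2.4, seed=12,
        n_steps=10_000, emit_stride=1, dt=dt,
        bind_prob=uniform_bind_prob(0.0),
        diffusion_coeff={k: D for k in DEFAULT_DIFFUSION})
    topo, frame, layout = build_system(params)
    traj = simulate(topo, frame, params, layout)
    centers = np.array([unit_centers(topo, f) for f in traj.frames])
    steps = centers[1:] - centers[:-1]
    steps -= params.box_edge * np.round(steps / params.box_edge)
    var = steps.reshape(-1, 3).var(axis=0)
    expected = 2 * D * dt
    assert np.all(np.abs(var - expected) / expected < 0.05)


# ---------------------------------------------------------------------
# coordination fixtures
# ---------------------------------------------------------------------

def test_dimer_bridge_fixture_manifest():
    topo, frame, manifest = make_coordination_fixture("dimer_bridge", 0.21)
    assert sorted((c, r, rn, an) for c, r, rn, an, _ in manifest) == [
        ("A", 11, "GLU", "OE1"), ("A", 14, "HIS", "NE2"),
        ("B", 11, "GLU", "OE1"), ("B", 14, "HIS", "NE2")]
    # donors sit at the requested distance from the zinc atom
    zn = frame.coords[-1]
    donor_ids = [a.atom_id for a in topo.atoms
                 if a.atom_name in ("OE1", "NE2")]
    d = np.linalg.norm(frame.coords[donor_ids] - zn, axis=1)
    np.testing.assert_allclose(d, 0.21, atol=1e-9)


def test_monomer_closed_fixture_manifest():
    _, _, manifest = make_coordination_fixture("monomer_closed", 0.22)
    assert sorted((r, rn) for _, r, rn, _, _ in manifest) == [
        (6, "HIS"), (11, "GLU"), (13, "HIS"), (14, "HIS")]


def test_custom_fixture_with_no_donors_keeps_zinc_bare():
    topo, frame, manifest = make_coordination_fixture("custom", donors=[],
                                                      distances=0.2)
    assert manifest == []
    zn = frame.coords[-1]
    others = frame.coords[:-1]
    assert np.linalg.norm(others - zn, axis=1).min() > 0.6  # 2x cutoff


def test_fixture_rejects_impossible_geometry():
    with pytest.raises(FixtureError):
        make_coordination_fixture("dimer_bridge", distances=2.0)
    with pytest.raises(FixtureError):
        make_coordination_fixture("dimer_bridge", distances=-0.1)


# ---------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------

def test_partition_extremes():
    assert make_partition(5, 5).sizes == (1, 1, 1, 1, 1)
    assert make_partition(7, 1).sizes == (7,)


def test_partition_rejects_too_many_parts():
    with pytest.raises(ValueError):
        make_partition(3, 4)


@settings(derandomize=True, max_examples=300)
@given(st.integers(1, 500), st.data())
def test_partition_sums_to_total(total, data):
    n_parts = data.draw(st.integers(1, total))
    seed = data.draw(st.integers(0, 2**31 - 1))
    p = make_partition(total, n_parts, seed)
    assert p.total == total
    assert len(p.sizes) == n_parts
    assert all(s >= 1 for s in p.sizes)
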