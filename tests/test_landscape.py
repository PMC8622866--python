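"""Superposition, dihedrals, clustering and free-energy surfaces."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helpers import (
    backbone_topology,
    build_backbone,
    exhaustive_peeling_max_cluster,
    rotation_search_rmsd,
    torsion_plane_normal,
)
from zincagg import (
    find_minima,
    free_energy_landscape,
    kabsch_rmsd,
    minimum_members,
    nn_cluster,
    pairwise_rmsd_matrix,
    phi_psi,
    radius_of_gyration,
    representative_frames,
)
from zincagg.core import DegenerateGeometryError, Frame
from zincagg.landscape import circular_mean_deg, dihedral, intersect_minima_members


# ---------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------

def test_identical_sets_have_zero_rmsd():
    X = np.random.default_rng(0).normal(size=(8, 3))
    assert kabsch_rmsd(X, X) == pytest.approx(0.0, abs=1e-12)


def test_rigid_copy_has_zero_rmsd():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(12, 3))
    R = Rotation.random(random_state=2).as_matrix()
    Y = X @ R.T + np.array([3.0, -1.0, 7.0])
    assert kabsch_rmsd(X, Y) < 1e-10


def test_reflection_is_not_allowed():
    """A mirrored cloud keeps a positive RMSD: chirality is preserved."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(10, 3))
    Y = X * np.array([-1.0, 1.0, 1.0])
    assert kabsch_rmsd(X, Y) > 0.1


def test_degenerate_inputs_rejected():
    with pytest.raises(DegenerateGeometryError):
        kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
    with pytest.raises(DegenerateGeometryError):
        kabsch_rmsd(line, line)


@pytest.mark.parametrize("seed", range(15))
def test_kabsch_matches_rotation_search(seed):
    """SVD superposition equals brute-force minimisation over sampled
    rotations within 1e-3."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(10, 3))
    Y = rng.normal(size=(10, 3))
    assert kabsch_rmsd(X, Y) == pytest.approx(
        rotation_search_rmsd(X, Y, seed=seed), abs=1e-3)


@pytest.mark.parametrize("seed", range(10))
def test_kabsch_is_pseudometric(seed):
    rng = np.random.default_rng(100 + seed)
    A, B, C = rng.normal(size=(3, 9, 3))
    ab, ba = kabsch_rmsd(A, B), kabsch_rmsd(B, A)
    assert ab == pytest.approx(ba, abs=1e-9)
    assert kabsch_rmsd(A, C) <= ab + kabsch_rmsd(B, C) + 1e-9


# ---------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------

def test_two_points_rg_is_half_distance():
    assert radius_of_gyration([[0, 0, 0], [0, 0, 2.0]]) == pytest.approx(1.0)


def test_coincident_points_rg_zero():
    assert radius_of_gyration(np.ones((5, 3))) == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_rg_matches_direct_formula(seed):
    rng = np.random.default_rng(seed)
    c = rng.normal(size=(30, 3))
    m = rng.uniform(1, 15, size=30)
    com = (m[:, None] * c).sum(0) / m.sum()
    direct = np.sqrt((m * ((c - com) ** 2).sum(1)).sum() / m.sum())
    assert radius_of_gyration(c, m) == pytest.approx(direct, abs=1e-12)


def test_empty_selection_rejected():
    with pytest.raises(ValueError):
        radius_of_gyration(np.empty((0, 3)))


# ---------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------

def test_backbone_built_from_target_angles_is_recovered():
    """A chain constructed to realise given phi/psi values reproduces
    them within 1e-6 degrees."""
    phis = [-60.0, -120.0, 75.0]
    psis = [145.0, -45.0, 160.0]
    coords = build_backbone(phis, psis)
    topo = backbone_topology(4)
    frame = Frame(coords=coords, box_edge=100.0)
    result = {r.resseq: r for r in phi_psi(frame, topo)}
    for k, phi in enumerate(phis):
        assert result[k + 2].phi == pytest.approx(phi, abs=1e-6)
    for k, psi in enumerate(psis):
        assert result[k + 1].psi == pytest.approx(psi, abs=1e-6)


def test_two_residue_chain_has_one_phi_and_one_psi():
    coords = build_backbone([-70.0], [120.0])
    topo = backbone_topology(2)
    res = phi_psi(Frame(coords=coords, box_edge=100.0), topo)
    phis = [r.phi for r in res if r.phi is not None]
    psis = [r.psi for r in res if r.psi is not None]
    assert len(phis) == 1 and len(psis) == 1


@pytest.mark.parametrize("seed", range(20))
def test_dihedral_matches_plane_normal_oracle(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(4, 3))
    assert dihedral(*pts) == pytest.approx(
        torsion_plane_normal(*pts), abs=1e-9)


def test_incomplete_backbone_skipped_with_warning():
    coords = build_backbone([-60.0], [140.0])
    topo = backbone_topology(2)
    # drop the CA of residue 2
    keep = [a for a in topo.atoms if not (a.resseq == 2 and a.atom_name == "CA")]
    from zincagg.core import Atom, Topology, Unit
    atoms = [Atom(i, a.chain_id, a.resseq, a.atom_name, a.element)
             for i, a in enumerate(keep)]
    topo2 = Topology([Unit(0, "monomer")], [("A", 0)],
                     [("A", 1, "GLY"), ("A", 2, "GLY")], atoms)
    coords2 = np.array([coords[a.atom_id] for a in keep])
    with pytest.warns(UserWarning, match="incomplete backbone"):
        res = phi_psi(Frame(coords=coords2, box_edge=100.0), topo2)
    assert all(r.resseq != 2 for r in res)


def test_circular_mean_wraps_correctly():
    assert circular_mean_deg([179.0, -179.0]) == pytest.approx(180.0)
    assert circular_mean_deg([-60.0, -80.0]) == pytest.approx(-70.0)


# ---------------------------------------------------------------------
# pairwise RMSD + clustering
# ---------------------------------------------------------------------

def _ensemble(seed, n=6, atoms=8):
    rng = np.random.default_rng(seed)
    return [rng.normal(size=(atoms, 3)) for _ in range(n)]


def test_duplicate_conformations_give_zero_matrix():
    X = np.random.default_rng(0).normal(size=(7, 3))
    m = pairwise_rmsd_matrix([X, X.copy(), X.copy()])
    assert np.abs(m).max() < 1e-10


def test_matrix_symmetric_and_matches_direct_calls():
    ens = _ensemble(5)
    m = pairwise_rmsd_matrix(ens)
    assert np.abs(m - m.T).max() < 1e-12
    assert np.all(np.diag(m) == 0)
    for i in range(len(ens)):
        for j in range(i + 1, len(ens)):
            assert m[i, j] == pytest.approx(kabsch_rmsd(ens[i], ens[j]))


def test_nn_cluster_triangle_and_isolates():
    m = np.array([[0, 1, 1, 9], [1, 0, 1, 9], [1, 1, 0, 9], [9, 9, 9, 0]], float)
    clusters, rest = nn_cluster(m, threshold=2.0)
    assert clusters == [[0, 1, 2]] and rest == [3]
    clusters, rest = nn_cluster(m, threshold=0.5)
    assert clusters == [] and rest == [0, 1, 2, 3]


@pytest.mark.parametrize("seed", range(30))
def test_max_cluster_size_matches_exhaustive_peeling(seed):
    """Greedy peeling reaches the same maximum cluster size as an
    exhaustive search over peeling orders (<= 12 members)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    pts = rng.normal(size=(n, 2))
    m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    thr = float(rng.uniform(0.3, 2.0))
    clusters, _ = nn_cluster(m, thr)
    got = max((len(c) for c in clusters), default=0)
    want = exhaustive_peeling_max_cluster(m, thr)
    assert got == want


@pytest.mark.parametrize("seed", range(10))
def test_nn_cluster_is_a_partition(seed):
    rng = np.random.default_rng(seed)
    n = 15
    pts = rng.normal(size=(n, 2))
    m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    clusters, rest = nn_cluster(m, 1.0)
    everything = [i for c in clusters for i in c] + rest
    assert sorted(everything) == list(range(n))


# ---------------------------------------------------------------------
# free-energy landscapes
# ---------------------------------------------------------------------

def test_uniform_occupancy_is_flat_zero():
    xs, ys = np.meshgrid(np.arange(4) + 0.5, np.arange(4) + 0.5)
    g = free_energy_landscape(xs.ravel(), ys.ravel(), bins=4)
    assert np.all(g.counts == 1)
    assert np.abs(np.asarray(g.free_energy)).max() == 0.0


def test_single_bin_landscape():
    g = free_energy_landscape(np.zeros(50), np.zeros(50), bins=8)
    occ = g.occupied
    assert occ.sum() == 1
    assert float(g.free_energy[occ][0]) == 0.0
    assert np.all(g.free_energy.mask[~occ])
    assert find_minima(g) == [tuple(np.argwhere(occ)[0])]


def test_gaussian_samples_recover_quadratic_surface():
    """1e5 standard-normal samples give F = (x^2+y^2)/2 up to a constant
    within 0.15 kT RMS over well-populated bins, with exactly one
    zero-valued global minimum."""
    rng = np.random.default_rng(2024)
    xy = rng.normal(size=(100_000, 2))
    g = free_energy_landscape(xy[:, 0], xy[:, 1], bins=32)
    fe = np.asarray(g.free_energy)
    assert (fe[g.occupied] == 0.0).sum() == 1
    xc, yc = g.bin_centers()
    XX, YY = np.meshgrid(xc, yc, indexing="ij")
    well = g.counts >= 100
    diff = (fe - (XX ** 2 + YY ** 2) / 2)[well]
    diff -= diff.mean()
    assert np.sqrt((diff ** 2).mean()) < 0.15


def test_two_modes_give_two_minima_and_representatives():
    rng = np.random.default_rng(7)
    a = rng.normal(size=(5000, 2)) * 0.4
    b = rng.normal(size=(5000, 2)) * 0.4 + 4.0
    xs = np.concatenate([a[:, 0], b[:, 0]])
    ys = np.concatenate([a[:, 1], b[:, 1]])
    g = free_energy_landscape(xs, ys, bins=24)
    minima = find_minima(g, depth=1.0, min_count=5)
    assert len(minima) == 2
    reps = representative_frames(g, minima, xs, ys)
    assert len(reps) == 2
    # one representative from each mode
    assert sorted(int(r >= 5000) for r in reps) == [0, 1]


def test_minima_intersection_idempotent():
    rng = np.random.default_rng(9)
    xy = rng.normal(size=(3000, 2))
    g1 = free_energy_landscape(xy[:, 0], xy[:, 1], bins=16)
    g2 = free_energy_landscape(xy[:, 0], xy[:, 1], bins=16)
    m1 = find_minima(g1, min_count=3)
    m2 = find_minima(g2, min_count=3)
    mem1 = [minimum_members(g1, m, xy[:, 0], xy[:, 1]) for m in m1]
    mem2 = [minimum_members(g2, m, xy[:, 0], xy[:, 1]) for m in m2]
    inter = intersect_minima_members(mem1, mem2)
    assert inter == set().union(*mem1)


def test_empty_series_rejected():
    with pytest.raises(ValueError):
        free_energy_landscape([], [], bins=8)
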