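"""Conformational geometry, ensemble clustering and free-energy landscapes.

Free energies are constructed from occupancy over a pair of reaction
coordinates (RMSD vs radius of gyration, or circular-mean phi vs psi):
F/kT = -ln(n_bin / n_max), so the most occupied bin sits at 0 and empty
bins are masked rather than set to zero.  Local minima of such a surface
mark the energetically favourable conformations; representatives are the
frames falling nearest the centre of a minimum bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DegenerateGeometryError, Frame, Topology


# ---------------------------------------------------------------------
# superposition and geometry
# ---------------------------------------------------------------------

def kabsch_rmsd(X: np.ndarray, Y: np.ndarray, weights=None) -> float:
    """RMSD after optimal rigid superposition of Y onto X.

    Least-squares translation plus proper rotation (SVD with determinant
    correction, so reflections are excluded and chirality is preserved).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must both have shape (n, 3)")
    n = X.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points to superpose")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    xc = X - (w[:, None] * X).sum(0)
    yc = Y - (w[:, None] * Y).sum(0)
    if np.linalg.matrix_rank(xc, tol=1e-10) < 2 or \
       np.linalg.matrix_rank(yc, tol=1e-10) < 2:
        raise DegenerateGeometryError("point set is rank-deficient (collinear)")
    H = (w[:, None] * yc).T @ xc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    diff = yc @ R - xc
    return float(np.sqrt((w * np.sum(diff * diff, axis=1)).sum()))


def radius_of_gyration(coords: np.ndarray, masses=None) -> float:
    """Mass-weighted RMS distance from the centre of mass (unit masses
    by default)."""
    c = np.asarray(coords, float)
    if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 1:
        raise ValueError("need at least one (x, y, z) point")
    m = np.ones(c.shape[0]) if masses is None else np.asarray(masses, float)
    com = (m[:, None] * c).sum(0) / m.sum()
    d2 = np.sum((c - com) ** 2, axis=1)
    return float(np.sqrt((m * d2).sum() / m.sum()))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC (-180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    u = b2 - np.dot(b2, b1n) * b1n
    ang = np.degrees(np.arctan2(np.dot(np.cross(b1n, v), u), np.dot(v, u)))
    # arctan2 returns [-180, 180]; map -180 to +180 per IUPAC
    return float(ang if ang != -180.0 else 180.0)


@dataclass(frozen=True)
class ResidueDihedrals:
    chain_id: str
    resseq: int
    phi: float | None  # degrees; None at the N-terminus
    psi: float | None  # degrees; None at the C-terminus


def phi_psi(frame: Frame, topology: Topology) -> list[ResidueDihedrals]:
    """Backbone phi/psi per residue for chains with full N/CA/C backbones.

    Residues missing a backbone atom are skipped with a warning; the
    first residue of a chain has no phi, the last no psi (reported as
    None).  Pseudo-atom scaffolds (no N/CA/C) yield no entries.
    """
    by_chain: dict[str, dict[int, dict[str, int]]] = {}
    for a in topology.atoms:
        if a.atom_name in ("N", "CA", "C"):
            by_chain.setdefault(a.chain_id, {}).setdefault(
                a.resseq, {})[a.atom_name] = a.atom_id
    out: list[ResidueDihedrals] = []
    for chain_id, resmap in by_chain.items():
        seqs = sorted(resmap)
        complete = []
        for s in seqs:
            if set(resmap[s]) == {"N", "CA", "C"}:
                complete.append(s)
            else:
                warnings.warn(
                    f"chain {chain_id} residue {s}: incomplete backbone, skipped")
        for k, s in enumerate(complete):
            phi = psi = None
            N, CA, C = (frame.coords[resmap[s][x]] for x in ("N", "CA", "C"))
            if k > 0 and complete[k - 1] == s - 1:
                Cprev = frame.coords[resmap[s - 1]["C"]]
                phi = dihedral(Cprev, N, CA, C)
            if k < len(complete) - 1 and complete[k + 1] == s + 1:
                Nnext = frame.coords[resmap[s + 1]["N"]]
                psi = dihedral(N, CA, C, Nnext)
            if phi is not None or psi is not None:
                out.append(ResidueDihedrals(chain_id, s, phi, psi))
    return out


def circular_mean_deg(angles) -> float:
    """Circular mean of angles in degrees, in (-180, 180]."""
    a = np.radians(np.asarray(list(angles), float))
    if a.size == 0:
        raise ValueError("no angles to average")
    m = np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean()))
    return float(m if m != -180.0 else 180.0)


# ---------------------------------------------------------------------
# ensemble clustering
# ---------------------------------------------------------------------

def pairwise_rmsd_matrix(ensemble) -> np.ndarray:
    """Symmetric matrix of pairwise superposition RMSDs, zero diagonal."""
    members = [np.asarray(m, float) for m in ensemble]
    n = len(members)
    if n == 0:
        raise ValueError("empty ensemble")
    counts = {m.shape for m in members}
    if len(counts) != 1:
        raise ValueError("all ensemble members must share one atom selection")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_rmsd(members[i], members[j])
    return mat


def nn_cluster(matrix: np.ndarray, threshold: float):
    """Nearest-neighbour clustering by iterative peeling.

    Repeatedly take the member with the most remaining neighbours within
    ``threshold`` (ties broken by lowest index), emit it with those
    neighbours as one cluster, remove them, and stop when nobody has a
    neighbour left.  Remaining members are reported unclustered.

    Returns ``(clusters, unclustered)`` with original indices.
    """
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    n = m.shape[0]
    adj = (m <= threshold) & ~np.eye(n, dtype=bool)
    remaining = set(range(n))
    clusters: list[list[int]] = []
    while True:
        best, best_count = None, 0
        for i in sorted(remaining):
            count = sum(1 for j in remaining if j != i and adj[i, j])
            if count > best_count:
                best, best_count = i, count
        if best is None:
            break
        members = [best] + [j for j in sorted(remaining)
                            if j != best and adj[best, j]]
        clusters.append(members)
        remaining -= set(members)
    return clusters, sorted(remaining)


# ---------------------------------------------------------------------
# free-energy landscapes
# ---------------------------------------------------------------------

@dataclass
class LandscapeGrid:
    """2D free-energy surface over a reaction-coordinate pair.

    ``free_energy`` is in kT units (-ln of occupancy relative to the
    most occupied bin, so its minimum over occupied bins is exactly 0);
    empty bins are masked, never reported as 0.
    """

    x_name: str
    y_name: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    free_energy: np.ma.MaskedArray
    kT: float = 1.0

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def bin_centers(self):
        return (0.5 * (self.x_edges[:-1] + self.x_edges[1:]),
                0.5 * (self.y_edges[:-1] + self.y_edges[1:]))


def free_energy_landscape(
    xs, ys, bins: int = 32, kT: float = 1.0,
    x_name: str = "x", y_name: str = "y", padding: float = 0.05,
) -> LandscapeGrid:
    """Histogram two coordinate series into a free-energy surface.

    Ranges span the observed data with 5% padding per side by default.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if xs.size == 0 or xs.shape != ys.shape:
        raise ValueError("xs and ys must be equal-length, non-empty series")

    def padded(a):
        lo, hi = float(a.min()), float(a.max())
        span = hi - lo
        pad = padding * span if span > 0 else max(abs(hi), 1.0) * padding
        return lo - pad, hi + pad

    counts, x_edges, y_edges = np.histogram2d(
        xs, ys, bins=bins, range=[padded(xs), padded(ys)])
    occupied = counts > 0
    fe = np.ma.masked_array(np.zeros_like(counts), mask=~occupied)
    fe[occupied] = -np.log(counts[occupied] / counts.max())
    return LandscapeGrid(
        x_name=x_name, y_name=y_name, x_edges=x_edges, y_edges=y_edges,
        counts=counts, free_energy=fe, kT=kT)


def _neighbors(i, j, shape):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            a, b = i + di, j + dj
            if 0 <= a < shape[0] and 0 <= b < shape[1]:
                yield a, b


def find_minima(
    grid: LandscapeGrid, depth: float = 0.0, min_count: int = 1,
) -> list[tuple[int, int]]:
    """Local minima of the surface, optionally filtered by basin depth.

    A local minimum is an occupied bin whose free energy is <= that of
    all occupied 8-neighbours.  With ``depth`` > 0, a watershed merge
    estimates each minimum's saddle (the level at which its basin joins
    a deeper one); minima shallower than ``depth`` below their saddle
    are discarded.  The deepest minimum of each connected occupied
    region always survives.  ``min_count`` raises the occupancy floor
    (bins with fewer samples are treated as empty), which suppresses
    spurious single-sample minima in sparsely sampled tails.
    """
    occ = grid.counts >= max(min_count, 1)
    fe = grid.free_energy
    minima = []
    for i, j in zip(*np.nonzero(occ)):
        if all(fe[a, b] >= fe[i, j]
               for a, b in _neighbors(i, j, occ.shape) if occ[a, b]):
            minima.append((int(i), int(j)))
    if depth <= 0 or len(minima) <= 1:
        return sorted(minima)

    # watershed: flood occupied bins in order of increasing free energy;
    # when the basins of two minima meet, the shallower minimum's saddle
    # is the level of the meeting bin (a prominence estimate).
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    # per basin root: (free energy of its minimum, the minimum bin)
    basin: dict[tuple[int, int], tuple[float, tuple[int, int]]] = {}
    saddle: dict[tuple[int, int], float] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = sorted(
        ((int(i), int(j)) for i, j in zip(*np.nonzero(occ))),
        key=lambda ij: (float(fe[ij]), ij))
    for ij in order:
        parent[ij] = ij
        basin[ij] = (float(fe[ij]), ij)
        for nb in _neighbors(*ij, occ.shape):
            if nb not in parent or not occ[nb]:
                continue
            ra, rb = find(ij), find(nb)
            if ra == rb:
                continue
            deep, shallow = (ra, rb) if basin[ra] <= basin[rb] else (rb, ra)
            shallow_min_bin = basin[shallow][1]
            saddle.setdefault(shallow_min_bin, float(fe[ij]))
            parent[shallow] = deep
    global_min = min(minima, key=lambda ij: (float(fe[ij]), ij))
    kept = []
    for mn in minima:
        if mn == global_min:
            kept.append(mn)
            continue
        s = saddle.get(mn)
        if s is None or (s - float(fe[mn])) >= depth:
            kept.append(mn)
    return sorted(kept)


def _bin_index(value, edges):
    idx = int(np.searchsorted(edges, value, side="right") - 1)
    return min(max(idx, 0), len(edges) - 2)


def minimum_members(grid: LandscapeGrid, minimum, xs, ys) -> set[int]:
    """Frame indices whose (x, y) fall inside one minimum bin."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    i, j = minimum
    out = set()
    for k in range(xs.size):
        if (_bin_index(xs[k], grid.x_edges) == i
                and _bin_index(ys[k], grid.y_edges) == j):
            out.add(k)
    return out


def representative_frames(grid: LandscapeGrid, minima, xs, ys) -> list[int]:
    """For each minimum, the member frame nearest the bin centre."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    xc, yc = grid.bin_centers()
    reps = []
    for (i, j) in minima:
        members = minimum_members(grid, (i, j), xs, ys)
        if not members:
            continue
        cx, cy = xc[i], yc[j]
        reps.append(min(
            members,
            key=lambda k: ((xs[k] - cx) ** 2 + (ys[k] - cy) ** 2, k)))
    return reps


def intersect_minima_members(members_a, members_b) -> set[int]:
    """Frames that belong to minima of both landscapes (set intersection)."""
    union_a = set().union(*members_a) if members_a else set()
    union_b = set().union(*members_b) if members_b else set()
    return union_a & union_b
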