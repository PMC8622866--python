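"""Shared builders and independent oracles for the test suite.

Everything here is deliberately written by a different route than the
implementation it checks (brute-force scans, enumeration, closed forms),
so agreement is evidence rather than tautology.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from zincagg.core import Atom, Frame, MONOMER, Topology, Unit
from zincagg.core import chain_id_alphabet


# ---------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------

def point_system(positions, box_edge: float) -> tuple[Topology, Frame]:
    """n monomer units of one CA pseudo-atom each, at given positions."""
    positions = np.asarray(positions, float)
    n = positions.shape[0]
    alphabet = chain_id_alphabet()
    units = [Unit(i, MONOMER) for i in range(n)]
    chains = [(alphabet[i], i) for i in range(n)]
    residues = [(alphabet[i], 1, "ASP") for i in range(n)]
    atoms = [Atom(i, alphabet[i], 1, "CA", "C") for i in range(n)]
    topo = Topology(units, chains, residues, atoms)
    return topo, Frame(coords=positions, box_edge=box_edge, time=0.0)


def backbone_topology(n_res: int) -> Topology:
    """One chain of GLY residues with N/CA/C backbone atoms."""
    units = [Unit(0, MONOMER)]
    chains = [("A", 0)]
    residues = [("A", r, "GLY") for r in range(1, n_res + 1)]
    atoms = []
    for r in range(1, n_res + 1):
        for name, el in (("N", "N"), ("CA", "C"), ("C", "C")):
            atoms.append(Atom(len(atoms), "A", r, name, el))
    return Topology(units, chains, residues, atoms)


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement: point d with |cd|=bond, angle(b,c,d)=angle and
    dihedral(a,b,c,d)=torsion."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phis, psis, omega: float = 180.0) -> np.ndarray:
    """Backbone N/CA/C coordinates (nm) realising given phi/psi lists.

    ``phis[k]`` is the phi of residue k+2 (first residue has none);
    ``psis[k]`` the psi of residue k+1 (last residue has none).
    Ideal geometry: N-CA 0.1458, CA-C 0.1525, C-N 0.1329 nm.
    """
    n_res = len(psis) + 1
    assert len(phis) == n_res - 1
    coords = [np.array([0.0, 0.0, 0.0]),            # N1
              np.array([0.1458, 0.0, 0.0])]         # CA1
    coords.append(place_atom([0.0, 0.1, 0.0], coords[0], coords[1],
                             0.1525, 111.0, 60.0))  # C1 (arbitrary start)
    for r in range(1, n_res):
        N_prev, CA_prev, C_prev = coords[-3], coords[-2], coords[-1]
        N = place_atom(N_prev, CA_prev, C_prev, 0.1329, 116.2, psis[r - 1])
        CA = place_atom(CA_prev, C_prev, N, 0.1458, 121.7, omega)
        C = place_atom(C_prev, N, CA, 0.1525, 111.0, phis[r - 1])
        coords += [N, CA, C]
    return np.array(coords)


# ---------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------

def brute_force_contact_pairs(frame, topology, cutoff: float) -> set[frozenset]:
    """All-pairs minimum-image atom scan for unit contacts (no trees)."""
    box = frame.box_edge
    unit_ids = topology.atom_unit_ids()
    peptide = set(topology.peptide_unit_ids())
    keep = np.array([u in peptide for u in unit_ids])
    coords = frame.coords[keep]
    uids = unit_ids[keep]
    delta = coords[:, None, :] - coords[None, :, :]
    delta -= box * np.round(delta / box)
    dist = np.sqrt((delta ** 2).sum(-1))
    ii, jj = np.nonzero(dist <= cutoff)
    return {
        frozenset((int(uids[i]), int(uids[j])))
        for i, j in zip(ii, jj)
        if uids[i] != uids[j]
    }


def union_find_component_sizes(n_nodes: int, edges) -> list[int]:
    """Component size multiset by plain union-find."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    sizes: dict[int, int] = {}
    for x in range(n_nodes):
        r = find(x)
        sizes[r] = sizes.get(r, 0) + 1
    return sorted(sizes.values())


def rotation_search_rmsd(X, Y, n_samples: int = 2000, seed: int = 0) -> float:
    """Minimum RMSD over rotations by sampling plus local refinement.

    Independent of the SVD route: centres both sets, evaluates the plain
    RMSD under many sampled rotations, then polishes the best with a
    general-purpose optimiser over rotation vectors.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = Yc @ R.T - Xc
        return np.sqrt((d ** 2).sum() / len(Xc))

    samples = Rotation.random(n_samples, random_state=seed)
    vals = [rmsd_of(r.as_rotvec()) for r in samples]
    best = samples[int(np.argmin(vals))].as_rotvec()
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return float(res.fun)


def torsion_plane_normal(p0, p1, p2, p3) -> float:
    """Torsion via the angle between the two bond planes' normals, sign
    from the scalar triple product (distinct from the arctan2 route)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return float(ang if ang != -180.0 else 180.0)


def brute_force_donor_contacts(frame, topology, cutoff: float, zinc_atom: int):
    """Direct scan over every atom, re-deriving donor status in place."""
    donor_names = {"HIS": {"ND1", "NE2"}, "ASP": {"OD1", "OD2"},
                   "GLU": {"OE1", "OE2"}}
    resname = {(c, s): r for c, s, r in topology.residues}
    zn = frame.coords[zinc_atom]
    box = frame.box_edge
    found = set()
    for a in topology.atoms:
        if a.atom_id == zinc_atom:
            continue
        rn = resname[(a.chain_id, a.resseq)]
        is_donor = (a.atom_name in donor_names.get(rn, set())
                    or (a.atom_name == "N" and a.resseq == 1))
        if not is_donor:
            continue
        d = frame.coords[a.atom_id] - zn
        d -= box * np.round(d / box)
        if np.sqrt((d ** 2).sum()) <= cutoff:
            found.add((a.chain_id, a.resseq, a.atom_name))
    return found


def exhaustive_peeling_max_cluster(matrix, threshold: float) -> int:
    """Largest cluster size over every admissible peeling order.

    At each step any member with at least one remaining neighbour may be
    chosen as a centre; the cluster is that member plus its remaining
    neighbours.  Memoised over the frozenset of remaining members.
    """
    m = np.asarray(matrix, float)
    n = m.shape[0]
    adj = [frozenset(j for j in range(n) if j != i and m[i, j] <= threshold)
           for i in range(n)]

    @lru_cache(maxsize=None)
    def best(remaining: frozenset) -> int:
        out = 0
        for i in remaining:
            nbrs = adj[i] & remaining
            if not nbrs:
                continue
            cluster = nbrs | {i}
            out = max(out, len(cluster), best(remaining - cluster))
        return out

    return best(frozenset(range(n)))
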