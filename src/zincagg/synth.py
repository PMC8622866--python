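"""Synthetic systems and a coarse-grained Brownian aggregation simulator.

The simulator is a deliberately minimal surrogate for the atomistic MD
it emulates: each molecule unit (an Aβ16 monomer, a zinc-bridged dimer
counted as one unit, or a free zinc ion) is a rigid scaffold of
pseudo-atoms diffusing by overdamped Brownian motion in a 15 nm cubic
periodic box.  When two units of different clusters come within the
contact radius, they bind irreversibly with a species-pair probability;
bound clusters then move rigidly with diffusion scaled by size^(-1/3)
(Stokes-like).  Irreversible binding reflects the observation that
zinc-mediated bridges, once formed, were never broken on the simulated
timescale; the species-dependent stickiness encodes the aggregation
propensity ordering dimer > zinc-free monomer > zinc-saturated monomer.

Units carry one pseudo-atom per residue (Asp1..Lys16 per chain) so that
I/O, contact detection and coordination code paths all see realistic
topologies without atomistic detail.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AB16_SEQUENCE,
    Atom,
    DIMER,
    FixtureError,
    Frame,
    MONOMER,
    PlacementError,
    Topology,
    Trajectory,
    Unit,
    ZINC_ION,
    chain_id_alphabet,
)
from .pbc import min_image_dist, min_image_vec, wrap

#: distinguishes zinc-saturated monomers from zinc-free ones for binding
MONOMER_ZN = "monomer_zn"

#: translational diffusion coefficients, nm^2/ps (dilute aqueous values:
#: small peptide ~1.5e-4, the bulkier dimer slower, the bare ion faster)
DEFAULT_DIFFUSION = {
    MONOMER: 1.5e-4,
    MONOMER_ZN: 1.5e-4,
    DIMER: 1.0e-4,
    ZINC_ION: 7.0e-4,
}

#: per-contact, per-step binding probabilities by species pair.  The
#: ordering dimer > zinc-free monomer > zinc-saturated monomer is the
#: modelled aggregation-propensity ordering; free zinc never binds.
#: Values are deliberately small so that binding is reaction-controlled:
#: a pair dwells ~(contact_radius / step length)^2 ~ 30-40 steps inside
#: the contact zone per encounter, and only p * dwell << 1 keeps the
#: species stickiness (rather than the diffusion limit) in charge of
#: the aggregation rate.
DEFAULT_BIND_PROB = {
    frozenset({DIMER}): 0.05,
    frozenset({DIMER, MONOMER}): 0.03,
    frozenset({DIMER, MONOMER_ZN}): 0.01,
    frozenset({MONOMER}): 0.012,
    frozenset({MONOMER, MONOMER_ZN}): 0.006,
    frozenset({MONOMER_ZN}): 0.003,
}


def uniform_bind_prob(p: float) -> dict:
    """Same binding probability for every peptide species pair."""
    species = (MONOMER, MONOMER_ZN, DIMER)
    return {frozenset({a, b}): p
            for a, b in itertools.combinations_with_replacement(species, 2)}


@dataclass
class SimParams:
    """Conditions for system construction and Brownian aggregation.

    Counts, the 15 nm box and the minimum initial separations mirror the
    study conditions; kinetic parameters (contact radius, stickiness,
    diffusion, time step) are the coarse model's own.
    """

    n_dimer: int = 0
    n_monomer_free: int = 0
    n_monomer_zn: int = 0
    n_zinc_free: int = 0
    box_edge: float = 15.0          # nm
    min_separation: float = 2.4     # nm, initial center-center
    contact_radius: float = 1.8     # nm, center-center binding range
                                    # (the mean dimer diameter scale)
    bond_distance: float = 0.5      # nm, center-center after binding
    bind_prob: dict = field(default_factory=lambda: dict(DEFAULT_BIND_PROB))
    diffusion_coeff: dict = field(default_factory=lambda: dict(DEFAULT_DIFFUSION))
    dt: float = 100.0               # ps
    n_steps: int = 1000
    emit_stride: int = 10
    seed: int = 0
    max_placement_attempts: int = 100_000

    def __post_init__(self) -> None:
        for name in ("n_dimer", "n_monomer_free", "n_monomer_zn", "n_zinc_free"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.box_edge > 0:
            raise ValueError("box_edge must be positive")
        if not self.min_separation < self.box_edge / 2:
            raise ValueError("min_separation must be < box_edge/2")
        for k, p in self.bind_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"bind_prob[{set(k)}] must be in [0, 1]")


# ---------------------------------------------------------------------
# scaffold geometry
# ---------------------------------------------------------------------

def _chain_scaffold(n_res: int = 16, radius: float = 0.35) -> np.ndarray:
    """One pseudo-atom (CA) per residue on a compact helix around the
    origin, fitting within ``radius`` nm."""
    t = np.linspace(0, 4 * np.pi, n_res)
    z = np.linspace(-radius, radius, n_res)
    r = radius * 0.9
    return np.column_stack([r * np.cos(t), r * np.sin(t), z])


def _unit_offsets(species: str) -> list[np.ndarray]:
    """Per-chain atom offsets from the unit centre."""
    if species == ZINC_ION:
        return [np.zeros((1, 3))]
    if species in (MONOMER, MONOMER_ZN):
        return [_chain_scaffold()]
    if species == DIMER:
        sep = np.array([0.35, 0.0, 0.0])
        return [_chain_scaffold() - sep, _chain_scaffold() + sep]
    raise ValueError(species)


def _binding_species(species: str, zinc_bound: bool) -> str:
    if species == MONOMER and zinc_bound:
        return MONOMER_ZN
    return species


@dataclass
class SystemLayout:
    """Bookkeeping produced by build_system: which unit is what, and the
    atom indices / centre offsets of each unit (needed to move units
    rigidly)."""

    binding_species: list[str]          # per unit, incl. monomer_zn
    atom_indices: list[np.ndarray]      # per unit
    offsets: list[np.ndarray]           # per unit, (n_atoms_unit, 3)


def build_system(params: SimParams, rng: np.random.Generator | None = None):
    """Place units uniformly in the box at pairwise minimum-image
    distance >= min_separation (rejection sampling, bounded attempts).

    Returns (topology, frame, layout); deterministic for a fixed seed.
    """
    n_units = (params.n_dimer + params.n_monomer_free
               + params.n_monomer_zn + params.n_zinc_free)
    if n_units == 0:
        raise ValueError("empty system: all species counts are zero")
    rng = np.random.default_rng(params.seed) if rng is None else rng

    plan: list[tuple[str, bool]] = (
        [(DIMER, True)] * params.n_dimer
        + [(MONOMER, False)] * params.n_monomer_free
        + [(MONOMER, True)] * params.n_monomer_zn
        + [(ZINC_ION, False)] * params.n_zinc_free
    )

    centers = np.empty((n_units, 3))
    attempts = 0
    for i in range(n_units):
        while True:
            attempts += 1
            if attempts > params.max_placement_attempts:
                raise PlacementError(
                    f"could not place unit {i}/{n_units} at separation "
                    f">= {params.min_separation} nm after {attempts - 1} attempts")
            cand = rng.uniform(0.0, params.box_edge, size=3)
            if i == 0 or np.all(
                    min_image_dist(centers[:i], cand, params.box_edge)
                    >= params.min_separation):
                centers[i] = cand
                break

    alphabet = chain_id_alphabet()
    chain_iter = iter(alphabet)
    units, chains, residues, atoms = [], [], [], []
    coords_parts = []
    layout = SystemLayout(binding_species=[], atom_indices=[], offsets=[])
    atom_counter = 0
    for uid, (species, zinc_bound) in enumerate(plan):
        units.append(Unit(uid, species))
        layout.binding_species.append(_binding_species(species, zinc_bound))
        offsets = _unit_offsets(species)
        unit_atom_idx = []
        unit_offsets = []
        for chain_offsets in offsets:
            try:
                cid = next(chain_iter)
            except StopIteration:
                raise PlacementError(
                    "system needs more chains than single-character ids allow")
            chains.append((cid, uid))
            if species == ZINC_ION:
                residues.append((cid, 1, "ZN"))
                atoms.append(Atom(atom_counter, cid, 1, "ZN", "ZN"))
                unit_atom_idx.append(atom_counter)
                atom_counter += 1
            else:
                for r, resname in enumerate(AB16_SEQUENCE, start=1):
                    residues.append((cid, r, resname))
                    atoms.append(Atom(atom_counter, cid, r, "CA", "C"))
                    unit_atom_idx.append(atom_counter)
                    atom_counter += 1
            unit_offsets.append(chain_offsets)
        off = np.vstack(unit_offsets)
        layout.atom_indices.append(np.asarray(unit_atom_idx, dtype=np.intp))
        layout.offsets.append(off)
        coords_parts.append(centers[uid] + off)

    topology = Topology(units, chains, residues, atoms)
    frame = Frame(coords=np.vstack(coords_parts), box_edge=params.box_edge, time=0.0)
    return topology, frame, layout


# ---------------------------------------------------------------------
# Brownian aggregation
# ---------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def simulate(
    topology: Topology,
    frame: Frame,
    params: SimParams,
    layout: SystemLayout | None = None,
) -> Trajectory:
    """Run overdamped Brownian aggregation from an initial frame.

    Per step each cluster takes an independent Gaussian displacement of
    per-axis variance 2*D*dt, D scaled by cluster size^(-1/3); unit
    pairs from different clusters within the contact radius bind
    irreversibly with the species-pair probability, and the smaller
    cluster snaps to bond_distance so geometric contact detection sees
    the bond.  Fully reproducible from the seed; total unit count is
    conserved and the set of bound pairs only grows.
    """
    rng = np.random.default_rng(params.seed + 1)  # distinct from placement
    n_units = topology.n_units
    unit_ids = topology.atom_unit_ids()
    atom_idx = [np.flatnonzero(unit_ids == u) for u in range(n_units)]
    centers = np.array([frame.coords[idx].mean(axis=0) for idx in atom_idx])
    offsets = [frame.coords[idx] - centers[u] for u, idx in enumerate(atom_idx)]
    bspecies = (layout.binding_species if layout is not None
                else [u.species for u in topology.units])
    uf = _UnionFind(n_units)
    box = frame.box_edge
    d_unit = np.array([params.diffusion_coeff[s] for s in bspecies])

    def emit(time: float) -> Frame:
        coords = np.empty((topology.n_atoms, 3))
        for u, idx in enumerate(atom_idx):
            coords[idx] = centers[u] + offsets[u]
        return Frame(coords=coords, box_edge=box, time=time)

    frames = [emit(0.0)]

    for step in range(1, params.n_steps + 1):
        roots = [uf.find(u) for u in range(n_units)]
        clusters: dict[int, list[int]] = {}
        for u, r in enumerate(roots):
            clusters.setdefault(r, []).append(u)
        # rigid Brownian displacement per cluster
        order = sorted(clusters)
        disp = rng.standard_normal((len(order), 3))
        for k, r in enumerate(order):
            members = clusters[r]
            d_eff = d_unit[members].mean() * len(members) ** (-1.0 / 3.0)
            step_vec = math.sqrt(2.0 * d_eff * params.dt) * disp[k]
            centers[members] = wrap(centers[members] + step_vec, box)

        # binding: cross-cluster unit pairs within contact radius
        d = min_image_dist(centers[:, None, :], centers[None, :, :], box)
        iu, ju = np.triu_indices(n_units, k=1)
        close = d[iu, ju] <= params.contact_radius
        for a, b in zip(iu[close], ju[close]):
            a, b = int(a), int(b)
            ra, rb = uf.find(a), uf.find(b)
            if ra == rb:
                continue
            p = params.bind_prob.get(frozenset({bspecies[a], bspecies[b]}), 0.0)
            if p <= 0.0 or rng.random() >= p:
                continue
            # snap the smaller cluster so the new bond is a real contact
            mem_a, mem_b = clusters[ra], clusters[rb]
            small, anchor, su, au = (
                (mem_b, mem_a, b, a) if len(mem_b) <= len(mem_a)
                else (mem_a, mem_b, a, b))
            sep = min_image_vec(centers[su] - centers[au], box)
            dist = np.linalg.norm(sep)
            if dist > 0:
                shift = sep * (params.bond_distance / dist - 1.0)
                centers[small] = wrap(centers[small] + shift, box)
            uf.union(a, b)
            merged = clusters[ra] + clusters[rb]
            clusters[uf.find(a)] = merged
            clusters.pop(ra if uf.find(a) != ra else rb, None)

        if step % params.emit_stride == 0 or step == params.n_steps:
            frames.append(emit(step * params.dt))

    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------
# coordination fixtures
# ---------------------------------------------------------------------

#: tetrahedral donor directions
_TETRA = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3)

DIMER_BRIDGE_DONORS = (
    ("A", 11, "GLU", "OE1"),
    ("B", 11, "GLU", "OE1"),
    ("A", 14, "HIS", "NE2"),
    ("B", 14, "HIS", "NE2"),
)
MONOMER_CLOSED_DONORS = (
    ("A", 6, "HIS", "NE2"),
    ("A", 11, "GLU", "OE1"),
    ("A", 13, "HIS", "NE2"),
    ("A", 14, "HIS", "NE2"),
)


def make_coordination_fixture(
    motif: str = "dimer_bridge",
    distances=0.21,
    donors=None,
    coordination_cutoff: float = 0.30,
    box_edge: float = 15.0,
):
    """Build a zinc-at-origin fixture with donors at known distances.

    ``motif`` is dimer_bridge, monomer_closed or custom (then ``donors``
    is a list of (chain_id, resseq, resname, atom_name)).  ``distances``
    is a scalar or one value per donor, in nm.  All non-donor atoms are
    kept beyond twice the coordination cutoff of the zinc.  Returns
    (topology, frame, manifest) where the manifest lists the intended
    contacts as (chain_id, resseq, resname, atom_name, distance).
    """
    if motif == "dimer_bridge":
        donor_spec = DIMER_BRIDGE_DONORS
    elif motif == "monomer_closed":
        donor_spec = MONOMER_CLOSED_DONORS
    elif motif == "custom":
        donor_spec = tuple(donors or ())
    else:
        raise ValueError(f"unknown motif {motif!r}")

    dist = np.atleast_1d(np.asarray(distances, float))
    if dist.size == 1:
        dist = np.full(len(donor_spec), float(dist[0])) if donor_spec else dist[:0]
    if len(donor_spec) != dist.size:
        raise FixtureError(
            f"{len(donor_spec)} donors but {dist.size} distances")
    if np.any(dist <= 0):
        raise FixtureError("donor distances must be positive")
    if np.any(dist > 2 * coordination_cutoff):
        raise FixtureError(
            "requested donor distance exceeds the non-donor exclusion radius; "
            "the fixture geometry would be ambiguous")
    if len(donor_spec) > len(_TETRA):
        raise FixtureError("at most four donors supported")

    chain_ids = sorted({c for c, *_ in donor_spec}) or ["A"]
    if motif == "dimer_bridge" or len(chain_ids) == 2:
        unit_species = [DIMER] if len(chain_ids) == 2 else [MONOMER]
    else:
        unit_species = [MONOMER]
    # peptide unit 0 (chains), zinc unit 1
    units = [Unit(0, unit_species[0]), Unit(1, ZINC_ION)]
    chains = [(c, 0) for c in chain_ids] + [("z", 1)]
    residues, atoms, coords = [], [], []
    exclusion = 2.0 * coordination_cutoff
    donor_map: dict[tuple[str, int], list] = {}
    for k, (c, r, rn, an) in enumerate(donor_spec):
        donor_map.setdefault((c, r), []).append((rn, an, k))

    center = np.full(3, box_edge / 2.0)  # zinc placed here ("origin" of fixture)
    for ci, cid in enumerate(chain_ids):
        # scaffold CAs on a ring well outside the exclusion zone
        ring_r = exclusion + 0.5
        phase = ci * math.pi
        for r, resname in enumerate(AB16_SEQUENCE, start=1):
            ang = phase + 2 * math.pi * r / 16.0
            pos = center + ring_r * np.array([math.cos(ang), math.sin(ang),
                                              0.3 * (ci - 0.5)])
            residues.append((cid, r, resname))
            atoms.append(Atom(len(atoms), cid, r, "CA", "C"))
            coords.append(pos)
            # attach this residue's donor atoms if requested
            for rn2, an2, k in donor_map.pop((cid, r), []):
                if rn2 != resname:
                    raise FixtureError(
                        f"donor {cid}/{r} requests resname {rn2}, "
                        f"sequence has {resname}")
                atoms.append(Atom(len(atoms), cid, r, an2, an2[0]))
                coords.append(center + dist[k] * _TETRA[k])
    if donor_map:
        raise FixtureError(f"donors not placeable on sequence: {set(donor_map)}")
    residues.append(("z", 1, "ZN"))
    atoms.append(Atom(len(atoms), "z", 1, "ZN", "ZN"))
    coords.append(center)

    topology = Topology(units, chains, residues, atoms)
    frame = Frame(coords=np.array(coords), box_edge=box_edge, time=0.0)
    manifest = [
        (c, r, rn, an, float(d))
        for (c, r, rn, an), d in zip(donor_spec, dist)
    ]
    return topology, frame, manifest


# ---------------------------------------------------------------------
# partitions (test inputs for the connectivity length)
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sizes):
            raise ValueError("all parts must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.sizes)


def make_partition(total: int, n_parts: int, seed: int = 0) -> Partition:
    """Uniform random composition of ``total`` into ``n_parts`` positive
    parts (uniform over ordered compositions via random cut points)."""
    if not 1 <= n_parts <= total:
        raise ValueError("need 1 <= n_parts <= total")
    rng = np.random.default_rng(seed)
    cuts = np.sort(rng.choice(total - 1, size=n_parts - 1, replace=False)) + 1
    bounds = np.concatenate([[0], cuts, [total]])
    return Partition(sizes=tuple(int(b - a) for a, b in zip(bounds, bounds[1:])))
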