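"""Zinc coordination-shell analysis.

A zinc coordination shell is the set of protein donor atoms within a
cutoff of the ion: histidine imidazole nitrogens (ND1/NE2), aspartate and
glutamate carboxylate oxygens (OD1/OD2, OE1/OE2) and the free N-terminal
backbone amine (N of residue 1).  Typical Zn-N/O bond lengths are
0.20-0.23 nm; the default cutoff of 0.30 nm adds margin for thermal
spread and should be logged with every report, since no single value is
canonical.

Motifs
------
dimer_bridge
    One zinc shared between two peptide chains through the 11EVHH14
    metal-binding segment: Glu11 and His14 of each chain, with the
    observed variants (Asp1 substituting a glutamate, an extra His13
    bond) accepted.
monomer_closed
    A single chain wrapping the ion with His6 plus at least two of
    Glu11/His13/His14 — the closed monomeric site that aggregates poorly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Frame, Topology, Trajectory, ZINC_ION
from .pbc import min_image_dist

DEFAULT_COORDINATION_CUTOFF = 0.30  # nm

#: side-chain donor atoms per residue type
DONOR_ATOMS = {
    "HIS": ("ND1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
N_TERMINAL_RESSEQ = 1  # backbone N of residue 1 is also a donor

DIMER_BRIDGE = "dimer_bridge"
MONOMER_CLOSED = "monomer_closed"
OTHER = "other"
UNBOUND = "unbound"


@dataclass(frozen=True)
class Contact:
    chain_id: str
    resseq: int
    resname: str
    atom_name: str
    distance: float  # nm


@dataclass(frozen=True)
class CoordinationShell:
    zinc_unit_id: int
    contacts: tuple[Contact, ...]
    motif: str
    cutoff: float


@dataclass(frozen=True)
class RecaptureEvent:
    zinc_unit_id: int
    onset: int   # frame index
    dwell: int   # frames


def donor_atom_indices(topology: Topology) -> list[int]:
    """Indices of all donor atoms (the whitelist plus N-terminal N)."""
    resname = {(c, s): r for c, s, r in topology.residues}
    out = []
    for a in topology.atoms:
        rn = resname[(a.chain_id, a.resseq)]
        if a.atom_name in DONOR_ATOMS.get(rn, ()):
            out.append(a.atom_id)
        elif a.atom_name == "N" and a.resseq == N_TERMINAL_RESSEQ:
            out.append(a.atom_id)
    return out


def classify_motif(contacts) -> str:
    """Map a contact set to exactly one motif label.

    Rules (residues identified by (name, number)):
    - empty -> unbound
    - dimer_bridge: contacts span >= 2 chains; per chain the residue set
      is within {Glu11, His13, His14, Asp1}; Glu11 or Asp1 on at least
      one chain; His14 on at least one chain.
    - monomer_closed: single chain, His6 present, plus >= 2 of
      {Glu11, His13, His14}.
    - otherwise other.
    """
    contacts = tuple(contacts)
    if not contacts:
        return UNBOUND
    per_chain: dict[str, set[tuple[str, int]]] = {}
    for c in contacts:
        per_chain.setdefault(c.chain_id, set()).add((c.resname, c.resseq))
    bridge_allowed = {("GLU", 11), ("HIS", 13), ("HIS", 14), ("ASP", 1)}
    all_res = set().union(*per_chain.values())
    if len(per_chain) >= 2:
        within = all(rs <= bridge_allowed for rs in per_chain.values())
        has_acid = ("GLU", 11) in all_res or ("ASP", 1) in all_res
        has_his14 = ("HIS", 14) in all_res
        if within and has_acid and has_his14:
            return DIMER_BRIDGE
    elif len(per_chain) == 1:
        (residues,) = per_chain.values()
        closed_core = {("GLU", 11), ("HIS", 13), ("HIS", 14)}
        if ("HIS", 6) in residues and len(residues & closed_core) >= 2:
            return MONOMER_CLOSED
    return OTHER


def coordination_shell(
    frame: Frame,
    topology: Topology,
    cutoff: float = DEFAULT_COORDINATION_CUTOFF,
) -> list[CoordinationShell]:
    """One CoordinationShell per zinc_ion unit in the topology.

    Returns an empty list (with a warning) if the system has no zinc.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    zincs = topology.zinc_unit_ids()
    if not zincs:
        warnings.warn("no zinc_ion units in topology; empty coordination result")
        return []
    donors = donor_atom_indices(topology)
    resname = {(c, s): r for c, s, r in topology.residues}
    unit_ids = topology.atom_unit_ids()
    shells = []
    for zid in zincs:
        zn_atoms = np.flatnonzero(unit_ids == zid)
        zn_pos = frame.coords[zn_atoms[0]]
        contacts = []
        for ai in donors:
            d = float(min_image_dist(frame.coords[ai], zn_pos, frame.box_edge))
            if d <= cutoff:
                a = topology.atoms[ai]
                contacts.append(Contact(
                    chain_id=a.chain_id, resseq=a.resseq,
                    resname=resname[(a.chain_id, a.resseq)],
                    atom_name=a.atom_name, distance=d))
        contacts.sort(key=lambda c: (c.distance, c.chain_id, c.resseq, c.atom_name))
        shells.append(CoordinationShell(
            zinc_unit_id=zid, contacts=tuple(contacts),
            motif=classify_motif(contacts), cutoff=cutoff))
    return shells


def recapture_events(
    trajectory: Trajectory,
    zinc_id: int,
    site_selection,
    capture_cutoff: float,
    min_persistence: int = 10,
) -> list[RecaptureEvent]:
    """Detect zinc (re)capture by a coordination site over a trajectory.

    The site is the centroid of ``site_selection`` (donor atom indices).
    An event opens at the first frame of a run of at least
    ``min_persistence`` consecutive frames with zinc-centroid
    minimum-image distance <= ``capture_cutoff``; its dwell is the run
    length.  Runs are disjoint by construction, so events are too.
    """
    site = list(site_selection)
    if not site:
        raise ValueError("site_selection must name at least one donor atom")
    topo = trajectory.topology
    if zinc_id not in topo.zinc_unit_ids():
        raise ValueError(f"unit {zinc_id} is not a zinc_ion unit")
    if min_persistence < 1:
        raise ValueError("min_persistence must be >= 1")
    unit_ids = topo.atom_unit_ids()
    zn_atom = int(np.flatnonzero(unit_ids == zinc_id)[0])
    events = []
    run_start = None
    n = len(trajectory.frames)
    for i, f in enumerate(trajectory.frames):
        centroid = f.coords[site].mean(axis=0)
        d = float(min_image_dist(f.coords[zn_atom], centroid, f.box_edge))
        inside = d <= capture_cutoff
        if inside and run_start is None:
            run_start = i
        if (not inside or i == n - 1) and run_start is not None:
            end = i if not inside else i + 1
            dwell = end - run_start
            if dwell >= min_persistence:
                events.append(RecaptureEvent(zinc_id, run_start, dwell))
            run_start = None
    return events
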