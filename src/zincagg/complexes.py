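"""Complex detection: connected components of a periodic contact graph.

Two molecule units are in contact when any atom of one lies within the
contact cutoff of any atom of the other under the minimum-image
convention.  A complex is a connected component of this contact graph.
Zinc ions are never counted as molecules, matching the convention that
aggregation statistics are computed over peptide units only.

The cutoff that defines "in contact" is a free parameter of the analysis
(0.45 nm between heavy/pseudo atoms by default) and is carried on every
result so reports can echo it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .core import ComplexComposition, Frame, Topology, Trajectory
from .pbc import wrap

DEFAULT_CONTACT_CUTOFF = 0.45   # nm, atom-atom
DEFAULT_MERGE_CUTOFF = 1.0      # nm, complex-complex proximity merge


@dataclass
class ContactGraph:
    """Unit-level contact graph for one frame (zinc ions excluded)."""

    nodes: tuple[int, ...]
    edges: frozenset[frozenset[int]]
    frame_index: int | None = None
    cutoff: float | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError("edges must join two distinct units")
            if not e <= node_set:
                raise ValueError(f"edge {set(e)} references unknown node")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g


def _check_cutoff(cutoff: float, box_edge: float) -> None:
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= box_edge / 2:
        raise ValueError(
            f"cutoff {cutoff} >= box_edge/2 = {box_edge / 2}: "
            "minimum-image distances are ambiguous")


def _unit_pairs_within(
    frame: Frame, topology: Topology, unit_ids: np.ndarray,
    atom_mask: np.ndarray, cutoff: float,
) -> set[frozenset[int]]:
    """All unit pairs with some atom-atom minimum-image distance <= cutoff.

    Uses a periodic k-d tree; by construction this equals the all-pairs
    definition exactly (no approximation).
    """
    idx = np.flatnonzero(atom_mask)
    pts = wrap(frame.coords[idx], frame.box_edge)
    # guard against points folded exactly onto the box edge by fp rounding
    pts[pts >= frame.box_edge] = 0.0
    tree = cKDTree(pts, boxsize=frame.box_edge)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    out: set[frozenset[int]] = set()
    if len(pairs):
        u = unit_ids[idx[pairs[:, 0]]]
        v = unit_ids[idx[pairs[:, 1]]]
        diff = u != v
        out = {frozenset((int(a), int(b))) for a, b in zip(u[diff], v[diff])}
    return out


def contact_graph(
    frame: Frame,
    topology: Topology,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    frame_index: int | None = None,
) -> ContactGraph:
    """Build the unit-level contact graph of one frame."""
    _check_cutoff(cutoff, frame.box_edge)
    unit_ids = topology.atom_unit_ids()
    peptide = set(topology.peptide_unit_ids())
    mask = np.array([u in peptide for u in unit_ids])
    edges = _unit_pairs_within(frame, topology, unit_ids, mask, cutoff)
    return ContactGraph(
        nodes=tuple(sorted(peptide)),
        edges=frozenset(edges),
        frame_index=frame_index,
        cutoff=cutoff,
    )


def complexes(graph: ContactGraph) -> ComplexComposition:
    """Connected-component sizes as a multiset (singletons included)."""
    comps = nx.connected_components(graph.to_networkx())
    return ComplexComposition(
        sizes=tuple(len(c) for c in comps), frame_index=graph.frame_index)


def _components(graph: ContactGraph) -> list[set[int]]:
    return [set(c) for c in nx.connected_components(graph.to_networkx())]


def merge_proximal(
    composition: ComplexComposition,
    graph: ContactGraph,
    frame: Frame,
    topology: Topology,
    merge_cutoff: float = DEFAULT_MERGE_CUTOFF,
) -> ComplexComposition:
    """Merge complexes that sit within ``merge_cutoff`` of each other.

    Implements the convention that conglomerates "located very close"
    are identified as a single complex: complexes whose minimum
    inter-complex atom distance is <= merge_cutoff are merged
    transitively.  With merge_cutoff equal to the contact cutoff the
    composition is returned unchanged.
    """
    if graph.cutoff is not None and merge_cutoff < graph.cutoff:
        raise ValueError("merge_cutoff must be >= the contact cutoff")
    _check_cutoff(merge_cutoff, frame.box_edge)
    comps = _components(graph)
    if sorted(len(c) for c in comps) != sorted(composition.sizes):
        raise ValueError("composition does not match the supplied graph")
    comp_of_unit = {}
    for ci, members in enumerate(comps):
        for u in members:
            comp_of_unit[u] = ci
    unit_ids = topology.atom_unit_ids()
    peptide = set(topology.peptide_unit_ids())
    mask = np.array([u in peptide for u in unit_ids])
    prox = _unit_pairs_within(frame, topology, unit_ids, mask, merge_cutoff)
    meta = nx.Graph()
    meta.add_nodes_from(range(len(comps)))
    for pair in prox:
        a, b = tuple(pair)
        ca, cb = comp_of_unit[a], comp_of_unit[b]
        if ca != cb:
            meta.add_edge(ca, cb)
    sizes = tuple(
        sum(len(comps[c]) for c in group)
        for group in nx.connected_components(meta)
    )
    return ComplexComposition(sizes=sizes, frame_index=composition.frame_index)


def composition_timeseries(
    trajectory: Trajectory,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    merge_cutoff: float | None = None,
) -> list[ComplexComposition]:
    """Per-frame compositions; optionally with the proximity merge."""
    out = []
    for i, frame in enumerate(trajectory.frames):
        g = contact_graph(frame, trajectory.topology, cutoff, frame_index=i)
        comp = complexes(g)
        if merge_cutoff is not None:
            comp = merge_proximal(comp, g, frame, trajectory.topology, merge_cutoff)
        out.append(comp)
    return out
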