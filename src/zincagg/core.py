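"""Domain types shared by every analysis stage.

The counting unit throughout is the *molecule unit*: an Aβ16 monomer
(with or without a bound zinc), a zinc-bridged Aβ16 dimer (two peptide
chains sharing one zinc, counted as ONE unit for aggregation statistics),
or a free zinc ion.  Coordinates are stored in nanometres; boxes are cubic
and periodic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MONOMER = "monomer"
DIMER = "dimer"
ZINC_ION = "zinc_ion"
SPECIES = (MONOMER, DIMER, ZINC_ION)

#: Aβ(1-16) sequence, three-letter codes, residues Asp1..Lys16.
AB16_SEQUENCE = (
    "ASP", "ALA", "GLU", "PHE", "ARG", "HIS", "ASP", "SER",
    "GLY", "TYR", "GLU", "VAL", "HIS", "HIS", "GLN", "LYS",
)


class ZincAggError(Exception):
    """Base class for all package errors."""


class TopologyError(ZincAggError):
    """A topology violates a structural invariant."""


class ParseError(ZincAggError):
    """A structure or trajectory file could not be parsed."""


class PlacementError(ZincAggError):
    """Random placement could not satisfy the separation constraint."""


class FixtureError(ZincAggError):
    """A geometric fixture could not be constructed as requested."""


class DegenerateGeometryError(ZincAggError):
    """Input geometry is too degenerate for the requested operation."""


@dataclass(frozen=True)
class Unit:
    unit_id: int
    species: str


@dataclass(frozen=True)
class Atom:
    atom_id: int
    chain_id: str
    resseq: int
    atom_name: str
    element: str


@dataclass
class Topology:
    """Static structure: units -> chains -> residues -> atoms.

    ``units`` are contiguous ids from 0.  Every chain belongs to exactly
    one unit; a dimer owns exactly two peptide chains, a monomer one, a
    zinc ion one single-atom chain.
    """

    units: list[Unit]
    chains: list[tuple[str, int]]                    # (chain_id, unit_id)
    residues: list[tuple[str, int, str]]             # (chain_id, resseq, resname)
    atoms: list[Atom]

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        ids = [u.unit_id for u in self.units]
        if ids != list(range(len(ids))):
            raise TopologyError("unit_ids must be unique and contiguous from 0")
        for u in self.units:
            if u.species not in SPECIES:
                raise TopologyError(f"unknown species {u.species!r}")
        chain_unit = {}
        for chain_id, unit_id in self.chains:
            if chain_id in chain_unit:
                raise TopologyError(f"chain {chain_id!r} assigned twice")
            if not 0 <= unit_id < len(self.units):
                raise TopologyError(f"chain {chain_id!r} -> unknown unit {unit_id}")
            chain_unit[chain_id] = unit_id
        per_unit: dict[int, int] = {}
        for unit_id in chain_unit.values():
            per_unit[unit_id] = per_unit.get(unit_id, 0) + 1
        for u in self.units:
            n = per_unit.get(u.unit_id, 0)
            if u.species == DIMER and n != 2:
                raise TopologyError(
                    f"dimer unit {u.unit_id} owns {n} chains, expected 2")
            if u.species in (MONOMER, ZINC_ION) and n != 1:
                raise TopologyError(
                    f"{u.species} unit {u.unit_id} owns {n} chains, expected 1")
        seen: dict[str, int] = {}
        for chain_id, resseq, _ in self.residues:
            if chain_id not in chain_unit:
                raise TopologyError(f"residue on unknown chain {chain_id!r}")
            if chain_id in seen and resseq <= seen[chain_id]:
                raise TopologyError(
                    f"resseq not strictly increasing on chain {chain_id!r}")
            seen[chain_id] = resseq
        for a in self.atoms:
            if a.chain_id not in chain_unit:
                raise TopologyError(f"atom {a.atom_id} on unknown chain {a.chain_id!r}")
        if [a.atom_id for a in self.atoms] != list(range(len(self.atoms))):
            raise TopologyError("atom_ids must be contiguous from 0")

    # -- convenience --------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def chain_to_unit(self) -> dict[str, int]:
        return dict(self.chains)

    def atom_unit_ids(self) -> np.ndarray:
        """Per-atom unit id, aligned with atom order."""
        c2u = self.chain_to_unit()
        return np.array([c2u[a.chain_id] for a in self.atoms], dtype=np.intp)

    def resname(self, chain_id: str, resseq: int) -> str:
        for cid, seq, name in self.residues:
            if cid == chain_id and seq == resseq:
                return name
        raise KeyError((chain_id, resseq))

    def zinc_unit_ids(self) -> list[int]:
        return [u.unit_id for u in self.units if u.species == ZINC_ION]

    def peptide_unit_ids(self) -> list[int]:
        return [u.unit_id for u in self.units if u.species != ZINC_ION]

    # -- (de)serialisation --------------------------------------------
    def to_dict(self) -> dict:
        return {
            "units": [[u.unit_id, u.species] for u in self.units],
            "chains": [list(c) for c in self.chains],
            "residues": [list(r) for r in self.residues],
            "atoms": [[a.atom_id, a.chain_id, a.resseq, a.atom_name, a.element]
                      for a in self.atoms],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        return cls(
            units=[Unit(int(i), s) for i, s in d["units"]],
            chains=[(c, int(u)) for c, u in d["chains"]],
            residues=[(c, int(s), n) for c, s, n in d["residues"]],
            atoms=[Atom(int(i), c, int(s), n, e) for i, c, s, n, e in d["atoms"]],
        )


@dataclass
class Frame:
    """One snapshot: coordinates in nm, cubic box edge in nm, time in ps."""

    coords: np.ndarray
    box_edge: float
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.box_edge > 0:
            raise ValueError("box_edge must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """An ordered frame sequence bound to one topology."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise TopologyError(
                    f"frame {i} has {f.n_atoms} atoms, topology has {n}")
        times = [f.time for f in self.frames]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class ComplexComposition:
    """Multiset of complex sizes (in molecule units) at one frame.

    This is the domain of the connectivity-length statistic; zinc ions are
    never counted.
    """

    sizes: tuple[int, ...]
    frame_index: int | None = None

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sizes):
            raise ValueError("complex sizes must be >= 1")
        object.__setattr__(self, "sizes", tuple(sorted(self.sizes, reverse=True)))

    @property
    def n_units(self) -> int:
        return sum(self.sizes)

    @property
    def n_complexes(self) -> int:
        return len(self.sizes)


def chain_id_alphabet() -> str:
    """Single-character chain identifiers usable in fixed-column PDB."""
    import string

    return string.ascii_uppercase + string.ascii_lowercase + string.digits
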