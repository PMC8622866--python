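"""Structure and trajectory I/O.

Formats
-------
PDB
    Fixed-column ATOM/HETATM records (first MODEL by default; NMR
    ensembles such as the Aβ16 starting structures are multi-model).
    PDB files carry Å; everything internal is nm.  Chain grouping into
    molecule units is explicit configuration, because a zinc-bridged
    dimer (two chains, one unit) cannot be inferred from the file.
GRO
    Multi-frame GROMACS coordinate files, nm native, box-vector line per
    frame.  GRO has no chain records, so a Topology must be supplied.
xyzb
    Internal plain-text dialect: per frame a header line
    ``natoms time box_edge`` followed by one ``atom_id x y z`` line per
    atom (nm, ps).  Floats are written with ``repr`` so a write/read
    round trip is bit-identical.  Standard XYZ lacks the box information
    periodic analysis needs, hence the dialect.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.gro as gro_io
import biotite.structure.io.pdb as pdb_io

from .core import (
    Atom,
    DIMER,
    Frame,
    MONOMER,
    ParseError,
    Topology,
    TopologyError,
    Trajectory,
    Unit,
    ZINC_ION,
    chain_id_alphabet,
)

ANGSTROM_PER_NM = 10.0
#: Box edge used when a PDB has no CRYST1 record: large enough that the
#: minimum-image convention never wraps (effectively non-periodic).
NO_BOX_EDGE = 1000.0


# ---------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------

def _prescan_pdb(text: str, path) -> int:
    """Validate ATOM/HETATM records; return their count.

    Gives line-numbered errors for malformed records, which the backing
    parser does not.
    """
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        n += 1
        if len(line) < 54:
            raise ParseError(f"{path}: truncated record at line {lineno}")
        try:
            int(line[22:26])
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed ATOM/HETATM record at line {lineno}: {exc}"
            ) from exc
    return n


def read_pdb(
    path,
    chain_units: dict[str, object] | None = None,
    model: int = 1,
    box_edge: float | None = None,
) -> tuple[Topology, Frame]:
    """Read one model of a PDB file into (Topology, Frame).

    Parameters
    ----------
    chain_units
        Map chain_id -> unit key; chains sharing a key become one unit
        (two peptide chains -> a dimer).  Default: each chain is its own
        monomer unit.  ZN HETATM atoms always become zinc_ion units.
    model
        1-based model index for multi-model (NMR ensemble) files.
    box_edge
        Override the box edge in nm; default: CRYST1 if present, else a
        large non-periodic sentinel.
    """
    path = Path(path)
    text = path.read_text()
    if _prescan_pdb(text, path) == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records (empty input)")
    pdb_file = pdb_io.PDBFile.read(str(path))
    try:
        arr = pdb_file.get_structure(model=model)
    except Exception as exc:  # biotite raises several types here
        raise ParseError(f"{path}: {exc}") from exc

    if box_edge is None:
        if arr.box is not None:
            box_edge = float(arr.box[0, 0]) / ANGSTROM_PER_NM
        else:
            box_edge = NO_BOX_EDGE

    chain_units = dict(chain_units or {})
    elements = [str(e).upper() for e in arr.element]
    is_zinc = [
        el == "ZN" or str(rn).strip().upper() == "ZN"
        for el, rn in zip(elements, arr.res_name)
    ]

    used_chain_ids = {str(c) for c in arr.chain_id}
    peptide_chain_ids = {
        str(c) for c, z in zip(arr.chain_id, is_zinc) if not z}
    spare = (c for c in chain_id_alphabet() if c not in used_chain_ids)

    units: list[Unit] = []
    chains: list[tuple[str, int]] = []
    residues: list[tuple[str, int, str]] = []
    atoms: list[Atom] = []
    unit_of_key: dict[object, int] = {}
    chain_registered: set[str] = set()
    seen_residues: set[tuple[str, int]] = set()

    for i in range(arr.array_length()):
        cid = str(arr.chain_id[i])
        if is_zinc[i]:
            # keep the file's chain id when the ion has a chain to itself
            if cid not in peptide_chain_ids and cid not in chain_registered \
                    and cid not in (c for c, _ in chains):
                zn_chain = cid
            else:
                zn_chain = next(spare)
            unit_id = len(units)
            units.append(Unit(unit_id, ZINC_ION))
            chains.append((zn_chain, unit_id))
            residues.append((zn_chain, int(arr.res_id[i]), "ZN"))
            atoms.append(Atom(len(atoms), zn_chain, int(arr.res_id[i]), "ZN", "ZN"))
            continue
        if cid not in chain_registered:
            key = chain_units.get(cid, cid)
            if key not in unit_of_key:
                unit_of_key[key] = len(units)
                units.append(Unit(len(units), MONOMER))
            chains.append((cid, unit_of_key[key]))
            chain_registered.add(cid)
        rid = int(arr.res_id[i])
        if (cid, rid) not in seen_residues:
            residues.append((cid, rid, str(arr.res_name[i]).strip()))
            seen_residues.add((cid, rid))
        atoms.append(
            Atom(len(atoms), cid, rid, str(arr.atom_name[i]).strip(), elements[i])
        )

    # promote multi-chain units to dimers
    n_chains: dict[int, int] = {}
    for _, uid in chains:
        n_chains[uid] = n_chains.get(uid, 0) + 1
    promoted = []
    for u in units:
        n = n_chains.get(u.unit_id, 0)
        if u.species == MONOMER and n == 2:
            promoted.append(Unit(u.unit_id, DIMER))
        elif u.species == MONOMER and n > 2:
            raise TopologyError(
                f"unit key groups {n} chains; only monomers (1) and dimers (2) exist")
        else:
            promoted.append(u)

    topology = Topology(promoted, chains, residues, atoms)
    coords = np.asarray(arr.coord, float) / ANGSTROM_PER_NM
    return topology, Frame(coords=coords, box_edge=box_edge, time=0.0)


def write_pdb(topology: Topology, frame: Frame, path) -> None:
    """Write a frame as a standard fixed-column PDB (nm -> Å)."""
    topology.validate()
    if frame.n_atoms != topology.n_atoms:
        raise TopologyError(
            f"frame has {frame.n_atoms} atoms, topology has {topology.n_atoms}")
    for cid, _ in topology.chains:
        if len(cid) != 1:
            raise ValueError(f"PDB chain ids must be single characters, got {cid!r}")
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = frame.coords * ANGSTROM_PER_NM
    resname = {(c, s): r for c, s, r in topology.residues}
    arr.chain_id = np.array([a.chain_id for a in topology.atoms], dtype="U4")
    arr.res_id = np.array([a.resseq for a in topology.atoms], dtype=int)
    arr.res_name = np.array(
        [resname[(a.chain_id, a.resseq)] for a in topology.atoms], dtype="U5")
    arr.atom_name = np.array([a.atom_name for a in topology.atoms], dtype="U6")
    arr.element = np.array([a.element for a in topology.atoms], dtype="U2")
    arr.hetero = np.array([a.element.upper() == "ZN" for a in topology.atoms])
    arr.box = np.eye(3) * frame.box_edge * ANGSTROM_PER_NM
    pdb_file = pdb_io.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------
# xyzb dialect
# ---------------------------------------------------------------------

def _read_xyzb(path, topology: Topology) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        header = lines[i].split()
        if len(header) != 3:
            raise ParseError(
                f"{path}: frame {len(frames)}: header must be "
                f"'natoms time box_edge', got {lines[i]!r}")
        try:
            natoms, time, box_edge = int(header[0]), float(header[1]), float(header[2])
        except ValueError as exc:
            raise ParseError(f"{path}: frame {len(frames)}: bad header: {exc}") from exc
        if natoms != topology.n_atoms:
            raise TopologyError(
                f"{path}: frame {len(frames)} has {natoms} atoms, "
                f"topology has {topology.n_atoms}")
        if i + 1 + natoms > len(lines):
            raise ParseError(f"{path}: frame {len(frames)} truncated")
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            parts = lines[i + 1 + k].split()
            if len(parts) != 4:
                raise ParseError(
                    f"{path}: frame {len(frames)}, atom line {k}: "
                    f"expected 'atom_id x y z'")
            if int(parts[0]) != k:
                raise ParseError(
                    f"{path}: frame {len(frames)}: atom_id {parts[0]} out of order")
            coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(Frame(coords=coords, box_edge=box_edge, time=time))
        i += 1 + natoms
    if not frames:
        raise ParseError(f"{path}: no frames")
    return frames


def _write_xyzb(trajectory: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for f in trajectory.frames:
            fh.write(f"{f.n_atoms} {float(f.time)!r} {float(f.box_edge)!r}\n")
            for k, (x, y, z) in enumerate(f.coords):
                fh.write(f"{k} {float(x)!r} {float(y)!r} {float(z)!r}\n")


# ---------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------

_GRO_TIME_RE = re.compile(r"\bt=\s*([0-9.eE+-]+)")


def _read_gro(path, topology: Topology) -> list[Frame]:
    gro_file = gro_io.GROFile.read(str(path))
    try:
        stack = gro_file.get_structure()
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    if stack.array_length() != topology.n_atoms:
        raise TopologyError(
            f"{path}: frames have {stack.array_length()} atoms, "
            f"topology has {topology.n_atoms}")
    if stack.box is None:
        raise ParseError(f"{path}: missing box-vector line")
    # biotite normalises to Å; GRO is natively nm
    coords = np.asarray(stack.coord, float) / ANGSTROM_PER_NM
    boxes = np.asarray(stack.box, float) / ANGSTROM_PER_NM

    # pull "t=" time stamps from title lines; fall back to frame index (ps)
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        m = _GRO_TIME_RE.search(lines[i])
        times.append(float(m.group(1)) if m else float(len(times)))
        try:
            natoms = int(lines[i + 1])
        except (IndexError, ValueError) as exc:
            raise ParseError(
                f"{path}: frame {len(times) - 1}: bad atom-count line") from exc
        i += natoms + 3  # title + count + atoms + box line
    frames = []
    for j in range(coords.shape[0]):
        frames.append(Frame(coords=coords[j], box_edge=float(boxes[j][0, 0]),
                            time=times[j] if j < len(times) else float(j)))
    return frames


def _write_gro(trajectory: Trajectory, path) -> None:
    """Write GRO; per-frame time goes into the title line ('t=')."""
    topo = trajectory.topology
    resname = {(c, s): r for c, s, r in topo.residues}
    with open(path, "w") as fh:
        for f in trajectory.frames:
            fh.write(f"zincagg trajectory, t= {f.time:.3f}\n")
            fh.write(f"{f.n_atoms:5d}\n")
            for a, (x, y, z) in zip(topo.atoms, f.coords):
                rn = resname[(a.chain_id, a.resseq)]
                fh.write(
                    f"{a.resseq:5d}{rn:<5s}{a.atom_name:>5s}"
                    f"{(a.atom_id + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
            e = f.box_edge
            fh.write(f"{e:10.5f}{e:10.5f}{e:10.5f}\n")


# ---------------------------------------------------------------------
# public trajectory API
# ---------------------------------------------------------------------

def read_trajectory(path, topology: Topology, format: str = "xyzb") -> Trajectory:
    """Read a multi-frame trajectory bound to an existing topology."""
    if format == "xyzb":
        frames = _read_xyzb(path, topology)
    elif format == "gro":
        frames = _read_gro(path, topology)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return Trajectory(topology=topology, frames=frames)


def write_trajectory(trajectory: Trajectory, path, format: str = "xyzb") -> None:
    """Write a trajectory; xyzb round-trips coordinates bit-identically."""
    if format == "xyzb":
        _write_xyzb(trajectory, path)
    elif format == "gro":
        _write_gro(trajectory, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
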