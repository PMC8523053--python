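"""Structure/trajectory data model, format I/O, periodic geometry and selections.

Everything downstream works in a single unit system: lengths in nm, energies
in kJ/mol, temperatures in K, times in ns.  PDB files (Å) are converted on
read and write; GRO files are already in nm.  Boxes are orthorhombic only —
the bilayer systems this package targets are rectangular, and triclinic
inputs are rejected with an explicit error rather than silently mishandled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

KB = 0.0083145  # Boltzmann constant, kJ mol^-1 K^-1
KCAL = 4.184    # kJ per kcal; used only when reporting

#: standard atomic masses (u); mass-weighting for centers of mass
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "B": 10.811, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "NA": 22.990, "MG": 24.305, "SI": 28.086,
    "P": 30.974, "S": 32.06, "CL": 35.45, "K": 39.098, "CA": 40.078,
    "FE": 55.845, "ZN": 65.38, "BR": 79.904, "I": 126.904,
}

#: residue names recognised as water (one O, two H expected)
WATER_RESNAMES = {"HOH", "SOL", "TIP3", "WAT", "TIP", "SPC", "W"}

#: the 20 standard amino acids plus common protonation variants
PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "ASH", "GLH", "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "LYN", "CYX",
}


class ParseError(ValueError):
    """A structure/trajectory file could not be parsed."""


class FormatError(ValueError):
    """Unsupported or inconsistent file format."""


class StructuralError(ValueError):
    """Topology/coordinate inconsistency (e.g. atom-count mismatch)."""


class SelectionError(ValueError):
    """A selection expression is malformed or resolves to nothing."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity only, no coordinates."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str


class Topology:
    """Ordered atom table with cached per-column numpy views."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms = list(atoms)
        if len({a.index for a in self.atoms}) != len(self.atoms):
            raise StructuralError("atom indices must be unique within a topology")
        self.names = np.array([a.name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.residue_ids = np.array([a.residue_id for a in self.atoms], dtype=int)
        self.chain_ids = np.array([a.chain_id for a in self.atoms])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def masses(self) -> np.ndarray:
        """Per-atom masses from element symbols; unknown elements fall back to carbon."""
        m = np.empty(self.n_atoms)
        unknown = set()
        for i, el in enumerate(self.elements):
            key = el.upper()
            if key in ATOMIC_MASSES:
                m[i] = ATOMIC_MASSES[key]
            else:
                m[i] = ATOMIC_MASSES["C"]
                unknown.add(el)
        if unknown:
            warnings.warn(
                f"unknown element(s) {sorted(unknown)}: using carbon mass", stacklevel=2
            )
        return m

    def residues(self) -> list[tuple[str, int, str, np.ndarray]]:
        """Group atoms into residues, preserving file order.

        Returns (chain_id, residue_id, residue_name, atom_index_array) tuples.
        """
        out: list[tuple[str, int, str, list[int]]] = []
        seen: dict[tuple[str, int], int] = {}
        for a in self.atoms:
            key = (a.chain_id, a.residue_id)
            if key not in seen:
                seen[key] = len(out)
                out.append((a.chain_id, a.residue_id, a.residue_name, [a.index]))
            else:
                out[seen[key]][3].append(a.index)
        return [(c, r, n, np.asarray(idx, dtype=int)) for c, r, n, idx in out]

    def select(self, expression: str) -> np.ndarray:
        """Resolve a selection expression to sorted atom indices (see :func:`select_atoms`)."""
        return select_atoms(self, expression)


@dataclass
class Frame:
    """Coordinates (nm) + orthorhombic box (nm) at one time point (ns)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructuralError("coordinates must be an (N, 3) array")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise StructuralError("box must be three positive edge lengths")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        for i, f in enumerate(self.frames):
            if f.coordinates.shape[0] != self.topology.n_atoms:
                raise StructuralError(
                    f"frame {i}: {f.coordinates.shape[0]} coordinates for "
                    f"{self.topology.n_atoms} atoms"
                )
        times = [f.time for f in self.frames]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise StructuralError("frame times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass(frozen=True)
class CylinderMask:
    """Validity cylinder along z through the protein center of mass.

    Defaults follow the restraint geometry used for the translocation
    coordinate: diameter 1.5 nm, height 6 nm.
    """

    diameter: float = 1.5
    height: float = 6.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise ValueError("cylinder diameter and height must be positive")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_SELECTION_KEYWORDS = {"chain", "resid", "resname", "name", "element", "water", "protein"}


def select_atoms(topology: Topology, expression: str) -> np.ndarray:
    """Resolve a selection like ``"chain A and resid 14 and name OE1 OE2"``.

    Grammar: a conjunction of clauses joined by ``and``.  Each clause is a
    keyword (``chain``, ``resid``, ``resname``, ``name``, ``element``)
    followed by one or more values, or one of the bare keywords ``water`` /
    ``protein``.  ``resid`` accepts ranges written ``a:b`` (inclusive).
    Resolution is deterministic; indices are returned sorted.
    """
    tokens = expression.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = np.ones(topology.n_atoms, dtype=bool)
    i = 0
    while i < len(tokens):
        kw = tokens[i].lower()
        if kw == "and":
            i += 1
            continue
        if kw not in _SELECTION_KEYWORDS:
            raise SelectionError(f"unknown selection keyword {tokens[i]!r}")
        if kw == "water":
            mask &= np.isin(topology.residue_names, list(WATER_RESNAMES))
            i += 1
            continue
        if kw == "protein":
            mask &= np.isin(topology.residue_names, list(PROTEIN_RESNAMES))
            i += 1
            continue
        values = []
        i += 1
        while i < len(tokens) and tokens[i].lower() not in _SELECTION_KEYWORDS \
                and tokens[i].lower() != "and":
            values.append(tokens[i])
            i += 1
        if not values:
            raise SelectionError(f"selection keyword {kw!r} needs at least one value")
        if kw == "chain":
            mask &= np.isin(topology.chain_ids, values)
        elif kw == "resname":
            mask &= np.isin(topology.residue_names, values)
        elif kw == "name":
            mask &= np.isin(topology.names, values)
        elif kw == "element":
            mask &= np.isin(np.char.upper(topology.elements.astype(str)),
                            [v.upper() for v in values])
        elif kw == "resid":
            ids: set[int] = set()
            for v in values:
                if ":" in v:
                    lo, hi = v.split(":")
                    ids.update(range(int(lo), int(hi) + 1))
                else:
                    ids.add(int(v))
            mask &= np.isin(topology.residue_ids, sorted(ids))
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Periodic geometry and the reaction coordinate
# ---------------------------------------------------------------------------

def min_image_vector(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement b - a for an orthorhombic box (broadcasts)."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box components must be positive")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float | np.ndarray:
    """Minimum-image distance between points a and b in an orthorhombic box."""
    d = min_image_vector(a, b, box)
    return np.linalg.norm(d, axis=-1)


def center_of_mass(frame: Frame, topology: Topology,
                   indices: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted center of the selected atoms (no periodic unwrapping)."""
    if indices is None:
        indices = np.arange(topology.n_atoms)
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise SelectionError("center of mass of an empty selection")
    m = topology.masses()[indices]
    x = frame.coordinates[indices]
    return (m[:, None] * x).sum(axis=0) / m.sum()


def reaction_coordinate_z(frame: Frame, topology: Topology,
                          protein_indices: np.ndarray, ligand_atom: int) -> float:
    """z-component of (ligand position − protein center of mass), in nm.

    The sign convention puts the solvent-open side of the transporter at
    positive z.  Translation-invariant by construction.
    """
    com = center_of_mass(frame, topology, protein_indices)
    return float(frame.coordinates[ligand_atom, 2] - com[2])


def in_cylinder(frame: Frame, topology: Topology, protein_indices: np.ndarray,
                mask: CylinderMask, atom: int) -> bool:
    """True iff the atom lies inside the z-axis cylinder through the protein COM."""
    com = center_of_mass(frame, topology, protein_indices)
    d = frame.coordinates[atom] - com
    radial = float(np.hypot(d[0], d[1]))
    return radial <= mask.diameter / 2.0 and abs(float(d[2])) <= mask.height / 2.0


def wrap_coordinates(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, box) per dimension (used for k-d tree queries)."""
    return np.mod(coords, box)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _element_from_name(name: str, residue_name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    # two-letter elements only when unambiguous (monatomic ions etc.)
    if two in {"CL", "NA", "MG", "BR", "FE", "ZN"} and residue_name.strip().upper() in {
            "CL", "CLA", "NA", "SOD", "MG", "BR", "FE", "ZN", "ION"}:
        return two.capitalize()
    return stripped[0].upper()


def _parse_pdb_box(line: str, lineno: int) -> np.ndarray:
    try:
        a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
        alpha, beta, gamma = float(line[33:40]), float(line[40:47]), float(line[47:54])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed CRYST1 record") from exc
    if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
        raise FormatError(
            f"line {lineno}: triclinic box (angles {alpha}, {beta}, {gamma}) not supported"
        )
    return np.array([a, b, c]) / 10.0  # Å -> nm


def _parse_pdb_atom(line: str, lineno: int, index: int) -> tuple[AtomRecord, np.ndarray]:
    try:
        name = line[12:16].strip()
        residue_name = line[17:21].strip()
        chain_id = line[21].strip() or "A"
        residue_id = int(line[22:26])
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])]) / 10.0
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM/HETATM record") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _element_from_name(name, residue_name)
    return AtomRecord(index, name, element, residue_name, residue_id, chain_id), xyz


def read_pdb(path: str | Path) -> tuple[Topology, list[Frame], list[np.ndarray | None]]:
    """Parse a (possibly multi-model) PDB file.

    Returns the topology, one Frame per MODEL (or a single frame for plain
    files) and the per-model boxes (None where no CRYST1 was present).
    """
    atoms: list[AtomRecord] = []
    frames_xyz: list[list[np.ndarray]] = [[]]
    box: np.ndarray | None = None
    first_model_done = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                box = _parse_pdb_box(line, lineno)
            elif rec in ("ATOM  ", "HETATM"):
                idx = len(frames_xyz[-1])
                atom, xyz = _parse_pdb_atom(line, lineno, idx)
                if not first_model_done:
                    atoms.append(atom)
                elif idx >= len(atoms):
                    raise StructuralError(
                        f"line {lineno}: model has more atoms than the first model"
                    )
                frames_xyz[-1].append(xyz)
            elif rec.startswith("ENDMDL"):
                first_model_done = True
                frames_xyz.append([])
    if frames_xyz and not frames_xyz[-1]:
        frames_xyz.pop()
    if not frames_xyz or not atoms:
        raise ParseError(f"{path}: no atoms found")
    for i, xyz in enumerate(frames_xyz):
        if len(xyz) != len(atoms):
            raise StructuralError(
                f"model {i + 1} has {len(xyz)} atoms, expected {len(atoms)}"
            )
    topology = Topology(atoms)
    default_box = box if box is not None else np.full(3, 100.0)
    frames = [Frame(np.asarray(xyz), default_box, time=float(i))
              for i, xyz in enumerate(frames_xyz)]
    boxes = [box for _ in frames]
    return topology, frames, boxes


def write_pdb(path: str | Path, topology: Topology,
              frames: Frame | Sequence[Frame]) -> None:
    """Write one or more frames as a (multi-model) PDB file, coordinates in Å."""
    if isinstance(frames, Frame):
        frames = [frames]
    multi = len(frames) > 1
    with open(path, "w") as fh:
        box = frames[0].box * 10.0
        fh.write(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for imodel, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            for a, xyz in zip(topology.atoms, frame.coordinates * 10.0):
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {(a.index + 1) % 100000:5d} {name:<4.4s} "
                    f"{a.residue_name:<4.4s}{a.chain_id[:1]}{a.residue_id % 10000:4d}"
                    f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2.2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def read_gro(path: str | Path) -> tuple[Topology, Frame]:
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GRO file")
    try:
        n_atoms = int(lines[1])
    except ValueError as exc:
        raise ParseError("line 2: expected atom count") from exc
    if len(lines) < n_atoms + 3:
        raise ParseError(f"{path}: expected {n_atoms} atom lines")
    atoms, xyz = [], []
    for i in range(n_atoms):
        line = lines[2 + i]
        lineno = 3 + i
        try:
            residue_id = int(line[0:5])
            residue_name = line[5:10].strip()
            name = line[10:15].strip()
            x, y, z = float(line[20:28]), float(line[28:36]), float(line[36:44])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"line {lineno}: malformed GRO atom record") from exc
        element = _element_from_name(name, residue_name)
        atoms.append(AtomRecord(i, name, element, residue_name, residue_id, "A"))
        xyz.append([x, y, z])
    box_fields = lines[2 + n_atoms].split()
    if len(box_fields) < 3:
        raise ParseError(f"line {3 + n_atoms}: malformed box line")
    vals = [float(v) for v in box_fields]
    if len(vals) > 3 and any(abs(v) > 1e-9 for v in vals[3:]):
        raise FormatError("triclinic GRO box not supported")
    return Topology(atoms), Frame(np.asarray(xyz), np.asarray(vals[:3]))


def write_gro(path: str | Path, topology: Topology, frame: Frame,
              title: str = "protonflux") -> None:
    with open(path, "w") as fh:
        fh.write(f"{title}\n{topology.n_atoms:5d}\n")
        for a, xyz in zip(topology.atoms, frame.coordinates):
            fh.write(
                f"{a.residue_id % 100000:5d}{a.residue_name:<5.5s}{a.name:>5.5s}"
                f"{(a.index + 1) % 100000:5d}{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}\n"
            )
        fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# XYZ (nm convention, box/time carried on the comment line)
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path, topology: Topology | None = None,
             box: np.ndarray | None = None) -> Trajectory:
    """Read a multi-frame XYZ file written by :func:`write_xyz` (lengths in nm).

    The comment line may carry ``box=a,b,c`` and ``time=t``; otherwise a box
    must be supplied.  A topology, when given, must match the atom count.
    """
    frames: list[Frame] = []
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    nframe = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i])
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: expected atom count") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        fbox, ftime = box, float(nframe)
        for tok in comment.split():
            if tok.startswith("box="):
                fbox = np.array([float(v) for v in tok[4:].split(",")])
            elif tok.startswith("time="):
                ftime = float(tok[5:])
        if fbox is None:
            raise FormatError(f"{path}: no box on comment line and none supplied")
        if i + 2 + n > len(lines):
            raise ParseError(f"line {i + 1}: truncated frame")
        xyz = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ParseError(f"line {i + 3 + j}: malformed XYZ atom line")
            if nframe == 0 and topology is None:
                el = parts[0]
                atoms.append(AtomRecord(j, el, el, "UNK", 1, "A"))
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(Frame(np.asarray(xyz), np.asarray(fbox, dtype=float), time=ftime))
        i += 2 + n
        nframe += 1
    if not frames:
        raise ParseError(f"{path}: no frames found")
    top = topology if topology is not None else Topology(atoms)
    return Trajectory(top, frames)


def write_xyz(path: str | Path, trajectory: Trajectory) -> None:
    with open(path, "w") as fh:
        top = trajectory.topology
        for frame in trajectory.frames:
            fh.write(f"{top.n_atoms}\n")
            b = frame.box
            fh.write(f"box={b[0]:.6f},{b[1]:.6f},{b[2]:.6f} time={frame.time:.6f}\n")
            for el, xyz in zip(top.elements, frame.coordinates):
                fh.write(f"{el or 'X':<3s} {xyz[0]:14.8f} {xyz[1]:14.8f} {xyz[2]:14.8f}\n")


# ---------------------------------------------------------------------------
# Unified loaders
# ---------------------------------------------------------------------------

def load_structure(path: str | Path, format: str | None = None) -> tuple[Topology, Frame]:
    """Load a single structure from PDB or GRO; coordinates in nm."""
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt == "pdb":
        topology, frames, _ = read_pdb(path)
        return topology, frames[0]
    if fmt == "gro":
        return read_gro(path)
    raise FormatError(f"unsupported structure format {fmt!r}")


def load_trajectory(path: str | Path, format: str | None = None,
                    topology: Topology | None = None,
                    box: np.ndarray | None = None) -> Trajectory:
    """Load a trajectory: multi-model PDB / XYZ natively, XTC/DCD via MDAnalysis.

    XTC/DCD need a ``topology`` (from :func:`load_structure`) plus a topology
    file path is not required — MDAnalysis only provides coordinates here.
    """
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt == "pdb":
        top, frames, boxes = read_pdb(path)
        if topology is not None:
            if topology.n_atoms != top.n_atoms:
                raise StructuralError("supplied topology does not match PDB atom count")
            top = topology
        if boxes[0] is None and box is not None:
            for f in frames:
                f.box = np.asarray(box, dtype=float)
        return Trajectory(top, frames)
    if fmt == "xyz":
        return read_xyz(path, topology=topology, box=box)
    if fmt in ("xtc", "dcd"):
        return _load_mdanalysis(path, topology, box)
    raise FormatError(f"unsupported trajectory format {fmt!r}")


def _load_mdanalysis(path: str | Path, topology: Topology | None,
                     box: np.ndarray | None) -> Trajectory:
    import MDAnalysis as mda

    if topology is None:
        raise StructuralError("XTC/DCD trajectories require an explicit topology")
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    u.load_new(str(path))
    frames = []
    for ts in u.trajectory:
        if ts.n_atoms != topology.n_atoms:
            raise StructuralError(
                f"frame {ts.frame}: {ts.n_atoms} atoms, topology has {topology.n_atoms}"
            )
        if ts.dimensions is not None and ts.dimensions[:3].any():
            if not np.allclose(ts.dimensions[3:], 90.0, atol=1e-3):
                raise FormatError("triclinic trajectory boxes not supported")
            fbox = np.asarray(ts.dimensions[:3], dtype=float) / 10.0
        elif box is not None:
            fbox = np.asarray(box, dtype=float)
        else:
            raise FormatError("trajectory carries no box and none was supplied")
        frames.append(Frame(ts.positions.astype(float) / 10.0, fbox,
                            time=float(ts.time) / 1000.0))  # ps -> ns
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(topology, frames)
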