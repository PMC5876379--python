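"""Data model and file I/O for topologies and trajectories.

Units follow the conventions of the Amber-style analysis this pipeline
mirrors: coordinates in angstrom (A), times in nanoseconds (ns), energies
in kcal/mol.  Residue numbering is taken verbatim from the PDB author
numbering so that outputs read "L172", "F197" exactly as a structural
biologist expects for the Mincle carbohydrate-recognition domain.

Supported trajectory formats: multi-model PDB (MODEL/ENDMDL), extended XYZ
(comment line carrying ``time_ns=<float>``) and, for convenience, DCD read
through :mod:`mdtraj`.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DuplicateAtomError,
    GroupingError,
    PDBParseError,
    SegmentMapError,
    ShapeError,
)

__all__ = [
    "Segment",
    "Atom",
    "Topology",
    "Trajectory",
    "load_topology",
    "load_trajectory",
    "assign_acyl_groups",
    "write_topology_pdb",
    "write_trajectory_pdb",
    "write_trajectory_xyz",
]

# Elements recognised when inferring from atom names (two-letter first).
_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "CA", "MN", "CU"}

# Monoisotopic-ish masses for mass-weighted geometry (amu).
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "CL": 35.45, "NA": 22.990, "CA": 40.078, "MG": 24.305,
    "FE": 55.845, "ZN": 65.38,
}


class Segment(str, enum.Enum):
    """Coarse molecular role of an atom."""

    PROTEIN = "protein"
    LIGAND = "ligand"
    SOLVENT = "solvent"
    ION = "ion"


@dataclass
class Atom:
    """One atom of the system.

    ``group_label`` marks acyl-chain CH2/CH3 membership in the form
    ``"F1:CH6"`` (chain F1, methylene group at carbon 6); it is set by
    :func:`assign_acyl_groups`.  ``lj_key`` is the ``(residue_name,
    atom_name)`` lookup used by the energetics module; by default it is the
    atom's own identity.
    """

    index: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain_id: str
    segment: Segment
    group_label: str | None = None
    lj_key: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.lj_key is None:
            self.lj_key = (self.residue_name, self.name)

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), 12.011)


@dataclass
class Topology:
    """Ordered atom list with a residue index."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        for i, atom in enumerate(self.atoms):
            if atom.index != i:
                raise ValueError(
                    f"atom indices must be 0-based and contiguous; "
                    f"atom {i} has index {atom.index}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_index(self) -> dict[tuple[str, int], list[int]]:
        """Mapping (chain_id, residue_id) -> atom indices, covering every atom."""
        index: dict[tuple[str, int], list[int]] = {}
        for atom in self.atoms:
            index.setdefault((atom.chain_id, atom.residue_id), []).append(atom.index)
        return index

    def residues(self, segment: Segment | None = None) -> list[tuple[str, int, str]]:
        """Ordered unique residues as (chain_id, residue_id, residue_name)."""
        seen: dict[tuple[str, int], str] = {}
        for atom in self.atoms:
            if segment is not None and atom.segment != segment:
                continue
            seen.setdefault((atom.chain_id, atom.residue_id), atom.residue_name)
        return [(c, r, n) for (c, r), n in seen.items()]

    def indices(self, segment: Segment) -> np.ndarray:
        return np.array(
            [a.index for a in self.atoms if a.segment == segment], dtype=np.intp
        )

    def masses(self, indices: Sequence[int] | None = None) -> np.ndarray:
        atoms = self.atoms if indices is None else [self.atoms[i] for i in indices]
        return np.array([a.mass for a in atoms])


@dataclass
class Trajectory:
    """Coordinate frames (A) with a time axis (ns) over a fixed topology."""

    topology: Topology
    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,), ns, strictly increasing
    box: np.ndarray | None = None  # optional (n_frames, 3) orthorhombic lengths

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ShapeError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ShapeError(
                f"frames carry {self.coordinates.shape[1]} atoms but topology "
                f"has {self.topology.n_atoms}"
            )
        if len(self.times) != self.coordinates.shape[0]:
            raise ShapeError("one time stamp per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def frame_spacing_ns(self) -> float:
        if self.n_frames < 2:
            raise ValueError("frame spacing undefined for <2 frames")
        return float(np.median(np.diff(self.times)))

    def __getitem__(self, frame: int) -> np.ndarray:
        return self.coordinates[frame]


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in _TWO_LETTER_ELEMENTS and len(atom_name.strip()) <= 2:
        return two.capitalize()
    return stripped[0].upper()


def _parse_atom_record(line: str, line_number: int) -> dict:
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(line_number, "record shorter than coordinate fields")
    try:
        name = line[12:16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip() or " "
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(line_number, f"unparsable field ({exc})") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name)
    return {
        "name": name, "resname": resname, "chain": chain, "resid": resid,
        "xyz": (x, y, z), "element": element.capitalize(),
        "hetatm": line.startswith("HETATM"),
    }


_MONOATOMIC_IONS = {"NA", "CL", "K", "MG", "CA", "ZN", "FE", "MN", "BR", "I"}


def _segment_for(record: dict, segment_map: Mapping[str, Segment | str]) -> Segment:
    chain = record["chain"]
    if chain in segment_map:
        seg = segment_map[chain]
        return Segment(seg)
    if record["resname"] in ("HOH", "WAT", "TIP3"):
        return Segment.SOLVENT
    if record["hetatm"] and record["resname"].upper() in _MONOATOMIC_IONS:
        return Segment.ION
    raise SegmentMapError(
        f"chain {chain!r} (residue {record['resname']}) not covered by segment_map"
    )


def load_topology(
    pdb_text: str, segment_map: Mapping[str, Segment | str]
) -> tuple[Topology, np.ndarray]:
    """Parse the first MODEL of PDB text into a Topology plus coordinates.

    Parameters
    ----------
    pdb_text:
        PDB-format text with at least one ATOM/HETATM record.
    segment_map:
        chain_id -> segment for every chain present.  Unmapped chains fall
        back to solvent (waters) or ion (monoatomic HETATM); anything else
        raises :class:`SegmentMapError`.

    Returns
    -------
    (topology, coordinates) where coordinates has shape (n_atoms, 3) in A.
    """
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    seen: set[tuple[str, int, str]] = set()
    in_model = 0
    for line_number, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model += 1
            if in_model > 1:
                break
        elif rec == "ENDMDL":
            break
        elif rec in ("ATOM", "HETATM"):
            record = _parse_atom_record(line, line_number)
            key = (record["chain"], record["resid"], record["name"])
            if key in seen:
                raise DuplicateAtomError(
                    f"duplicate atom {record['name']!r} in "
                    f"{record['resname']} {record['resid']} chain {record['chain']!r}"
                )
            seen.add(key)
            atoms.append(
                Atom(
                    index=len(atoms),
                    name=record["name"],
                    element=record["element"],
                    residue_id=record["resid"],
                    residue_name=record["resname"],
                    chain_id=record["chain"],
                    segment=_segment_for(record, segment_map),
                )
            )
            coords.append(record["xyz"])
    if not atoms:
        raise PDBParseError(0, "no ATOM/HETATM records found")
    return Topology(atoms), np.array(coords)


# ---------------------------------------------------------------------------
# Trajectory reading
# ---------------------------------------------------------------------------

def _read_multi_model_pdb(text: str, n_atoms: int) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] = []
    saw_model = False
    for line_number, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            current = []
        elif rec == "ENDMDL":
            frames.append(np.array(current))
            current = []
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_atom_record(line, line_number)["xyz"])
    if not saw_model and current:
        frames.append(np.array(current))
        current = []
    if current:
        if len(current) == n_atoms:
            frames.append(np.array(current))
        else:
            import warnings

            warnings.warn("dropping truncated final frame", stacklevel=3)
    return frames


def _read_extended_xyz(text: str, n_atoms: int) -> tuple[list[np.ndarray], list[float] | None]:
    lines = text.splitlines()
    frames: list[np.ndarray] = []
    times: list[float] = []
    have_times = True
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        count = int(lines[i].strip())
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        match = re.search(r"time_ns=([-+0-9.eE]+)", comment)
        if match:
            times.append(float(match.group(1)))
        else:
            have_times = False
        body = lines[i + 2 : i + 2 + count]
        if len(body) < count:
            import warnings

            warnings.warn("dropping truncated final frame", stacklevel=3)
            break
        frame = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in body]
        )
        frames.append(frame)
        i += 2 + count
    return frames, (times if have_times and len(times) == len(frames) else None)


def load_trajectory(
    source: str | Path,
    topology: Topology,
    stride: int = 1,
    time_step_ns: float = 0.1,
) -> Trajectory:
    """Read a trajectory from multi-model PDB, extended XYZ, or DCD.

    ``times`` are read from the file when the format carries them (extended
    XYZ ``time_ns=`` comments), otherwise synthesised as
    ``frame_index * time_step_ns`` **before** striding, so a strided
    trajectory keeps the original clock.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    path = Path(source)
    suffix = path.suffix.lower()
    times: list[float] | None = None
    if suffix == ".dcd":
        import mdtraj

        dummy = mdtraj.Topology()
        ch = dummy.add_chain()
        res = dummy.add_residue("DUM", ch)
        for atom in topology.atoms:
            dummy.add_atom(atom.name, mdtraj.element.carbon, res)
        traj = mdtraj.load_dcd(str(path), top=dummy)
        frames = [np.asarray(f, dtype=float) * 10.0 for f in traj.xyz]  # nm -> A
    elif suffix == ".xyz":
        frames, times = _read_extended_xyz(path.read_text(), topology.n_atoms)
    else:
        frames = _read_multi_model_pdb(path.read_text(), topology.n_atoms)
    for f in frames:
        if f.shape != (topology.n_atoms, 3):
            raise ShapeError(
                f"frame has {f.shape[0]} atoms, topology has {topology.n_atoms}"
            )
    if times is None:
        times = [i * time_step_ns for i in range(len(frames))]
    coords = np.array(frames)[::stride]
    return Trajectory(topology, coords, np.array(times)[::stride])


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _pdb_atom_line(atom: Atom, xyz: np.ndarray, serial: int) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    record = "HETATM" if atom.segment in (Segment.LIGAND, Segment.ION) else "ATOM  "
    return (
        f"{record}{serial:>5d} {name:<4.4s} {atom.residue_name:<4.4s}"
        f"{atom.chain_id:1.1s}{atom.residue_id:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2.2s}"
    )


def write_topology_pdb(topology: Topology, coordinates: np.ndarray) -> str:
    """Render topology + one coordinate set as PDB text."""
    lines = [
        _pdb_atom_line(atom, coordinates[atom.index], atom.index + 1)
        for atom in topology.atoms
    ]
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_trajectory_pdb(traj: Trajectory) -> str:
    """Render a trajectory as multi-model PDB text."""
    parts = []
    for m in range(traj.n_frames):
        parts.append(f"MODEL     {m + 1:>4d}")
        for atom in traj.topology.atoms:
            parts.append(
                _pdb_atom_line(atom, traj.coordinates[m, atom.index], atom.index + 1)
            )
        parts.append("ENDMDL")
    parts.append("END")
    return "\n".join(parts) + "\n"


def write_trajectory_xyz(traj: Trajectory) -> str:
    """Render a trajectory as extended XYZ with time_ns comments."""
    parts = []
    for m in range(traj.n_frames):
        parts.append(str(traj.topology.n_atoms))
        parts.append(f"time_ns={traj.times[m]:.6f}")
        for atom in traj.topology.atoms:
            x, y, z = traj.coordinates[m, atom.index]
            parts.append(f"{atom.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# Acyl-chain CH2/CH3 grouping
# ---------------------------------------------------------------------------

def _hydrogens_for_carbon(carbon_name: str, ligand_atoms: list[Atom]) -> list[Atom]:
    number = re.search(r"(\d+)\'*$", carbon_name)
    if number is None:
        raise GroupingError(f"carbon name {carbon_name!r} carries no number")
    prime = "'" * carbon_name.count("'")
    pattern = re.compile(rf"^[hH]{number.group(1)}{re.escape(prime)}[a-zA-Z]*$")
    return [a for a in ligand_atoms if a.element.upper() == "H" and pattern.match(a.name)]


def assign_acyl_groups(
    topology: Topology, chain_spec: Mapping[str, Sequence[str]]
) -> Topology:
    """Label every acyl-chain atom with its CH2/CH3 group.

    ``chain_spec`` maps a chain label (``"F1"``, ``"F2"``) to the ordered
    carbon names of that chain (e.g. ``["c2", "c3", "c4"]``).  Hydrogens are
    associated to their carbon by the ``cN`` -> ``hNa/hNb/...`` naming
    convention.  Every non-terminal carbon must carry exactly 2 hydrogens
    (CH2) and the terminal carbon 3 (CH3); pseudo-hydrogen-free toy systems
    may carry 0, which is accepted and labelled the same way.
    """
    ligand_atoms = [a for a in topology.atoms if a.segment == Segment.LIGAND]
    by_name = {a.name: a for a in ligand_atoms}
    for chain_label, carbons in chain_spec.items():
        for pos, carbon_name in enumerate(carbons):
            carbon = by_name.get(carbon_name)
            if carbon is None:
                raise GroupingError(
                    f"carbon {carbon_name!r} of chain {chain_label} not in ligand"
                )
            hydrogens = _hydrogens_for_carbon(carbon_name, ligand_atoms)
            terminal = pos == len(carbons) - 1
            expected = 3 if terminal else 2
            if hydrogens and len(hydrogens) != expected:
                raise GroupingError(
                    f"carbon {carbon_name!r}: found {len(hydrogens)} hydrogens, "
                    f"expected {expected} ({'CH3' if terminal else 'CH2'})"
                )
            number = re.search(r"(\d+)", carbon_name).group(1)
            label = f"{chain_label}:CH{number}"
            carbon.group_label = label
            for h in hydrogens:
                h.group_label = label
    return topology


def acyl_atom_order(
    topology: Topology, chain_spec_chain: Sequence[str]
) -> list[int]:
    """Atom indices in published map order: each carbon then its hydrogens."""
    ligand_atoms = [a for a in topology.atoms if a.segment == Segment.LIGAND]
    by_name = {a.name: a for a in ligand_atoms}
    order: list[int] = []
    for carbon_name in chain_spec_chain:
        order.append(by_name[carbon_name].index)
        hydrogens = _hydrogens_for_carbon(carbon_name, ligand_atoms)
        order.extend(a.index for a in sorted(hydrogens, key=lambda a: a.name))
    return order
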