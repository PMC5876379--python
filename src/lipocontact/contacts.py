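"""Distance-criterion contact detection and aggregation.

A *contact* is an atom pair — one atom from each selection — at Euclidean
distance <= cutoff (default 5 A, inclusive, matching the criterion used in
protein–glycolipid MD analyses).  Per-residue counts sum pairs rather than
using binary residue flags, which is what produces per-system totals far
above the residue count; a binary mode is available.

Two detection back ends are provided: a brute-force O(N^2) reference and a
cell-list accelerated search.  Both classify pairs from the same squared
distance arithmetic and return identical results bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Segment, Topology, Trajectory
from .errors import OverlappingSelectionError
from .selection import AtomSelection

__all__ = [
    "atom_pair_contacts",
    "contact_count_series",
    "contacts_by_residue",
    "residue_atom_contact_map",
    "contact_time_heatmap",
    "contact_lifetimes",
    "contact_ratio_table",
    "ContactLifetimeStats",
]



_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def residue_label(residue_name: str, residue_id: int) -> str:
    """Compact residue label like "L172", "F197"."""
    code = _ONE_LETTER.get(residue_name.upper(), residue_name[:1].upper())
    return f"{code}{residue_id}"


def _check_disjoint(sel_a: AtomSelection, sel_b: AtomSelection) -> None:
    if len(np.intersect1d(sel_a.indices, sel_b.indices)):
        raise OverlappingSelectionError(
            "contact selections overlap; a contact of an atom with itself is undefined"
        )


def _pairs_brute(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float
) -> np.ndarray:
    """All (i, j) local-index pairs with |a_i - b_j| <= cutoff, O(N^2)."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return np.empty((0, 2), dtype=np.intp)
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    sq = np.einsum("ijk,ijk->ij", diff, diff)
    ii, jj = np.nonzero(sq <= cutoff * cutoff)
    return np.column_stack([ii, jj])


def _pairs_cell_list(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float
) -> np.ndarray:
    """Cell-list accelerated neighbour search, bit-identical to brute force.

    Atoms are binned into cubic cells of edge ``cutoff``; only the 27
    neighbouring cells of each occupied A-cell are examined, with the final
    distance test computed by exactly the same elementwise arithmetic as the
    brute-force path.
    """
    if len(coords_a) == 0 or len(coords_b) == 0:
        return np.empty((0, 2), dtype=np.intp)
    origin = np.minimum(coords_a.min(axis=0), coords_b.min(axis=0))
    cells_a = np.floor((coords_a - origin) / cutoff).astype(np.int64)
    cells_b = np.floor((coords_b - origin) / cutoff).astype(np.int64)

    bins_b: dict[tuple[int, int, int], list[int]] = {}
    for j, c in enumerate(map(tuple, cells_b)):
        bins_b.setdefault(c, []).append(j)
    bins_a: dict[tuple[int, int, int], list[int]] = {}
    for i, c in enumerate(map(tuple, cells_a)):
        bins_a.setdefault(c, []).append(i)

    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    out: list[np.ndarray] = []
    cut_sq = cutoff * cutoff
    for cell, ia in bins_a.items():
        jb: list[int] = []
        for off in offsets:
            jb.extend(bins_b.get((cell[0] + off[0], cell[1] + off[1], cell[2] + off[2]), ()))
        if not jb:
            continue
        ia_arr = np.array(ia, dtype=np.intp)
        jb_arr = np.array(jb, dtype=np.intp)
        diff = coords_a[ia_arr][:, None, :] - coords_b[jb_arr][None, :, :]
        sq = np.einsum("ijk,ijk->ij", diff, diff)
        ii, jj = np.nonzero(sq <= cut_sq)
        if len(ii):
            out.append(np.column_stack([ia_arr[ii], jb_arr[jj]]))
    if not out:
        return np.empty((0, 2), dtype=np.intp)
    pairs = np.concatenate(out)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def atom_pair_contacts(
    frame: np.ndarray,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    cutoff_A: float = 5.0,
    method: str = "cell_list",
) -> np.ndarray:
    """Contact pairs in one frame as an (n_pairs, 2) array of global indices.

    ``method`` is ``"cell_list"`` (default) or ``"brute"``; both give the
    same pairs, sorted by (index_a, index_b).
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff must be positive")
    _check_disjoint(sel_a, sel_b)
    coords_a = frame[sel_a.indices]
    coords_b = frame[sel_b.indices]
    finder = _pairs_cell_list if method == "cell_list" else _pairs_brute
    local = finder(coords_a, coords_b, cutoff_A)
    pairs = np.column_stack([sel_a.indices[local[:, 0]], sel_b.indices[local[:, 1]]])
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def _per_frame_pairs(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    cutoff_A: float,
    method: str = "cell_list",
):
    for m in range(traj.n_frames):
        yield atom_pair_contacts(traj.coordinates[m], sel_a, sel_b, cutoff_A, method)


def contact_count_series(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    cutoff_A: float = 5.0,
) -> dict:
    """Per-frame total contact-pair counts with mean and population SD."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    counts = np.array(
        [len(p) for p in _per_frame_pairs(traj, sel_a, sel_b, cutoff_A)], dtype=float
    )
    return {
        "counts": counts,
        "mean": float(counts.mean()),
        "sd": float(counts.std()),  # population SD, uniform frame weights
    }


def _protein_residue_keys(topology: Topology) -> list[tuple[str, int, str]]:
    return topology.residues(Segment.PROTEIN)


def _residue_of_atom(topology: Topology) -> np.ndarray:
    """Dense atom-index -> protein-residue row (or -1) lookup."""
    keys = _protein_residue_keys(topology)
    row_of = {(c, r): k for k, (c, r, _) in enumerate(keys)}
    lookup = np.full(topology.n_atoms, -1, dtype=np.intp)
    for atom in topology.atoms:
        if atom.segment == Segment.PROTEIN:
            lookup[atom.index] = row_of[(atom.chain_id, atom.residue_id)]
    return lookup


def contacts_by_residue(
    traj: Trajectory,
    ligand_sel: AtomSelection,
    cutoff_A: float = 5.0,
    protein_sel: AtomSelection | None = None,
    binary: bool = False,
) -> pd.DataFrame:
    """Mean +/- SD contact count per protein residue.

    Rows are every protein residue in topology order — zero rows are kept,
    as they are meaningful in per-residue bar plots.  ``binary`` counts a
    residue as 0/1 per frame instead of summing its atom pairs.
    """
    if len(ligand_sel) == 0:
        raise ValueError("ligand selection is empty")
    topology = traj.topology
    if protein_sel is None:
        protein_sel = AtomSelection(
            topology, topology.indices(Segment.PROTEIN), "segment protein"
        )
    keys = _protein_residue_keys(topology)
    lookup = _residue_of_atom(topology)
    per_frame = np.zeros((traj.n_frames, len(keys)))
    for m, pairs in enumerate(_per_frame_pairs(traj, protein_sel, ligand_sel, cutoff_A)):
        if len(pairs) == 0:
            continue
        rows = lookup[pairs[:, 0]]
        counts = np.bincount(rows[rows >= 0], minlength=len(keys)).astype(float)
        per_frame[m] = (counts > 0) if binary else counts
    return pd.DataFrame(
        {
            "chain": [c for c, _, _ in keys],
            "residue_id": [r for _, r, _ in keys],
            "residue_name": [n for _, _, n in keys],
            "label": [residue_label(n, r) for _, r, n in keys],
            "mean": per_frame.mean(axis=0),
            "sd": per_frame.std(axis=0),
        }
    )


def residue_atom_contact_map(
    traj: Trajectory,
    ligand_atom_order: list[int],
    cutoff_A: float = 5.0,
) -> pd.DataFrame:
    """Per-frame mean contacts, protein residue x ordered ligand atom.

    ``ligand_atom_order`` fixes the column layout in the published-map
    convention (each carbon followed by its hydrogens); every listed atom
    must carry a group label from :func:`core.assign_acyl_groups`.
    """
    topology = traj.topology
    for i in ligand_atom_order:
        if topology.atoms[i].group_label is None:
            raise ValueError(f"ligand atom {topology.atoms[i].name!r} is unlabeled")
    ligand_sel = AtomSelection(topology, np.array(ligand_atom_order), "acyl chain")
    protein_sel = AtomSelection(
        topology, topology.indices(Segment.PROTEIN), "segment protein"
    )
    keys = _protein_residue_keys(topology)
    lookup = _residue_of_atom(topology)
    col_of = {atom_idx: c for c, atom_idx in enumerate(ligand_atom_order)}
    acc = np.zeros((len(keys), len(ligand_atom_order)))
    for pairs in _per_frame_pairs(traj, protein_sel, ligand_sel, cutoff_A):
        for i, j in pairs:
            row = lookup[i]
            if row >= 0:
                acc[row, col_of[j]] += 1
    acc /= traj.n_frames
    row_labels = [residue_label(n, r) for _, r, n in keys]
    col_labels = [topology.atoms[i].name for i in ligand_atom_order]
    return pd.DataFrame(acc, index=row_labels, columns=col_labels)


def contact_time_heatmap(
    traj: Trajectory,
    ligand_sel: AtomSelection,
    window_ns: float = 1.0,
    cutoff_A: float = 5.0,
) -> pd.DataFrame:
    """Mean per-frame contacts, protein residue x time window.

    The last partial window is retained; its label carries a ``*``.  The
    DataFrame's ``attrs["partial_windows"]`` lists partial column indices.
    """
    spacing = traj.frame_spacing_ns
    if window_ns < spacing:
        raise ValueError("window must be at least one frame spacing")
    per_res = _contacts_by_residue_frames(traj, ligand_sel, cutoff_A)
    t0 = traj.times[0]
    window_idx = np.floor((traj.times - t0) / window_ns).astype(int)
    n_windows = window_idx.max() + 1
    full_frames = int(round(window_ns / spacing))
    cols = []
    partial = []
    for w in range(n_windows):
        members = window_idx == w
        cols.append(per_res[members].mean(axis=0))
        if members.sum() < full_frames:
            partial.append(w)
    keys = _protein_residue_keys(traj.topology)
    labels = [
        f"{(w * window_ns + t0):.3f}" + ("*" if w in partial else "")
        for w in range(n_windows)
    ]
    df = pd.DataFrame(
        np.column_stack(cols),
        index=[residue_label(n, r) for _, r, n in keys],
        columns=labels,
    )
    df.attrs["partial_windows"] = partial
    return df


def _contacts_by_residue_frames(
    traj: Trajectory, ligand_sel: AtomSelection, cutoff_A: float
) -> np.ndarray:
    """(n_frames, n_protein_residues) pair-count matrix."""
    topology = traj.topology
    protein_sel = AtomSelection(
        topology, topology.indices(Segment.PROTEIN), "segment protein"
    )
    keys = _protein_residue_keys(topology)
    lookup = _residue_of_atom(topology)
    out = np.zeros((traj.n_frames, len(keys)))
    for m, pairs in enumerate(_per_frame_pairs(traj, protein_sel, ligand_sel, cutoff_A)):
        if len(pairs):
            rows = lookup[pairs[:, 0]]
            out[m] = np.bincount(rows[rows >= 0], minlength=len(keys))
    return out


# ---------------------------------------------------------------------------
# Contact lifetimes
# ---------------------------------------------------------------------------

@dataclass
class ContactLifetimeStats:
    """Lifetime statistics of contact events.

    An event is a maximal run of contact-positive frames for an entity
    (a residue, or a single atom pair), allowing interruptions of at most
    ``gap_tolerance_frames``; its span runs first-to-last contact-positive
    frame inclusive.
    """

    level: str
    gap_tolerance_frames: int
    frame_spacing_ns: float
    events: list[tuple[int, int]]  # (start_frame, end_frame) inclusive
    entity_of_event: list[object] = field(default_factory=list)

    @property
    def event_lengths_frames(self) -> np.ndarray:
        return np.array([e - s + 1 for s, e in self.events], dtype=float)

    @property
    def mean_lifetime_frames(self) -> float:
        lengths = self.event_lengths_frames
        return float(lengths.mean()) if len(lengths) else float("nan")

    @property
    def mean_lifetime_ns(self) -> float:
        return self.mean_lifetime_frames * self.frame_spacing_ns

    def histogram(self, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.event_lengths_frames * self.frame_spacing_ns, bins=bins)


def _events_from_bool(series: np.ndarray, gap: int) -> list[tuple[int, int]]:
    positive = np.flatnonzero(series)
    if len(positive) == 0:
        return []
    events = []
    start = prev = positive[0]
    for f in positive[1:]:
        if f - prev - 1 > gap:
            events.append((int(start), int(prev)))
            start = f
        prev = f
    events.append((int(start), int(prev)))
    return events


def contact_lifetimes(
    traj: Trajectory,
    ligand_sel: AtomSelection,
    level: str = "residue",
    gap_tolerance_frames: int = 0,
    cutoff_A: float = 5.0,
) -> ContactLifetimeStats:
    """Contact lifetimes at residue or atom-pair level.

    With ``gap_tolerance_frames = 0`` the summed event lengths equal the
    number of contact-positive frames, a conservation property the tests
    rely on.
    """
    if gap_tolerance_frames < 0:
        raise ValueError("gap tolerance must be >= 0")
    topology = traj.topology
    events: list[tuple[int, int]] = []
    owners: list[object] = []
    if level == "residue":
        per_res = _contacts_by_residue_frames(traj, ligand_sel, cutoff_A) > 0
        keys = _protein_residue_keys(topology)
        for k, (_, rid, name) in enumerate(keys):
            for ev in _events_from_bool(per_res[:, k], gap_tolerance_frames):
                events.append(ev)
                owners.append(residue_label(name, rid))
    elif level == "atom_pair":
        protein_sel = AtomSelection(
            topology, topology.indices(Segment.PROTEIN), "segment protein"
        )
        on: dict[tuple[int, int], np.ndarray] = {}
        for m, pairs in enumerate(
            _per_frame_pairs(traj, protein_sel, ligand_sel, cutoff_A)
        ):
            for i, j in pairs:
                on.setdefault((int(i), int(j)), np.zeros(traj.n_frames, bool))[m] = True
        for pair in sorted(on):
            for ev in _events_from_bool(on[pair], gap_tolerance_frames):
                events.append(ev)
                owners.append(pair)
    else:
        raise ValueError("level must be 'residue' or 'atom_pair'")
    return ContactLifetimeStats(
        level=level,
        gap_tolerance_frames=gap_tolerance_frames,
        frame_spacing_ns=traj.frame_spacing_ns,
        events=events,
        entity_of_event=owners,
    )


def contact_ratio_table(system_means: dict[str, float]) -> pd.DataFrame:
    """Square matrix of mean-contact ratios, cell (y, x) = mean(y)/mean(x).

    Mirrors the published lower-triangular 'Systems (y/x)' layout: the
    DataFrame is full, but :func:`reporting.write_tables` prints the lower
    triangle.
    """
    names = list(system_means)
    for name, mean in system_means.items():
        if mean <= 0:
            raise ValueError(f"system {name!r} has non-positive mean contact count")
    values = np.array([system_means[n] for n in names])
    matrix = values[:, None] / values[None, :]
    return pd.DataFrame(matrix, index=names, columns=names)
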