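"""Rigid-body superposition, RMSF, groove-width distances, radius of gyration.

Superposition is the standard least-squares rigid fit (Kabsch, via SVD with
a determinant correction so the rotation is always proper).  RMSF uses the
mean structure as reference with one refinement pass: frames are first
fitted to frame 0, the mean is computed, and all frames are re-fitted to
that mean — the common convention when the reference is not stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Segment, Topology, Trajectory
from .errors import DegenerateFitError
from .selection import AtomSelection

__all__ = [
    "superpose",
    "apply_transform",
    "rmsf",
    "DistancePairSpec",
    "pair_distance_series",
    "radius_of_gyration",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")

# Default "most distal sidechain atoms" per residue type for groove-width
# distances; centroids are used when several atoms are listed.
DEFAULT_DISTAL_ATOMS = {
    "PHE": ["CZ"],
    "LEU": ["CD1", "CD2"],
    "VAL": ["CG1", "CG2"],
    "ILE": ["CD1"],
    "ALA": ["CB"],
}


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` minimises the RMSD over the fit
    atoms.  Requires >= 3 non-collinear fit atoms.
    """
    if fit_indices is None:
        fit_indices = np.arange(len(mobile))
    a = np.asarray(mobile, float)[fit_indices]
    b = np.asarray(reference, float)[fit_indices]
    if len(a) < 3:
        raise DegenerateFitError("need at least 3 fit atoms")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # Collinearity check: a rank-<2 centered cloud cannot fix the rotation.
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear or coincident")
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cb - rotation @ ca
    fitted = a @ rotation.T + translation
    rmsd = float(np.sqrt(((fitted - b) ** 2).sum(axis=1).mean()))
    return rotation, translation, rmsd


def apply_transform(
    coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray
) -> np.ndarray:
    return coords @ rotation.T + translation


def _fit_all(
    coords: np.ndarray, reference: np.ndarray, fit_indices: np.ndarray
) -> np.ndarray:
    out = np.empty_like(coords)
    for m in range(coords.shape[0]):
        rot, trans, _ = superpose(coords[m], reference, fit_indices)
        out[m] = apply_transform(coords[m], rot, trans)
    return out


def rmsf(
    traj: Trajectory,
    target_sel: AtomSelection,
    fit_sel: AtomSelection | None = None,
    reference: str = "mean",
    per_residue_atoms: tuple[str, ...] = BACKBONE_NAMES,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-atom and per-residue (backbone-averaged) RMSF in A.

    ``reference = "mean"`` (default) superposes all frames on the mean
    structure with one refinement pass; ``"frame0"`` fits to the first
    frame only.  RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2).  The per-residue
    value averages the atoms named in ``per_residue_atoms`` (backbone
    N/CA/C/O by default; pass ("CA",) for a Calpha-only profile).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if fit_sel is None:
        fit_sel = target_sel
    coords = traj.coordinates
    fitted = _fit_all(coords, coords[0], fit_sel.indices)
    if reference == "mean":
        mean_structure = fitted.mean(axis=0)
        fitted = _fit_all(coords, mean_structure, fit_sel.indices)
    elif reference != "frame0":
        raise ValueError("reference must be 'mean' or 'frame0'")
    mean_structure = fitted.mean(axis=0)
    dev = fitted - mean_structure
    per_atom_all = np.sqrt(np.einsum("mik,mik->i", dev, dev) / traj.n_frames)
    per_atom = per_atom_all[target_sel.indices]

    topology = traj.topology
    rows = []
    for chain, rid, name in topology.residues():
        members = [
            i
            for i in target_sel.indices
            if topology.atoms[i].residue_id == rid
            and topology.atoms[i].chain_id == chain
            and topology.atoms[i].name in per_residue_atoms
        ]
        if members:
            rows.append(
                {
                    "chain": chain,
                    "residue_id": rid,
                    "residue_name": name,
                    "rmsf": float(per_atom_all[members].mean()),
                }
            )
    return per_atom, pd.DataFrame(rows)


@dataclass
class DistancePairSpec:
    """A residue pair whose separation tracks the hydrophobic-groove width.

    ``mode = "calpha"`` measures Calpha–Calpha; ``"distal_sidechain"``
    measures the distance between per-residue distal points (the centroid
    of the configured terminal heavy atoms, e.g. CZ for Phe, CD1/CD2 for
    Leu, CG1/CG2 for Val).
    """

    residue_a: int
    residue_b: int
    mode: str = "calpha"
    distal_atoms: dict[str, list[str]] = field(
        default_factory=lambda: dict(DEFAULT_DISTAL_ATOMS)
    )


def _residue_point_indices(
    topology: Topology, residue_id: int, spec: DistancePairSpec
) -> list[int]:
    atoms = [a for a in topology.atoms if a.residue_id == residue_id]
    if not atoms:
        raise ValueError(f"residue {residue_id} not in topology")
    if spec.mode == "calpha":
        names = ["CA"]
    else:
        resname = atoms[0].residue_name.upper()
        names = spec.distal_atoms.get(resname)
        if not names:
            raise ValueError(f"no distal atoms configured for {resname}")
    members = [a.index for a in atoms if a.name in names]
    if not members:
        raise ValueError(
            f"residue {residue_id} ({atoms[0].residue_name}) lacks atoms {names}"
        )
    return members


def pair_distance_series(traj: Trajectory, spec: DistancePairSpec) -> pd.DataFrame:
    """Per-frame distance (A) between the two residue points of ``spec``."""
    ia = _residue_point_indices(traj.topology, spec.residue_a, spec)
    ib = _residue_point_indices(traj.topology, spec.residue_b, spec)
    pa = traj.coordinates[:, ia].mean(axis=1)
    pb = traj.coordinates[:, ib].mean(axis=1)
    dist = np.linalg.norm(pa - pb, axis=1)
    return pd.DataFrame({"time_ns": traj.times, "distance_A": dist})


def radius_of_gyration(
    traj: Trajectory, sel: AtomSelection, mass_weighted: bool = True
) -> pd.DataFrame:
    """Rg(t) = sqrt(sum_i m_i |x_i - x_com|^2 / sum_i m_i), per frame."""
    if len(sel) == 0:
        raise ValueError("empty selection")
    weights = (
        traj.topology.masses(sel.indices)
        if mass_weighted
        else np.ones(len(sel.indices))
    )
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    coords = traj.coordinates[:, sel.indices]
    com = np.einsum("mik,i->mk", coords, weights) / total
    dev = coords - com[:, None, :]
    rg = np.sqrt(np.einsum("mik,mik,i->m", dev, dev, weights) / total)
    return pd.DataFrame({"time_ns": traj.times, "rg_A": rg})
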