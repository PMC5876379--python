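"""Toy receptor–ligand systems with analytically known statistics.

The generator emulates, at bead resolution, the situation the pipeline is
built for: a rigid receptor bearing a hydrophobic groove lined by four key
residues (numbered 172/173/197/198 to echo the Mincle L172/V173/F197/F198
groove) and a ligand with a fixed anchor plus one or two flexible acyl
chains of 4–18 beads at aliphatic C–C bond length (1.53 A).  Chain
statistics — per-bead contact probabilities, contact lifetimes, end-to-end
distances, interaction energies — are known in closed form or by brute
force, so every analysis stage can be checked for parameter recovery
without running MD.

Dynamics modes
--------------
``uniform_bead``
    a single ligand bead uniform in a cubic box holding one receptor atom;
    the per-frame contact probability is the sphere/box volume ratio.
``freely_jointed_resample``
    i.i.d. freely-jointed-chain conformations anchored at the attachment
    point; <R^2> = n * b^2.
``two_state_schedule``
    alternates an "in-groove" and a "solvent" conformer pool with
    switching probability p per frame; the in-groove pool guarantees a
    contact with key residue 172, so that residue's mean contact lifetime
    is geometric with mean 1/p frames.
``metropolis_mc``
    seeded pivot moves with hard-core self/receptor avoidance and an
    optional Lennard-Jones attraction to the groove atoms; no closed form,
    ground truth comes from an independent long-run reference.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    Atom,
    Segment,
    Topology,
    Trajectory,
    assign_acyl_groups,
    write_topology_pdb,
    write_trajectory_pdb,
    write_trajectory_xyz,
)
from .errors import FrozenChainError, InfeasibleGeometryError

__all__ = [
    "SyntheticSystemSpec",
    "GroundTruth",
    "build_toy_system",
    "sample_chain_trajectory",
    "ground_truth",
    "write_fixture",
    "chain_atom_names",
]

KEY_RESIDUE_NAMES = {172: "LEU", 173: "VAL", 197: "PHE", 198: "PHE"}


@dataclass
class SyntheticSystemSpec:
    """Full parameterization of the toy generator (lengths in A, times ns)."""

    chains: tuple[int, ...] = (4,)  # beads per acyl chain (F1[, F2])
    bond_length: float = 1.53
    dynamics: str = "freely_jointed_resample"
    n_frames: int = 1000
    frame_spacing_ns: float = 0.1
    rng_seed: int = 0
    # receptor groove geometry
    ridge_separation: float = 10.0
    ridge_length: int = 8
    bead_spacing: float = 3.8
    anchor_height: float = 4.0
    hard_core: float = 1.0
    # mode-specific knobs
    box_size: float = 20.0  # uniform_bead
    switching_prob: float = 0.1  # two_state_schedule
    pool_size: int = 64  # two_state_schedule conformer pools
    contact_cutoff: float = 5.0
    potential: dict | None = None  # {"epsilon": kcal/mol, "rmin_half": A, "kT": ...}
    moves_per_frame: int | None = None  # metropolis_mc; default = n beads
    pseudo_hydrogens: bool = False

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.chains):
            raise ValueError("bead counts must be >= 1")
        if len(self.chains) > 2:
            raise ValueError("at most two acyl chains (F1, F2)")


def chain_atom_names(spec: SyntheticSystemSpec) -> dict[str, list[str]]:
    """Chain label -> ordered bead (carbon) names; F2 beads carry a prime."""
    out = {}
    for k, n in enumerate(spec.chains):
        prime = "'" * k
        out[f"F{k + 1}"] = [f"c{i + 1}{prime}" for i in range(n)]
    return out


def _receptor_atoms(spec: SyntheticSystemSpec) -> tuple[list[Atom], list[np.ndarray]]:
    if spec.dynamics == "uniform_bead":
        center = np.full(3, spec.box_size / 2.0)
        if spec.box_size / 2.0 < spec.contact_cutoff:
            raise InfeasibleGeometryError(
                "box too small: receptor atom closer than the cutoff to a wall"
            )
        atom = Atom(0, "CA", "C", 1, "ALA", "A", Segment.PROTEIN)
        return [atom], [center]
    if spec.ridge_separation <= 2.0 * spec.hard_core:
        raise InfeasibleGeometryError(
            "ridge separation must exceed the bead diameter"
        )
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    half = spec.ridge_separation / 2.0
    x0 = -(spec.ridge_length - 1) * spec.bead_spacing / 2.0
    ridge_ids = [range(170, 170 + spec.ridge_length), range(193, 193 + spec.ridge_length)]
    for ridge, (ids, y) in enumerate(zip(ridge_ids, (-half, half))):
        for j, rid in enumerate(ids):
            name = KEY_RESIDUE_NAMES.get(rid, "ALA")
            atoms.append(
                Atom(len(atoms), "CA", "C", rid, name, "A", Segment.PROTEIN)
            )
            coords.append(np.array([x0 + j * spec.bead_spacing, y, 0.0]))
    return atoms, coords


def build_toy_system(spec: SyntheticSystemSpec) -> tuple[Topology, np.ndarray]:
    """Deterministic topology + initial coordinates for a spec.

    Receptor pseudo-residues are CA beads on two parallel ridges; the four
    key residues carry their Mincle-groove numbers and residue names.
    Ligand chains are beads c1..cn (F2: c1'..cn') in chain "L", anchored at
    a fixed attachment point above the groove centre, and labelled with
    CH2/CH3-style group labels.
    """
    atoms, coords = _receptor_atoms(spec)
    if spec.dynamics == "uniform_bead":
        anchor = np.full(3, spec.box_size / 2.0) + np.array([6.0, 0.0, 0.0])
    else:
        anchor = np.array([0.0, 0.0, spec.anchor_height])
    names = chain_atom_names(spec)
    for k, (label, bead_names) in enumerate(names.items()):
        resid = 901 + k
        for i, bead in enumerate(bead_names):
            atoms.append(
                Atom(len(atoms), bead, "C", resid, "LIG", "L", Segment.LIGAND)
            )
            # initial conformation: straight chain along +x from the anchor
            coords.append(anchor + np.array([(i + 1) * spec.bond_length, 0.0, 0.0]))
    topology = Topology(atoms)
    assign_acyl_groups(topology, names)
    coords = np.array(coords)
    if spec.pseudo_hydrogens:
        topology, coords = add_pseudo_hydrogens(spec, topology, coords)
    return topology, coords


_H_OFFSETS = (
    np.array([0.0, 0.7, 0.7]),
    np.array([0.0, -0.7, 0.7]),
    np.array([0.0, 0.0, -1.0]),
)


def add_pseudo_hydrogens(
    spec: SyntheticSystemSpec, topology: Topology, coords: np.ndarray
) -> tuple[Topology, np.ndarray]:
    """Attach 2 (CH2) or 3 (terminal CH3) pseudo-hydrogens to every bead.

    Hydrogens ride rigidly on their carbon at fixed offsets, which is all
    the contact-map layout tests need.
    """
    names = chain_atom_names(spec)
    atoms = list(topology.atoms)
    new_coords = list(coords)
    for label, bead_names in names.items():
        for pos, bead in enumerate(bead_names):
            carbon = next(a for a in atoms if a.name == bead)
            n_h = 3 if pos == len(bead_names) - 1 else 2
            prime = "'" * bead.count("'")
            number = bead.strip("c'")
            for h in range(n_h):
                atoms.append(
                    Atom(
                        len(atoms),
                        f"h{number}{prime}{'abc'[h]}",
                        "H",
                        carbon.residue_id,
                        "LIG",
                        "L",
                        Segment.LIGAND,
                    )
                )
                new_coords.append(coords[carbon.index] + _H_OFFSETS[h])
    # rebuild so indices stay contiguous
    rebuilt = Topology(
        [dataclasses.replace(a, index=i, lj_key=None) for i, a in enumerate(atoms)]
    )
    assign_acyl_groups(rebuilt, names)
    return rebuilt, np.array(new_coords)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _fjc_conformation(
    rng: np.random.Generator, anchor: np.ndarray, n: int, b: float
) -> np.ndarray:
    bonds = _random_unit_vectors(rng, n) * b
    return anchor + np.cumsum(bonds, axis=0)


def _ligand_layout(spec: SyntheticSystemSpec, topology: Topology):
    """Carbon bead indices per chain + hydrogen (index, parent, offset) list."""
    names = chain_atom_names(spec)
    by_name = {a.name: a.index for a in topology.atoms}
    chain_beads = {label: [by_name[n] for n in beads] for label, beads in names.items()}
    hydrogens = []
    if spec.pseudo_hydrogens:
        for label, beads in names.items():
            for pos, bead in enumerate(beads):
                n_h = 3 if pos == len(beads) - 1 else 2
                prime = "'" * bead.count("'")
                number = bead.strip("c'")
                for h in range(n_h):
                    hydrogens.append(
                        (by_name[f"h{number}{prime}{'abc'[h]}"], by_name[bead], _H_OFFSETS[h])
                    )
    return chain_beads, hydrogens


def _place_ligand(
    frame: np.ndarray,
    chain_beads: dict[str, list[int]],
    hydrogens,
    conformations: dict[str, np.ndarray],
) -> None:
    for label, conf in conformations.items():
        frame[chain_beads[label]] = conf
    placed = {i for label in conformations for i in chain_beads[label]}
    for idx, parent, offset in hydrogens:
        if parent in placed:
            frame[idx] = frame[parent] + offset


def _chain_anchor(spec: SyntheticSystemSpec, label: str) -> np.ndarray:
    """Attachment point per chain; F2 attaches on the far side of the scaffold."""
    base = np.array([0.0, 0.0, spec.anchor_height])
    if label == "F2":
        base = base + np.array([2.0 * spec.bond_length, 0.0, 0.0])
    return base


def _two_state_pools(
    spec: SyntheticSystemSpec,
    rng: np.random.Generator,
    anchor: np.ndarray,
    receptor_coords: np.ndarray,
    key_coords: np.ndarray,
    n_beads: int,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Conformer pools: 'in' guarantees a key-172 contact, 'out' none at all."""
    target = key_coords[0]  # residue 172's bead
    in_pool: list[np.ndarray] = []
    out_pool: list[np.ndarray] = []
    budget = 200_000
    while (len(in_pool) < spec.pool_size or len(out_pool) < spec.pool_size) and budget:
        budget -= 1
        conf = _fjc_conformation(rng, anchor, n_beads, spec.bond_length)
        d_target = np.linalg.norm(conf - target, axis=1).min()
        d_all = np.linalg.norm(
            conf[:, None, :] - receptor_coords[None, :, :], axis=2
        ).min()
        if d_target <= spec.contact_cutoff - 0.5 and len(in_pool) < spec.pool_size:
            in_pool.append(conf)
        elif d_all > spec.contact_cutoff + 1.0 and len(out_pool) < spec.pool_size:
            # push clearly into solvent so no receptor atom is in contact
            out_pool.append(conf + np.array([0.0, 0.0, 30.0]))
    if len(in_pool) < spec.pool_size or len(out_pool) < spec.pool_size:
        raise InfeasibleGeometryError(
            "could not populate two-state conformer pools; chain too short to "
            "reach the groove from the anchor"
        )
    return in_pool, out_pool


def _lj_energy_to_receptor(
    conf: np.ndarray, receptor_coords: np.ndarray, eps: float, rmin: float
) -> float:
    d2 = ((conf[:, None, :] - receptor_coords[None, :, :]) ** 2).sum(axis=2)
    x6 = (rmin * rmin / d2) ** 3
    return float((eps * (x6 * x6 - 2.0 * x6)).sum())


def _hard_core_ok(
    conf: np.ndarray, receptor_coords: np.ndarray, hard_core: float
) -> bool:
    d_rec = ((conf[:, None, :] - receptor_coords[None, :, :]) ** 2).sum(axis=2)
    if (d_rec < hard_core * hard_core).any():
        return False
    if len(conf) > 2:
        d_self = ((conf[:, None, :] - conf[None, :, :]) ** 2).sum(axis=2)
        iu = np.triu_indices(len(conf), k=2)  # skip bonded neighbours
        if (d_self[iu] < hard_core * hard_core).any():
            return False
    return True


def sample_chain_trajectory(
    spec: SyntheticSystemSpec,
    n_frames: int | None = None,
    rng_seed: int | None = None,
) -> Trajectory:
    """Seeded stochastic trajectory over the toy system.

    Deterministic for a fixed spec/seed; the receptor is rigid in every
    mode.  See the module docstring for what each dynamics mode samples.
    """
    n_frames = spec.n_frames if n_frames is None else n_frames
    seed = spec.rng_seed if rng_seed is None else rng_seed
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    topology, coords0 = build_toy_system(spec)
    n_receptor = sum(1 for a in topology.atoms if a.segment == Segment.PROTEIN)
    receptor_coords = coords0[:n_receptor]
    chain_beads, hydrogens = _ligand_layout(spec, topology)
    frames = np.tile(coords0, (n_frames, 1, 1))

    if spec.dynamics == "uniform_bead":
        bead = chain_beads["F1"][0]
        frames[:, bead, :] = rng.uniform(0.0, spec.box_size, size=(n_frames, 3))
    elif spec.dynamics == "freely_jointed_resample":
        for m in range(n_frames):
            confs = {
                label: _fjc_conformation(
                    rng, _chain_anchor(spec, label), len(beads), spec.bond_length
                )
                for label, beads in chain_beads.items()
            }
            _place_ligand(frames[m], chain_beads, hydrogens, confs)
    elif spec.dynamics == "two_state_schedule":
        anchor = np.array([0.0, 0.0, spec.anchor_height])
        key_coords = np.array(
            [receptor_coords[i] for i, a in enumerate(topology.atoms[:n_receptor])
             if a.residue_id in KEY_RESIDUE_NAMES]
        )
        label = "F1"
        beads = chain_beads[label]
        in_pool, out_pool = _two_state_pools(
            spec, rng, anchor, receptor_coords, key_coords, len(beads)
        )
        state = True  # start in groove
        for m in range(n_frames):
            pool = in_pool if state else out_pool
            conf = pool[rng.integers(len(pool))]
            _place_ligand(frames[m], chain_beads, hydrogens, {label: conf})
            if rng.random() < spec.switching_prob:
                state = not state
    elif spec.dynamics == "metropolis_mc":
        pot = spec.potential or {}
        eps = float(pot.get("epsilon", 0.0))
        rmin = 2.0 * float(pot.get("rmin_half", 1.9))
        kT = float(pot.get("kT", 0.6))
        for label, beads in chain_beads.items():
            anchor = _chain_anchor(spec, label)
            n = len(beads)
            attempts = 0
            while True:
                bonds = _random_unit_vectors(rng, n)
                conf = anchor + np.cumsum(bonds * spec.bond_length, axis=0)
                if _hard_core_ok(conf, receptor_coords, spec.hard_core):
                    break
                attempts += 1
                if attempts >= 10_000:
                    raise FrozenChainError(
                        f"no valid starting conformation for chain {label} "
                        "in 10000 attempts"
                    )
            energy = (
                _lj_energy_to_receptor(conf, receptor_coords, eps, rmin) if eps else 0.0
            )
            moves = spec.moves_per_frame or n
            rejects = 0
            for m in range(n_frames):
                for _ in range(moves):
                    k = int(rng.integers(n))
                    axis = _random_unit_vectors(rng, 1)[0]
                    angle = rng.normal(0.0, 0.7)
                    rot = _axis_angle_matrix(axis, angle)
                    new_bonds = bonds.copy()
                    new_bonds[k:] = new_bonds[k:] @ rot.T
                    new_conf = anchor + np.cumsum(new_bonds * spec.bond_length, axis=0)
                    if not _hard_core_ok(new_conf, receptor_coords, spec.hard_core):
                        rejects += 1
                    else:
                        new_energy = (
                            _lj_energy_to_receptor(new_conf, receptor_coords, eps, rmin)
                            if eps
                            else 0.0
                        )
                        if new_energy <= energy or rng.random() < math.exp(
                            -(new_energy - energy) / kT
                        ):
                            bonds, conf, energy = new_bonds, new_conf, new_energy
                            rejects = 0
                        else:
                            rejects += 1
                    if rejects >= 10_000:
                        raise FrozenChainError(
                            f"no accepted move in 10000 attempts for chain {label}"
                        )
                _place_ligand(frames[m], chain_beads, hydrogens, {label: conf})
    else:
        raise ValueError(f"unknown dynamics mode {spec.dynamics!r}")

    times = np.arange(n_frames) * spec.frame_spacing_ns
    return Trajectory(topology, frames, times)


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    x, y, z = axis
    cc = 1.0 - c
    return np.array(
        [
            [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
            [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
            [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
        ]
    )


# ---------------------------------------------------------------------------
# Ground truth (independent of the pipeline under test)
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Expected statistics with standard errors; the test oracle.

    Closed-form entries carry ``se = 0``; Monte-Carlo references carry the
    sampling SE and ``empirical = True``.
    """

    contact_probability: float | None = None
    contact_probability_se: float = 0.0
    expected_mean_contacts: float | None = None
    expected_mean_lifetime_frames: float | None = None
    expected_mean_squared_end_to_end: dict[str, float] = field(default_factory=dict)
    per_group_energy: dict[str, float] = field(default_factory=dict)
    per_group_energy_se: dict[str, float] = field(default_factory=dict)
    empirical: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def ground_truth(
    spec: SyntheticSystemSpec,
    reference_samples: int = 100_000,
    rng_seed: int | None = None,
) -> GroundTruth:
    """Analytic or direct-sampling reference values for a spec.

    Computed by an independent path (closed forms, or a plain re-sampled
    reference for the Metropolis mode), never by the analysis pipeline.
    """
    if spec.dynamics == "uniform_bead":
        p = (4.0 / 3.0) * math.pi * spec.contact_cutoff**3 / spec.box_size**3
        return GroundTruth(contact_probability=p, expected_mean_contacts=p)
    if spec.dynamics == "freely_jointed_resample":
        r2 = {
            f"F{k + 1}": n * spec.bond_length**2 for k, n in enumerate(spec.chains)
        }
        return GroundTruth(expected_mean_squared_end_to_end=r2)
    if spec.dynamics == "two_state_schedule":
        return GroundTruth(
            expected_mean_lifetime_frames=1.0 / spec.switching_prob
        )
    if spec.dynamics == "metropolis_mc":
        ref = sample_chain_trajectory(
            dataclasses.replace(spec, n_frames=reference_samples),
            rng_seed=(spec.rng_seed + 1) if rng_seed is None else rng_seed,
        )
        # plain-python per-group energy reference (no pipeline code)
        pot = spec.potential or {}
        eps = float(pot.get("epsilon", 0.0))
        rmin = 2.0 * float(pot.get("rmin_half", 1.9))
        topo = ref.topology
        rec = [a.index for a in topo.atoms if a.segment == Segment.PROTEIN]
        groups: dict[str, list[int]] = {}
        for a in topo.atoms:
            if a.group_label:
                groups.setdefault(a.group_label, []).append(a.index)
        means, ses = {}, {}
        for g, members in groups.items():
            series = np.zeros(ref.n_frames)
            for m in range(ref.n_frames):
                total = 0.0
                for i in members:
                    for j in rec:
                        d2 = float(((ref.coordinates[m, i] - ref.coordinates[m, j]) ** 2).sum())
                        x6 = (rmin * rmin / d2) ** 3
                        total += eps * (x6 * x6 - 2.0 * x6)
                series[m] = total
            means[g] = float(series.mean())
            ses[g] = float(series.std(ddof=1) / math.sqrt(len(series)))
        return GroundTruth(
            per_group_energy=means, per_group_energy_se=ses, empirical=True
        )
    raise ValueError(f"no tractable reference for dynamics {spec.dynamics!r}")


def write_fixture(
    spec: SyntheticSystemSpec, out_dir: str | Path, fmt: str = "pdb"
) -> dict[str, Path]:
    """Write topology PDB, trajectory (PDB or XYZ) and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    topology, coords = build_toy_system(spec)
    traj = sample_chain_trajectory(spec)
    paths = {
        "topology": out / "topology.pdb",
        "trajectory": out / ("trajectory.pdb" if fmt == "pdb" else "trajectory.xyz"),
        "ground_truth": out / "ground_truth.json",
        "spec": out / "spec.json",
    }
    paths["topology"].write_text(write_topology_pdb(topology, coords))
    writer = write_trajectory_pdb if fmt == "pdb" else write_trajectory_xyz
    paths["trajectory"].write_text(writer(traj))
    try:
        truth = ground_truth(spec, reference_samples=spec.n_frames)
        paths["ground_truth"].write_text(truth.to_json())
    except ValueError:
        paths["ground_truth"].write_text("{}")
    paths["spec"].write_text(json.dumps(dataclasses.asdict(spec), indent=2, default=list))
    return paths
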