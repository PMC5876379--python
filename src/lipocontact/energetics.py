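"""Pairwise 12-6 Lennard-Jones interaction energies and decompositions.

The van der Waals energy between two atoms i, j at distance r is the
Amber-convention 12-6 form

    E(r) = eps_ij * [ (R_ij / r)^12 - 2 (R_ij / r)^6 ],

with Lorentz–Berthelot combining: eps_ij = sqrt(eps_i * eps_j) and
R_ij = rmin_half_i + rmin_half_j.  E has its minimum -eps_ij at r = R_ij
and crosses zero at R_ij / 2^(1/6).  Only inter-selection (cross) pairs are
summed — the selections are on different molecules, so no bonded or 1-4
exclusions apply — and by default no distance cutoff truncates the sum.
Electrostatics are deliberately out of scope: for apolar acyl chains the
LJ term is the meaningful affinity proxy.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import Topology, Trajectory
from .errors import MissingParameterError, OverlappingSelectionError
from .selection import AtomSelection

__all__ = [
    "LJParameterTable",
    "lj_pair_energy",
    "lj_interaction_energy",
    "energy_series_summary",
    "per_group_decomposition",
    "chain_length_fit",
    "ester_comparison_summary",
]


@dataclass
class LJParameterTable:
    """Per-atom epsilon (kcal/mol) and Rmin/2 (A), keyed by (residue, atom).

    A residue name of ``"*"`` acts as a wildcard fallback for that atom
    name.  Combining rule is Lorentz–Berthelot (the only one supported).
    """

    entries: dict[tuple[str, str], tuple[float, float]]
    combining_rule: str = "lorentz_berthelot"

    def __post_init__(self) -> None:
        for (res, atom), (eps, rh) in self.entries.items():
            if eps < 0:
                raise ValueError(f"negative epsilon for ({res}, {atom})")
            if rh <= 0:
                raise ValueError(f"non-positive rmin_half for ({res}, {atom})")

    @classmethod
    def from_tsv(cls, source: str | Path) -> "LJParameterTable":
        """Read columns residue_name, atom_name, epsilon_kcal_mol, rmin_half_A."""
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and "\t" not in source and "\n" not in source:
            text = Path(source).read_text()
        df = pd.read_csv(io.StringIO(text), sep="\t")
        entries = {
            (str(row.residue_name), str(row.atom_name)): (
                float(row.epsilon_kcal_mol),
                float(row.rmin_half_A),
            )
            for row in df.itertuples()
        }
        return cls(entries)

    def lookup(self, residue_name: str, atom_name: str) -> tuple[float, float]:
        for key in ((residue_name, atom_name), ("*", atom_name)):
            if key in self.entries:
                return self.entries[key]
        raise MissingParameterError(residue_name, atom_name)

    def arrays_for(
        self, topology: Topology, indices: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        eps = np.empty(len(indices))
        rh = np.empty(len(indices))
        for k, i in enumerate(indices):
            atom = topology.atoms[i]
            eps[k], rh[k] = self.lookup(*atom.lj_key)
        return eps, rh


def lj_pair_energy(
    r: float, eps_i: float, rmin_half_i: float, eps_j: float, rmin_half_j: float
) -> float:
    """12-6 LJ energy (kcal/mol) of one atom pair at distance r (A)."""
    if r <= 0:
        raise ValueError("distance must be positive")
    eps = np.sqrt(eps_i * eps_j)
    rmin = rmin_half_i + rmin_half_j
    x6 = (rmin / r) ** 6
    return float(eps * (x6 * x6 - 2.0 * x6))


def _cross_energy_matrix(
    frame: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    eps_a: np.ndarray,
    rh_a: np.ndarray,
    eps_b: np.ndarray,
    rh_b: np.ndarray,
    cutoff_A: float | None,
) -> np.ndarray:
    """(len(a), len(b)) matrix of pair energies, vectorized."""
    diff = frame[idx_a][:, None, :] - frame[idx_b][None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    eps = np.sqrt(eps_a[:, None] * eps_b[None, :])
    rmin = rh_a[:, None] + rh_b[None, :]
    x6 = (rmin * rmin / r2) ** 3
    energy = eps * (x6 * x6 - 2.0 * x6)
    if cutoff_A is not None:
        energy = np.where(r2 <= cutoff_A * cutoff_A, energy, 0.0)
    return energy


def lj_interaction_energy(
    frame: np.ndarray,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    params: LJParameterTable,
    cutoff_A: float | None = None,
) -> float:
    """Total LJ interaction energy (kcal/mol) between two disjoint selections."""
    if len(np.intersect1d(sel_a.indices, sel_b.indices)):
        raise OverlappingSelectionError("energy selections must be disjoint")
    topology = sel_a.topology
    eps_a, rh_a = params.arrays_for(topology, sel_a.indices)
    eps_b, rh_b = params.arrays_for(topology, sel_b.indices)
    matrix = _cross_energy_matrix(
        frame, sel_a.indices, sel_b.indices, eps_a, rh_a, eps_b, rh_b, cutoff_A
    )
    return float(matrix.sum())


def energy_series_summary(
    traj: Trajectory,
    chain_selections: dict[str, AtomSelection],
    protein_sel: AtomSelection,
    params: LJParameterTable,
    cutoff_A: float | None = None,
) -> pd.DataFrame:
    """Per-chain and total energy series with mean +/- population SD.

    ``chain_selections`` maps chain labels (``F1``, ``F2``) to ligand
    selections; the total row is the framewise sum of all chains.
    """
    series: dict[str, np.ndarray] = {}
    for label, sel in chain_selections.items():
        values = np.array(
            [
                lj_interaction_energy(traj.coordinates[m], sel, protein_sel, params, cutoff_A)
                for m in range(traj.n_frames)
            ]
        )
        series[label] = values
    total = np.sum(list(series.values()), axis=0)
    series["total"] = total
    return pd.DataFrame(
        {
            "chain": list(series),
            "mean": [s.mean() for s in series.values()],
            "sd": [s.std() for s in series.values()],
        }
    ).assign(series=[s for s in series.values()])


def per_group_decomposition(
    traj: Trajectory,
    ligand_sel: AtomSelection,
    protein_sel: AtomSelection,
    params: LJParameterTable,
    cutoff_A: float | None = None,
) -> pd.DataFrame:
    """Mean LJ energy per CH2/CH3 group (rows ordered by chain, carbon number).

    Group labels must partition the ligand selection (every atom labelled);
    the per-group means sum to the chain total, framewise — the partition
    identity the tests assert at 1e-8 relative tolerance.
    """
    topology = traj.topology
    labels = []
    for i in ligand_sel.indices:
        lab = topology.atoms[i].group_label
        if lab is None:
            raise ValueError(
                f"atom {topology.atoms[i].name!r} has no group label; groups must "
                "partition the ligand selection"
            )
        labels.append(lab)
    labels = np.array(labels)
    group_names = sorted(
        set(labels), key=lambda g: (g.split(":")[0], int(g.split("CH")[1]))
    )
    eps_l, rh_l = params.arrays_for(topology, ligand_sel.indices)
    eps_p, rh_p = params.arrays_for(topology, protein_sel.indices)
    acc = {g: np.zeros(traj.n_frames) for g in group_names}
    for m in range(traj.n_frames):
        matrix = _cross_energy_matrix(
            traj.coordinates[m], ligand_sel.indices, protein_sel.indices,
            eps_l, rh_l, eps_p, rh_p, cutoff_A,
        )
        per_atom = matrix.sum(axis=1)
        for g in group_names:
            acc[g][m] = per_atom[labels == g].sum()
    return pd.DataFrame(
        {
            "group": group_names,
            "mean": [acc[g].mean() for g in group_names],
            "sd": [acc[g].std() for g in group_names],
            "series": [acc[g] for g in group_names],
        }
    )


def average_decompositions(runs: list[pd.DataFrame]) -> pd.DataFrame:
    """Arithmetic mean of per-group means across independent runs."""
    base = runs[0][["group"]].copy()
    stacked = np.stack([r["mean"].to_numpy() for r in runs])
    base["mean"] = stacked.mean(axis=0)
    return base


def chain_length_fit(points: list[tuple[float, float]]) -> dict:
    """OLS of mean energy vs acyl carbon count.

    Returns slope (kcal/mol per carbon), intercept, and Pearson r.
    """
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct chain lengths")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": float(fit.rvalue),
    }


def _base_length(system: str) -> str | None:
    """'2xC18' / '2 x C18' / '2 × C18' -> 'C18'; monoesters -> None."""
    s = system.replace(" ", "").replace("×", "x")
    if s.lower().startswith("2x"):
        return s[2:]
    return None


def ester_comparison_summary(table: pd.DataFrame) -> dict:
    """Run-averaged totals and diester-vs-monoester comparisons.

    ``table`` has columns system, run, chain, mean (kcal/mol); monoester
    rows use a single chain label.  Every system must appear in every run
    present for that system pair.  Output maps each diester to its
    same-chain-length monoester with the absolute total difference and the
    percentage increase (diester_total / monoester_total - 1) * 100 in
    binding strength (energies are negative; the ratio of totals is used).
    """
    required = {"system", "run", "chain", "mean"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    totals: dict[str, float] = {}
    per_chain: dict[str, dict[str, float]] = {}
    for system, sub in table.groupby("system", sort=False):
        runs = sorted(sub["run"].unique())
        chains = sorted(sub["chain"].unique())
        chain_means = {}
        for chain in chains:
            chain_runs = sub[sub["chain"] == chain]
            if sorted(chain_runs["run"].unique()) != runs:
                raise ValueError(f"system {system!r} chain {chain!r} missing a run")
            chain_means[chain] = float(chain_runs["mean"].mean())
        per_chain[system] = chain_means
        totals[system] = float(sum(chain_means.values()))
    comparisons = {}
    for system in totals:
        mono = _base_length(system)
        if mono is None or mono not in totals:
            continue
        diff = totals[system] - totals[mono]
        pct = (totals[system] / totals[mono] - 1.0) * 100.0
        comparisons[f"{system} vs {mono}"] = {
            "diester_total": totals[system],
            "monoester_total": totals[mono],
            "difference": diff,
            "abs_difference": abs(diff),
            "percent_increase": pct,
        }
    return {
        "run_averaged_totals": totals,
        "run_averaged_per_chain": per_chain,
        "comparisons": comparisons,
    }
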