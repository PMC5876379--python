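"""Run orchestration: config-driven pipelines and table/JSON reporting.

A run config (YAML) names the topology, one trajectory per run, the
selections and analysis parameters; :func:`run_pipeline` executes
contacts -> energetics -> geometry per run, averages across runs, and
returns a :class:`ReportBundle` whose tables :func:`write_tables` writes as
TSV with fixed precision (2 decimals for energies, mirroring the usual
"-5.54 +/- 2.30" presentation).  Reports are deterministic: identical
inputs give byte-identical files, and every output carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as _contacts
from . import energetics as _energetics
from . import geometry as _geometry
from .core import Segment, Trajectory, assign_acyl_groups, load_topology, load_trajectory
from .errors import ConfigError
from .selection import AtomSelection, select

logger = logging.getLogger("lipocontact")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "write_tables", "load_config"]


@dataclass
class RunConfig:
    """Validated run configuration (paths resolved relative to the file)."""

    topology: Path
    trajectories: list[Path]  # one per independent run
    system: str = "system"
    segment_map: dict[str, str] = field(default_factory=lambda: {"A": "protein", "L": "ligand"})
    ligand_selection: str = "segment ligand"
    protein_selection: str = "segment protein"
    chains: dict[str, list[str]] = field(default_factory=dict)  # label -> carbon names
    cutoff_A: float = 5.0
    window_ns: float = 1.0
    gap_tolerance_frames: int = 0
    stride: int = 1
    time_step_ns: float = 0.1
    lj_params: Path | None = None
    distance_pairs: list[dict] = field(default_factory=list)
    out_dir: Path = Path("lipocontact_out")
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.cutoff_A <= 0:
            raise ConfigError("cutoff_A must be positive")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")
        if not self.topology.exists():
            raise ConfigError(f"topology not found: {self.topology}")
        for t in self.trajectories:
            if not t.exists():
                raise ConfigError(f"trajectory not found: {t}")
        if self.lj_params is not None and not self.lj_params.exists():
            raise ConfigError(f"LJ parameter table not found: {self.lj_params}")

    def hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent
    kwargs = dict(raw)
    kwargs["topology"] = base / raw["topology"]
    kwargs["trajectories"] = [base / t for t in raw["trajectories"]]
    if raw.get("lj_params"):
        kwargs["lj_params"] = base / raw["lj_params"]
    if raw.get("out_dir"):
        kwargs["out_dir"] = base / raw["out_dir"]
    config = RunConfig(**kwargs)
    config.validate()
    return config


@dataclass
class ReportBundle:
    """All tables and the machine-readable summary of one pipeline run."""

    system: str
    config_hash: str
    tables: dict[str, pd.DataFrame]
    summary: dict


def _analyze_run(
    config: RunConfig, traj: Trajectory, run_id: int, bundle_tables: dict, summary_runs: dict
) -> None:
    topology = traj.topology
    ligand = select(topology, config.ligand_selection)
    protein = select(topology, config.protein_selection)
    if len(ligand) == 0:
        raise ConfigError("ligand selection matches no atoms")

    series = _contacts.contact_count_series(traj, protein, ligand, config.cutoff_A)
    per_res = _contacts.contacts_by_residue(traj, ligand, config.cutoff_A)
    heat = _contacts.contact_time_heatmap(traj, ligand, config.window_ns, config.cutoff_A)
    life = _contacts.contact_lifetimes(
        traj, ligand, "residue", config.gap_tolerance_frames, config.cutoff_A
    )
    bundle_tables[f"run{run_id}_contacts_per_residue"] = per_res
    bundle_tables[f"run{run_id}_contacts_heatmap"] = heat.reset_index(names="residue")
    bundle_tables[f"run{run_id}_lifetime_events"] = pd.DataFrame(
        {
            "entity": [str(e) for e in life.entity_of_event],
            "start_frame": [s for s, _ in life.events],
            "end_frame": [e for _, e in life.events],
        }
    )
    run_summary = {
        "mean_contacts": series["mean"],
        "sd_contacts": series["sd"],
        "mean_lifetime_ns": life.mean_lifetime_ns,
    }

    per_chain = {}
    if config.chains:
        for label in config.chains:
            chain_sel = select(topology, f"group {label}")
            chain_series = _contacts.contact_count_series(
                traj, protein, chain_sel, config.cutoff_A
            )
            per_chain[label] = {
                "mean_contacts": chain_series["mean"],
                "sd_contacts": chain_series["sd"],
            }
    run_summary["per_chain"] = per_chain

    if config.lj_params is not None:
        params = _energetics.LJParameterTable.from_tsv(config.lj_params)
        chain_sels = (
            {label: select(topology, f"group {label}") for label in config.chains}
            if config.chains
            else {"F1": ligand}
        )
        energy = _energetics.energy_series_summary(traj, chain_sels, protein, params)
        bundle_tables[f"run{run_id}_energy"] = energy[["chain", "mean", "sd"]]
        run_summary["energy"] = {
            row.chain: {"mean": row.mean, "sd": row.sd}
            for row in energy.itertuples(index=False)
        }
        decomp = _energetics.per_group_decomposition(traj, ligand, protein, params)
        bundle_tables[f"run{run_id}_energy_groups"] = decomp[["group", "mean", "sd"]]

    _, per_res_rmsf = _geometry.rmsf(traj, protein)
    bundle_tables[f"run{run_id}_rmsf"] = per_res_rmsf
    run_summary["rmsf_max_A"] = float(per_res_rmsf["rmsf"].max()) if len(per_res_rmsf) else 0.0
    for pair in config.distance_pairs:
        spec = _geometry.DistancePairSpec(
            residue_a=int(pair["residue_a"]),
            residue_b=int(pair["residue_b"]),
            mode=pair.get("mode", "calpha"),
        )
        dist = _geometry.pair_distance_series(traj, spec)
        key = f"run{run_id}_dist_{spec.residue_a}_{spec.residue_b}_{spec.mode}"
        bundle_tables[key] = dist
        run_summary.setdefault("groove_width", {})[
            f"{spec.residue_a}-{spec.residue_b}:{spec.mode}"
        ] = {"mean": float(dist["distance_A"].mean()), "sd": float(dist["distance_A"].std(ddof=0))}
    rg = _geometry.radius_of_gyration(traj, ligand)
    bundle_tables[f"run{run_id}_rg"] = rg
    run_summary["ligand_rg_mean_A"] = float(rg["rg_A"].mean())
    summary_runs[f"run{run_id}"] = run_summary


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute contacts -> energetics -> geometry for every run of a config.

    Per-run tables are kept side by side and per-chain means are averaged
    across runs (the convention used when two independent trajectories per
    system are reported).  Deterministic for fixed inputs.
    """
    config.validate()
    logger.info(
        "run_pipeline system=%s cutoff_A=%s window_ns=%s gap=%s stride=%s",
        config.system, config.cutoff_A, config.window_ns,
        config.gap_tolerance_frames, config.stride,
    )
    topology, _ = load_topology(config.topology.read_text(), config.segment_map)
    if config.chains:
        assign_acyl_groups(topology, config.chains)
    # validate every selection before any trajectory is read or analyzed
    try:
        select(topology, config.ligand_selection)
        select(topology, config.protein_selection)
    except Exception as exc:
        raise ConfigError(f"invalid selection: {exc}") from exc
    tables: dict[str, pd.DataFrame] = {}
    summary_runs: dict[str, dict] = {}
    for run_id, traj_path in enumerate(config.trajectories, start=1):
        traj = load_trajectory(
            traj_path, topology, stride=config.stride, time_step_ns=config.time_step_ns
        )
        try:
            _analyze_run(config, traj, run_id, tables, summary_runs)
        except Exception as exc:
            raise type(exc)(f"run {run_id} ({traj_path.name}): {exc}") from exc

    mean_contacts = float(
        np.mean([r["mean_contacts"] for r in summary_runs.values()])
    )
    summary = {
        "system": config.system,
        "config_hash": config.hash(),
        "runs": summary_runs,
        "run_averaged": {"mean_contacts": mean_contacts},
    }
    if config.chains:
        averaged = {}
        for label in config.chains:
            averaged[label] = float(
                np.mean([r["per_chain"][label]["mean_contacts"] for r in summary_runs.values()])
            )
        summary["run_averaged"]["per_chain_contacts"] = averaged
    return ReportBundle(config.system, config.hash(), tables, summary)


_FLOAT_FORMATS = {"energy": "%.2f"}


def write_tables(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Write every table as TSV plus summary.json; returns the paths.

    Energies use 2 decimals; everything else 4.  Column order is the
    DataFrame's own (stable by construction).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(bundle.tables):
        df = bundle.tables[name].drop(columns=["series"], errors="ignore")
        fmt = "%.2f" if "energy" in name else "%.4f"
        path = out / f"{name}.tsv"
        with path.open("w") as fh:
            fh.write(f"# system={bundle.system} config={bundle.config_hash}\n")
            df.to_csv(fh, sep="\t", index=False, float_format=fmt)
        written.append(path)
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(bundle.summary, indent=2, sort_keys=True))
    written.append(summary_path)
    return written


def write_ratio_table(ratios: pd.DataFrame, path: str | Path) -> Path:
    """Write a contact-ratio matrix in the published lower-triangular layout."""
    path = Path(path)
    names = list(ratios.index)
    lines = ["Systems(y/x)\t" + "\t".join(names)]
    for yi, y in enumerate(names):
        cells = []
        for xi, x in enumerate(names):
            cells.append(f"{ratios.loc[y, x]:.2f}" if xi <= yi else "")
        lines.append(y + "\t" + "\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path
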