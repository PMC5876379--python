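#!/usr/bin/env python
"""Contact statistics across the synthetic study set.

For every system and run generated by 01_generate_systems.py: mean contact
count (per chain), per-residue contact profile, and residue-level contact
lifetimes; then the cross-system ratio matrix of run-averaged means, in
the lower-triangular "Systems (y/x)" layout.  Writes TSVs under
results/contacts/.
"""

import json
from pathlib import Path

import numpy as np

from lipocontact.contacts import (
    contact_count_series,
    contact_lifetimes,
    contact_ratio_table,
    contacts_by_residue,
)
from lipocontact.core import load_topology, load_trajectory
from lipocontact.reporting import write_ratio_table
from lipocontact.selection import select

BASE = Path(__file__).resolve().parent.parent / "results"
SYSTEMS_DIR = Path(__file__).resolve().parent.parent / "scratch" / "systems"
OUT = BASE / "contacts"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    system_means: dict[str, float] = {}
    summary = {}
    for system_dir in sorted((SYSTEMS_DIR).iterdir()):
        run_means = []
        for run_dir in sorted(system_dir.iterdir()):
            topo, _ = load_topology(
                (run_dir / "topology.pdb").read_text(), {"A": "protein", "L": "ligand"}
            )
            traj = load_trajectory(run_dir / "trajectory.pdb", topo)
            prot = select(topo, "segment protein")
            lig = select(topo, "segment ligand")
            series = contact_count_series(traj, prot, lig)
            run_means.append(series["mean"])
            per_res = contacts_by_residue(traj, lig)
            per_res.to_csv(
                OUT / f"{system_dir.name}_{run_dir.name}_per_residue.tsv",
                sep="\t", index=False, float_format="%.4f",
            )
            life = contact_lifetimes(traj, lig, "residue", 0)
            summary.setdefault(system_dir.name, {})[run_dir.name] = {
                "mean_contacts": series["mean"],
                "sd_contacts": series["sd"],
                "mean_lifetime_ns": life.mean_lifetime_ns,
            }
        system_means[system_dir.name] = float(np.mean(run_means))
        print(f"{system_dir.name}: run-averaged mean contacts "
              f"{system_means[system_dir.name]:.1f}")

    order = [s for s in ("C4", "C8", "C12", "C18", "2xC4", "2xC18") if s in system_means]
    ratios = contact_ratio_table({s: system_means[s] for s in order})
    write_ratio_table(ratios, OUT / "contact_ratio_matrix.tsv")
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    print(f"wrote ratio matrix and summaries to {OUT}")


if __name__ == "__main__":
    main()
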