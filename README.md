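# lipocontact

Post-processing toolkit for molecular-dynamics trajectories of
protein–glycolipid complexes, built around the analyses used to
characterize how trehalose mono- and diester acyl chains engage the
hydrophobic groove of the C-type lectin receptor Mincle (lined by L172,
V173, F197, F198). It is aimed at structural bioinformaticians who have
trajectories of a receptor with one or two flexible acyl chains and want
the standard battery of questions answered: who touches whom, for how
long, how strongly, and how rigid is the binding site.

## What it computes

- **Contacts** — an atom pair (one protein, one ligand atom) is a contact
  when its Euclidean distance is ≤ 5 Å (inclusive; configurable). Counts
  are aggregated per frame, per protein residue, per ligand atom
  (residue × acyl-atom maps in the published carbon-then-hydrogens column
  order), and per time window. Detection runs through a cell list that is
  bit-identical to the brute-force O(N²) reference.
- **Contact lifetimes** — maximal runs of contact-positive frames per
  residue or atom pair, with a gap tolerance; mean lifetime
  `= mean event length × frame spacing`.
- **van der Waals energetics** — pairwise 12-6 Lennard-Jones energy
  `E(r) = ε_ij[(R_ij/r)¹² − 2(R_ij/r)⁶]` with Lorentz–Berthelot combining
  (`ε_ij = √(ε_i ε_j)`, `R_ij = R_i/2 + R_j/2`), summed over all
  protein–ligand cross pairs (no cutoff by default), decomposed per
  CH₂/CH₃ group, regressed against acyl carbon count, and summarized as
  run-averaged monoester/diester comparisons.
- **Geometry** — Kabsch superposition, per-residue backbone RMSF against
  the mean structure, groove-width distance series (Cα or distal-sidechain
  centroids for pairs such as F198–L172), and radius of gyration.
- **Synthetic systems** — a seeded toy generator (rigid two-ridge groove
  receptor + anchored bead chains, bond length 1.53 Å) whose contact
  probabilities, lifetimes, chain statistics and energies are known
  analytically, so every stage is verifiable without running MD.

## Worked example

```python
from lipocontact import (SyntheticSystemSpec, sample_chain_trajectory,
                         select, contact_count_series, contact_lifetimes)

spec = SyntheticSystemSpec(chains=(6,), dynamics="two_state_schedule",
                           n_frames=4000, rng_seed=3, switching_prob=0.1)
traj = sample_chain_trajectory(spec)
prot = select(traj.topology, "segment protein")
lig  = select(traj.topology, "segment ligand")
series = contact_count_series(traj, prot, lig)
life = contact_lifetimes(traj, lig, level="residue")
print(f"mean contacts {series['mean']:.2f} +/- {series['sd']:.2f}")
print(f"mean residue-level lifetime {life.mean_lifetime_ns:.2f} ns")
```

prints

```
mean contacts 3.59 +/- 3.83
mean residue-level lifetime 0.46 ns
```

i.e. on average ~3.6 protein–ligand atom pairs are within 5 Å per frame
(large SD — the chain hops between the groove and solvent), and a typical
residue that gains a contact keeps it for ~4.6 frames at 0.1 ns spacing.
The designated groove residue L172 alone averages 11.8 frames at this
seed, statistically consistent with the 1/p = 10 frames its geometric
switching schedule implies.

The same operations run from the shell: `lipocontact synth`,
`lipocontact contacts`, `lipocontact energy`, `lipocontact geometry`, and
`lipocontact report --config run.yaml` for config-driven multi-run
studies.

## Analysis scripts

`analysis/01_generate_systems.py` … `04_geometry.py` run the full
narrative on a synthetic study set (chains of 4–18 beads, mono- and
two-chain systems, two seeded Metropolis runs each): contact ratio
matrices, per-chain energies with CH-group decompositions, groove-width
and RMSF summaries. Tables land in `results/`; the bulky generated
trajectories in `scratch/` (regenerated on demand).

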