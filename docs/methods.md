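# Methods

This note documents the models, conventions and numerical choices behind
lipocontact, and what the synthetic-system tests do and do not establish
about real MD data.

## Units and identity conventions

Coordinates are in Å, times in ns, energies in kcal/mol. Residue numbers
are taken verbatim from the input PDB (author numbering), so outputs name
the Mincle groove residues L172, V173, F197, F198 exactly as a reader of
the structural literature expects. Atoms are partitioned into segments
(protein / ligand / solvent / ion) via a user-supplied chain→segment map;
unmapped water residues default to solvent and unmapped monoatomic
HETATM records to ion. Solvent and ions are parsed but excluded from all
analyses by default — the pipeline's subject is the protein–ligand
interface; crystal waters can be pulled in explicitly through selections
if a study needs them. Hydrogens are first-class on both sides: published
residue × acyl-atom contact maps enumerate the chain hydrogens
explicitly, and the default contact counting includes protein hydrogens
as well (a heavy-atom-only restriction is a selection away).

## Contacts

A contact is an atom pair, one atom per selection, with Euclidean
distance ≤ cutoff; the default cutoff is 5 Å and the comparison is
inclusive. Per-residue counts **sum pairs** rather than flagging a
residue 0/1 per frame; this is the convention consistent with per-system
totals of hundreds of contacts over a ~130-residue domain, and a binary
mode is provided for the other reading. Statistics use uniform frame
weights and the population (not sample) standard deviation; striding, if
any, is applied before statistics.

Two detection back ends exist: a vectorized brute-force O(N²) reference
and a cell list with cubic cells of edge = cutoff scanning 27 neighbour
cells. Both classify pairs with the same elementwise squared-distance
arithmetic, so their outputs are bit-identical, not merely close — the
test suite asserts exact pair-set equality on random 500–2000-atom
configurations.

Periodic boundaries are deliberately out of scope for the default path:
the analyses assume an imaged, whole solute, since re-imaging octahedral
MD boxes is an engine concern upstream of analysis. A minimum-image
correction could be layered onto the distance kernel if orthorhombic box
information is present, but none of the shipped analyses requires it.

### Lifetimes

A contact event at level *residue* (default) is a maximal run of frames
in which ≥ 1 atom pair of that residue is in contact, allowing
interruptions up to `gap_tolerance_frames` (default 0); at level
*atom_pair* the run is per pair. The event span is measured
first-to-last contact-positive frame inclusive, so with gap tolerance 0
the event lengths sum exactly to the number of contact-positive frames —
a conservation identity the tests assert. Mean lifetime in ns is the
mean event length times the frame spacing (taken as the median of
successive time differences).

### Windows

The contacts-vs-time heatmap uses 1 ns windows by default; the final
partial window is retained and flagged (starred column label and a
`partial_windows` attribute) rather than dropped, so short trajectories
do not silently lose their tail.

## van der Waals energetics

The pairwise energy is the Amber-convention 12-6 Lennard-Jones form

    E(r) = ε_ij [(R_ij/r)¹² − 2 (R_ij/r)⁶],
    ε_ij = √(ε_i ε_j),   R_ij = Rmin_half_i + Rmin_half_j,

with per-atom ε (kcal/mol) and Rmin/2 (Å) read from a TSV table.
**This functional form and combining rule are this package's own
declaration**: the convention matches the Amber/Glycam toolchain used to
produce the trajectories this pipeline targets, but upstream analysis
tools do not print their pairwise conventions (cutoffs, exclusion
handling), so the defaults here are stated, not inferred as ground
truth. Concretely: no distance cutoff is applied to protein–ligand sums
(the complexes are small and an uncut sum avoids per-group tail
artifacts; a cutoff flag exists for speed), no intramolecular or 1–4
terms are computed (only inter-selection pairs, which cross molecules),
and electrostatics are excluded by design — for apolar acyl chains the
LJ term is the meaningful affinity proxy.

Per-CH₂/CH₃-group decomposition attributes each pair's energy to the
ligand atom's group (carbon plus its attached hydrogens, assigned by the
cN → hNa/hNb naming convention); because the groups partition the ligand
selection, per-group energies sum to the chain total framewise, which
the tests assert at 1e-8 relative tolerance. Chain-length regression is
ordinary least squares (scipy.stats.linregress). The
monoester/diester summary averages each chain over runs, totals diester
chains F1+F2, and reports the percentage increase
`(diester_total / monoester_total − 1) × 100` on the energy totals.

The package also ships the published per-run energy table for the
Mincle–trehalose-ester systems (`lipocontact.reference`) as *input* to
these arithmetic operations; feeding it through the summary reproduces
the reported ≈36 % 2×C18-vs-C18 increase and the <1 kcal/mol 2×C4-vs-C4
difference, and its C4–C12 run-averaged means give a slope of
−0.86 kcal/mol per carbon.

## Geometry

Superposition is the least-squares rigid Kabsch fit via SVD with a
determinant correction guaranteeing a proper rotation; degenerate
(collinear or < 3-atom) fit sets are rejected. RMSF uses the mean
structure as reference with one refinement pass — fit all frames to
frame 0, compute the mean, re-fit to that mean — because the reference
convention is rarely stated in the literature; a frame-0 reference is
available as an option. Per-residue RMSF averages the backbone atoms
N/CA/C/O (a Cα-only mode exists). Note a small estimator property: the
rigid fit absorbs ~6 of the 3N fluctuation degrees of freedom, so pure
isotropic jitter of σ per coordinate yields an RMSF slightly below
σ√3 — about 0.5 % low at 200 atoms — which is why the recovery tests use
systems of that size.

Groove width is a per-frame distance between residue points: Cα–Cα, or
"most distal sidechain atoms". The latter is not a crystallographic
standard, so it is implemented as configurable named atoms with
documented defaults — CZ for Phe, the CD1/CD2 centroid for Leu, the
CG1/CG2 centroid for Val — matching the published F198–L172 and
F197–V173 pairs; a single configured atom reduces to a plain atom–atom
distance. Radius of gyration is mass-weighted by default with a uniform
weighting flag.

## Synthetic systems and what the tests show

The generator builds a rigid receptor of Cα pseudo-residues on two
parallel ridges (separation 10 Å, bead spacing 3.8 Å, 8 residues per
ridge numbered 170–177 and 193–200) with the four key groove residues
carrying their Mincle numbers, and one or two anchored bead chains at
the aliphatic C–C bond length 1.53 Å — so the synthetic geometry lives
on the physical scale of the 5 Å criterion. Receptor rigidity mirrors
the conformational stability of the real groove and makes the RMSF
null-result a built-in check. Each trajectory draws from one named,
seeded NumPy generator, and the seed is recorded in the fixture
metadata; two-run study designs get first-class run/seed provenance.

Four dynamics modes trade realism for tractable truth:

- `uniform_bead`: single bead uniform in a 20 Å box around one receptor
  atom; contact probability is exactly (4π/3)·cutoff³/box³ ≈ 0.0654.
- `freely_jointed_resample`: i.i.d. freely-jointed chains;
  ⟨R²⟩ = n·b² exactly.
- `two_state_schedule`: a symmetric Markov switch (p per frame, default
  0.1) between an in-groove conformer pool — every member guaranteed in
  contact with L172 — and a solvent pool guaranteed contact-free, so the
  L172 lifetime is geometric with mean 1/p frames.
- `metropolis_mc`: seeded pivot moves with hard-core self/receptor
  avoidance (1 Å core) and optional LJ attraction to the receptor at
  kT = 0.6 kcal/mol; no closed form, so its reference comes from an
  independent long-run plain-Python re-computation flagged empirical.
  A frozen chain (no accepted move in 10⁴ attempts) is a diagnostic
  error, not a hang.

Ground truths are computed by closed form or by samplers written
independently of the pipeline code under test. Parameter-recovery tests
run at 10⁴ frames and accept within 3 standard errors (2 % for the RMSF
check, whose truth is exact). Passing them shows the pipeline's
estimators are unbiased and correctly scaled on data with known
statistical structure; it does **not** validate force-field physics,
solvent effects, periodic imaging, or sampling adequacy of real MD —
those belong to the simulation, not the analysis.

The toy diester results illustrate the gap deliberately: both toy chains
reach the groove almost symmetrically, so the synthetic 2×C18-vs-C18
energy increase (~115 % in the shipped analysis run) is far larger than
the published 36 %, where the second chain is sterically hindered. The
analysis scripts print both side by side.

## Problem sizes and determinism

The shipped analysis runs use 600-frame Metropolis trajectories, two
runs per system, and the test suite's recovery checks use 2–10 × 10³
frames — sizes chosen so the full narrative re-runs in minutes on one
core while keeping Monte-Carlo standard errors well inside the test
bands. All fixtures and reports are deterministic: identical
specs/seeds/configs produce byte-identical files, and every report
carries a hash of its configuration.
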