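#!/usr/bin/env python
"""Generate the synthetic study set: anchored acyl chains of 4, 8, 12 and
18 beads (monoester analogues) and two-chain 2x4 / 2x18 systems (diester
analogues), two seeded Metropolis runs each, over the rigid two-ridge
groove receptor.  Writes topology/trajectory/ground-truth fixtures under
scratch/systems/<system>/run<k>/ (large, regenerated on demand).
"""

from pathlib import Path

from lipocontact.synthetic import SyntheticSystemSpec, write_fixture

OUT = Path(__file__).resolve().parent.parent / "scratch" / "systems"

SYSTEMS = {
    "C4": (4,),
    "C8": (8,),
    "C12": (12,),
    "C18": (18,),
    "2xC4": (4, 4),
    "2xC18": (18, 18),
}
N_FRAMES = 600
BASE_SEED = 2024


def main() -> None:
    for k, (name, chains) in enumerate(SYSTEMS.items()):
        for run in (1, 2):
            spec = SyntheticSystemSpec(
                chains=chains,
                dynamics="metropolis_mc",
                potential={"epsilon": 0.25, "rmin_half": 1.9, "kT": 0.6},
                n_frames=N_FRAMES,
                rng_seed=BASE_SEED + 10 * k + run,
            )
            paths = write_fixture(spec, OUT / name / f"run{run}")
            print(f"{name} run{run}: wrote {paths['trajectory'].parent}")


if __name__ == "__main__":
    main()
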