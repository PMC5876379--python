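"""Published reference values for the Mincle–trehalose-ester systems.

These are literature-reported results of two independent 300 ns
explicit-solvent MD runs per system of the Mincle carbohydrate-recognition
domain bound to trehalose mono- and diesters (acyl chains named by carbon
count; diester chains F1/F2).  They serve as *inputs* to the arithmetic
summary operations (run averaging, diester-vs-monoester comparison,
chain-length regression) and as cross-check constants in the test suite —
they are not produced by this package.
"""

from __future__ import annotations

import pandas as pd

# Mean +/- SD van der Waals (Lennard-Jones) interaction energy between the
# protein and the acyl chains, kcal/mol, per simulation run.
VDW_ENERGY_ROWS = [
    # (system, run, chain, mean, sd)
    ("C4", 1, "F1", -5.54, 2.30),
    ("C4", 2, "F1", -6.40, 2.11),
    ("C8", 1, "F1", -9.32, 3.31),
    ("C8", 2, "F1", -10.22, 2.77),
    ("C12", 1, "F1", -12.62, 3.08),
    ("C12", 2, "F1", -13.11, 2.48),
    ("C18", 1, "F1", -15.40, 3.64),
    ("C18", 2, "F1", -14.28, 4.48),
    ("2xC4", 1, "F1", -5.87, 1.94),
    ("2xC4", 2, "F1", -6.13, 2.18),
    ("2xC4", 1, "F2", -0.57, 0.87),
    ("2xC4", 2, "F2", -0.42, 0.70),
    ("2xC18", 1, "F1", -12.42, 4.26),
    ("2xC18", 2, "F1", -14.26, 3.20),
    ("2xC18", 1, "F2", -7.97, 4.08),
    ("2xC18", 2, "F2", -5.64, 2.54),
]


def vdw_energy_table() -> pd.DataFrame:
    """Reference per-run, per-chain vdW energies as a tidy DataFrame."""
    return pd.DataFrame(
        VDW_ENERGY_ROWS, columns=["system", "run", "chain", "mean", "sd"]
    )


# Reported ratios of mean acyl-chain contact numbers, row system / column
# system, averaged over both runs (lower triangle as published).
CONTACT_RATIO_ROWS = {
    ("C8", "C4"): 1.59,
    ("C12", "C4"): 2.25,
    ("C12", "C8"): 1.42,
    ("C18", "C4"): 2.53,
    ("C18", "C8"): 1.60,
    ("C18", "C12"): 1.12,
    ("2xC4", "C4"): 1.06,
    ("2xC4", "C8"): 0.67,
    ("2xC4", "C12"): 0.47,
    ("2xC4", "C18"): 0.42,
    ("2xC18", "C4"): 3.36,
    ("2xC18", "C8"): 2.12,
    ("2xC18", "C12"): 1.49,
    ("2xC18", "C18"): 1.33,
    ("2xC18", "2xC4"): 3.18,
}

# Carbon counts of the monoester systems used in the chain-length fit.
MONOESTER_CARBONS = {"C4": 4, "C8": 8, "C12": 12}
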