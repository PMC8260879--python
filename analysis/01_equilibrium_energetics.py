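#!/usr/bin/env python
"""Dimerization energetics and oligomeric fractions from the measured constants.

Takes the dissociation constants measured by FSI-FRET for the receptor
variants (wild type, mutants, with/without ligand) and computes the
2-D dimerization free energy at 298.15 K, plus the predicted oligomeric
fractions at a high-expression reference density of 3000 receptors/μm².

Writes results/equilibrium_energetics.csv and results/fraction_bounds.csv.
"""

from pathlib import Path

import pandas as pd

from oligomerkit import EquilibriumModel, ThermoConstants, free_energy, oligomeric_fraction
from oligomerkit.equilibrium import kdiss_from_half_saturation

OUT = Path(__file__).resolve().parents[1] / "results"

# Dimer-forming variants: measured K_diss (receptors/μm²).
DIMER_CONSTANTS = {
    "EphA4 WT (no ligand)": 1050.0,
    "EphA4 WT (ephrinA5-Fc)": 120.0,
    "EphA4 H945E (no ligand)": 540.0,
    "EphA4 dSAM (no ligand)": 1120.0,
    "EphA2 WT (no ligand)": 300.0,
    "EphA2 L913F (no ligand)": 90.0,
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    const = ThermoConstants(temperature=298.15)
    rows = [
        {"variant": name, "k_diss": k, "delta_g_kcal_mol": round(free_energy(k, const), 2)}
        for name, k in DIMER_CONSTANTS.items()
    ]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "equilibrium_energetics.csv", index=False)
    print(df.to_string(index=False))

    conc = 3000.0
    wt = EquilibriumModel(2, 1050.0)
    mut = EquilibriumModel(3, kdiss_from_half_saturation(580.0, 3))
    bounds = pd.DataFrame(
        [
            {
                "model": "monomer-dimer (WT-like, K=1050)",
                "total_conc": conc,
                "oligomeric_fraction": oligomeric_fraction(conc, wt),
            },
            {
                "model": "monomer-trimer (mutant-like, R_half=580)",
                "total_conc": conc,
                "oligomeric_fraction": oligomeric_fraction(conc, mut),
            },
        ]
    )
    bounds.to_csv(OUT / "fraction_bounds.csv", index=False)
    print()
    print(bounds.to_string(index=False))
    print(
        "\nAt 3000 receptors/um^2 the dimer-forming receptor is "
        f"{100 * bounds['oligomeric_fraction'][0]:.1f}% oligomeric and the "
        f"trimer-forming one {100 * bounds['oligomeric_fraction'][1]:.1f}% — "
        "both predominantly associated, which is why the high-concentration "
        "brightness histograms read out the oligomer size directly."
    )


if __name__ == "__main__":
    main()
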