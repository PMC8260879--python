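#!/usr/bin/env python
"""Molecular-brightness (FIF) histograms for dimer- and trimer-forming receptors.

Simulates compound-Poisson 15×15-pixel membrane segments whose species
composition follows the fitted equilibria (dimer K=1050; trimer
half-saturation 580, both receptors/μm²), then builds brightness
histograms over the full concentration range and after restricting to
segments above 3000 receptors/μm², where monomers are scarce and the
histogram maximum reads out the oligomer size.

Writes results/fif_modal_brightness.csv and per-condition histogram CSVs.
"""

from pathlib import Path

import pandas as pd

from oligomerkit import (
    EquilibriumModel,
    FifTruth,
    brightness_histogram,
    brightness_records,
    generate_fif_images,
)
from oligomerkit.equilibrium import kdiss_from_half_saturation
from oligomerkit.fif import SegmentGrid

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1
HIGH_CONC = 3000.0  # receptors/μm²


def run(label: str, model: EquilibriumModel, conc_range) -> dict:
    truth = FifTruth(model=model, conc_range=conc_range, segment_count=3000, seed=SEED)
    stack, _ = generate_fif_images(truth)
    grid = SegmentGrid(stack.astype(float), truth.segment_size, truth.pixel_area)
    records = brightness_records(grid, monomer_brightness=truth.monomer_brightness)
    full = brightness_histogram(records, bin_width=0.1)
    high = brightness_histogram(records, min_concentration=HIGH_CONC, bin_width=0.1)
    pd.DataFrame(
        {"bin_left": full.bin_edges[:-1], "bin_right": full.bin_edges[1:], "count": full.counts}
    ).to_csv(OUT / f"fif_histogram_{label}.csv", index=False)
    n_high = int(high.counts.sum())
    return {
        "condition": label,
        "modal_full_range": full.modal_epsilon,
        "modal_above_3000": high.modal_epsilon,
        "segments_above_3000": n_high,
    }


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = [
        run("dimer", EquilibriumModel(2, 1050.0), (50.0, 10_000.0)),
        run("trimer", EquilibriumModel(3, kdiss_from_half_saturation(580.0, 3)), (50.0, 10_000.0)),
    ]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "fif_modal_brightness.csv", index=False)
    print(df.to_string(index=False))
    print(
        "\nOver the full concentration range the modes sit below the pure "
        "oligomer values (monomer/oligomer mixture); restricting to "
        ">3000 receptors/um^2 pushes the dimer mode toward 2 and the trimer "
        "mode toward 3 monomeric units, the brightness signatures of dimers "
        "and trimers."
    )


if __name__ == "__main__":
    main()
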