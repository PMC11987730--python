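#!/usr/bin/env python
"""Generate one example of each synthetic dataset with its ground truth.

Writes a clean and a noisy culture frame (TIFF + truth JSON), a planted
plate-assay table and a planted protein matrix under results/data/, and
prints what was planted so the later analyses can be read against it.
"""

import argparse
from pathlib import Path

from neurocult import io, simulate
from neurocult.pipeline import stage_seed

OUT = Path("results/data")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    for label, noise in (("clean", 0.0), ("noisy",
                                          simulate.ROBUSTNESS_NOISE_SD)):
        params = simulate.FrameSimParams(seed=stage_seed(args.seed, 0),
                                         noise_sd=noise)
        scene = simulate.generate_frame(params)
        io.write_image(scene.image, OUT / f"frame_{label}.tif")
        io.write_truth(scene, OUT / f"frame_{label}_truth.json")
        print(f"frame_{label}: {len(scene.somata)} somata, "
              f"{len(scene.dendrites)} dendrites, "
              f"{scene.true_graph.number_of_edges()} cell-to-cell "
              f"connections (noise sd {noise})")

    design = simulate.PlateDesign(
        group_means={"control": 100.0, "B1": 162.29, "B6": 155.15,
                     "B12": 103.70, "combo": 197.32},
        wells_per_group=6, noise_sd=6.0, assay_name="viability",
        seed=stage_seed(args.seed, 1))
    plate = simulate.generate_plate(design)
    plate.to_csv(OUT / "plate_viability.csv")
    print(f"plate_viability: {len(plate.df)} wells, planted means "
          f"{design.group_means}")

    params = simulate.ProteinSimParams(seed=stage_seed(args.seed, 2))
    table, truth = simulate.generate_protein_matrix(params)
    table.to_tsv(OUT / "protein_groups.tsv")
    print(f"protein_groups: {len(table.protein_ids)} proteins, "
          f"{len(truth.spiked_ids)} spiked at |log2fc| = "
          f"{params.spike_log2fc}, groups {params.group_labels}")


if __name__ == "__main__":
    main()
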