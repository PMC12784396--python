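#!/usr/bin/env python
"""Generate the synthetic study inputs.

Draws moment-matched per-slice readout pools from the published condition
summaries, renders two fluorescence image sets per condition (apoptotic
fraction set to each condition's published cell-death index), and simulates
the five-condition RNA-seq count matrix with spiked heme-stress and
heme-metabolism programs.

Tables land in results/data/; images (binary TIFF) in scratch/images/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hemoscape.synthetic_data import (
    CONDITIONS,
    SyntheticCountDesign,
    SyntheticImageSpec,
    generate_counts,
    generate_image,
    generate_pools,
    get_preset,
    presets_frame,
    write_image_channels,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    parser.add_argument("--image-dir", type=Path, default=Path("scratch/images"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    args.image_dir.mkdir(parents=True, exist_ok=True)

    presets = presets_frame()
    presets.to_csv(args.out / "presets.csv", index=False)
    print(f"preset table: {len(presets)} rows "
          f"({presets['assumed'].sum()} carry assumed values)")

    pools = generate_pools(seed=args.seed)
    pools.to_csv(args.out / "pools.csv", index=False)
    print(f"readout pools: {len(pools)} per-slice values across "
          f"{pools.groupby(['condition', 'readout']).ngroups} cells")

    rows = []
    seeds = np.random.SeedSequence(args.seed).spawn(2 * len(CONDITIONS))
    i = 0
    for condition in CONDITIONS:
        fraction = get_preset(condition, "cell_death").mean
        for rep in (1, 2):
            spec = SyntheticImageSpec(
                n_cells=100,
                apoptotic_fraction=fraction,
                seed=int(seeds[i].generate_state(1)[0] % 2**31),
            )
            nuclei, neun, casp3, truth = generate_image(spec)
            prefix = args.image_dir / f"{condition}_{rep:02d}"
            write_image_channels(prefix, nuclei, neun, casp3)
            truth.to_csv(f"{prefix}_truth.csv", index=False)
            rows.append({"image": prefix.name, "condition": condition,
                         "true_fraction": truth["true_fraction"].iloc[0]})
            i += 1
    pd.DataFrame(rows).to_csv(args.out / "image_index.csv", index=False)
    print(f"images: {len(rows)} fields x 3 channels -> {args.image_dir}")

    design = SyntheticCountDesign(seed=args.seed)
    counts, samples, truth = generate_counts(design)
    counts.to_csv(args.out / "counts.tsv", sep="\t")
    samples.to_csv(args.out / "samples.csv", index=False)
    truth.to_csv(args.out / "gene_truth.csv", index=False)
    print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples "
          f"({(truth['program'] != 'none').sum()} program genes)")


if __name__ == "__main__":
    main()
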