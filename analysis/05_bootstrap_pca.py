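#!/usr/bin/env python
"""Integrate the five readouts by bootstrap-pseudoslice PCA.

Assembles 250 pseudoslices per condition from the readout pools, z-scales
the 1,250 x 5 matrix, runs PCA with oriented loadings, and maps each
condition's centroid (with 95% percentile intervals) to an attractor state
relative to the control.

Writes results/bootpca/{pseudoslices,loadings,explained,centroids,attractors}.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from hemoscape import bootpca as bp


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--replicates", type=int, default=250)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/bootpca"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pools = bp.ReadoutPools.from_frame(pd.read_csv(args.data / "pools.csv"))
    matrix = bp.make_pseudoslices(pools, B=args.replicates, seed=args.seed)
    print(f"pseudoslice matrix: {matrix.values.shape[0]} x {matrix.values.shape[1]} "
          f"({len(pools.conditions)} conditions x B={args.replicates})")
    matrix.frame.to_csv(args.out / "pseudoslices.csv", index=False)

    result = bp.orient_components(bp.run_pca(bp.zscale(matrix)))
    loadings = bp.loadings_frame(result)
    loadings.to_csv(args.out / "loadings.csv")
    explained = pd.DataFrame(
        {"component": [f"PC{i + 1}" for i in range(5)],
         "explained_pct": 100 * result.explained_fraction}
    )
    explained.to_csv(args.out / "explained.csv", index=False)
    print(f"variance explained: PC1 {explained['explained_pct'][0]:.1f}%, "
          f"PC2 {explained['explained_pct'][1]:.1f}%")
    print("loadings (oriented):")
    print(loadings[["PC1", "PC2"]].round(3).to_string())

    centroids = bp.condition_centroids(result)
    centroids.to_csv(args.out / "centroids.csv", index=False)
    states = bp.classify_attractors(centroids, "Ctrl")
    states.to_csv(args.out / "attractors.csv", index=False)
    print("condition centroids and attractor states:")
    print(centroids.round(2).merge(states, on="condition").to_string(index=False))


if __name__ == "__main__":
    main()
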