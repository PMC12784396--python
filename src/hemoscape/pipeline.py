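"""End-to-end orchestration of the five analysis stages.

Stages communicate only through files in the output directory, so each is
independently re-runnable:

1. ``synthetic_data`` — readout pools (CSV), per-condition fluorescence
   images (TIFF), RNA-seq counts (TSV) with sample sheet and truth labels;
2. ``pseudocytometry`` — segmentation + k-means classification per image,
   apoptotic fractions;
3. ``biochem`` — TBARS absorbance table → MDA μM g⁻¹ (round trip through
   the Beer–Lambert conversion, protein normalization, control centring);
4. ``genescores`` — VST, DE ranking, top-K heme-response set, per-sample
   scores, score–score correlations;
5. ``bootpca`` — pseudoslices, z-scaling, PCA, orientation, centroids,
   attractor states.

A JSON manifest (config echo, derived seeds, row counts, output hashes)
makes any run reproducible bit-for-bit from its config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biochem, bootpca, genescores, pseudocytometry
from .synthetic_data import (
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

log = logging.getLogger("hemoscape")

_FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """Pipeline constants; defaults match the study's published settings
    (B = 250 bootstrap replicates, top-50 gene set, k-means k = 2,
    ε = 156 mM⁻¹ cm⁻¹)."""

    seed: int = 7
    out_dir: Path = Path("results/pipeline")
    replicates: int = 250
    k_top_genes: int = 50
    kmeans_k: int = 2
    epsilon_tbars: float = 156.0
    control: str = "Ctrl"
    images_per_condition: int = 2
    cells_per_image: int = 80
    image_shape: tuple[int, int] = (256, 256)
    n_genes: int = 2000
    samples_per_condition: int = 8
    preset_overrides: Path | None = None

    def __post_init__(self) -> None:
        for name in (
            "replicates",
            "k_top_genes",
            "kmeans_k",
            "epsilon_tbars",
            "images_per_condition",
            "cells_per_image",
            "n_genes",
            "samples_per_condition",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "image_shape" in raw:
            raw["image_shape"] = tuple(raw["image_shape"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(5)
    names = ("synthetic_data", "pseudocytometry", "biochem", "genescores", "bootpca")
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(names, children)
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stage_seeds": seeds,
        "stats": {},
        "outputs": {},
    }
    outputs: list[Path] = []

    def _run_stage(name, fn):
        start = time.perf_counter()
        try:
            fn()
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - start)

    # -- stage 1: synthetic data -------------------------------------------
    images_dir = out / "images"

    def _synthetic() -> None:
        images_dir.mkdir(exist_ok=True)
        presets = presets_frame()
        _write_csv(presets, out / "presets.csv")
        pools = generate_pools(seed=seeds["synthetic_data"])
        _write_csv(pools, out / "pools.csv")
        image_seeds = np.random.SeedSequence(seeds["synthetic_data"]).spawn(
            len(CONDITIONS) * config.images_per_condition
        )
        index = []
        i = 0
        for condition in CONDITIONS:
            fraction = get_preset(condition, "cell_death").mean
            for rep in range(config.images_per_condition):
                spec = SyntheticImageSpec(
                    n_cells=config.cells_per_image,
                    apoptotic_fraction=fraction,
                    image_shape=config.image_shape,
                    seed=int(image_seeds[i].generate_state(1)[0] % 2**31),
                )
                nuclei, neun, casp3, truth = generate_image(spec)
                prefix = images_dir / f"{condition}_{rep + 1:02d}"
                write_image_channels(prefix, nuclei, neun, casp3)
                _write_csv(truth, Path(f"{prefix}_truth.csv"))
                index.append(
                    {"image": prefix.name, "condition": condition, "rep": rep + 1}
                )
                i += 1
        _write_csv(pd.DataFrame(index), out / "image_index.csv")
        design = SyntheticCountDesign(
            n_genes=config.n_genes,
            samples_per_condition=config.samples_per_condition,
            seed=seeds["synthetic_data"],
        )
        counts, samples, truth_genes = generate_counts(design)
        counts.to_csv(out / "counts.tsv", sep="\t")
        _write_csv(samples, out / "samples.csv")
        _write_csv(truth_genes, out / "gene_truth.csv")
        manifest["stats"]["n_pool_values"] = int(len(pools))
        manifest["stats"]["n_images"] = len(index)
        outputs.extend(
            [out / "presets.csv", out / "pools.csv", out / "image_index.csv",
             out / "counts.tsv", out / "samples.csv", out / "gene_truth.csv"]
        )

    _run_stage("synthetic_data", _synthetic)

    # -- stage 2: pseudocytometry ------------------------------------------
    def _pseudocyto() -> None:
        import tifffile

        index = pd.read_csv(out / "image_index.csv")
        results, names = [], []
        for _, row in index.iterrows():
            prefix = images_dir / row["image"]
            nuclei = tifffile.imread(f"{prefix}_nuclei.tif")
            neun = tifffile.imread(f"{prefix}_neun.tif")
            casp3 = tifffile.imread(f"{prefix}_casp3.tif")
            cells = pseudocytometry.segment_cells(nuclei, neun, casp3, min_area=20)
            result = pseudocytometry.classify_cells(
                cells, seed=seeds["pseudocytometry"]
            )
            results.append(result)
            names.append(row["image"])
        fractions = pseudocytometry.apoptotic_fraction_by_image(results, names)
        fractions = fractions.merge(
            index.rename(columns={"image": "image"}), on="image"
        )
        _write_csv(fractions, out / "apoptotic_fractions.csv")
        all_cells = pd.concat(
            [
                pseudocytometry.cells_to_frame(r).assign(image=n)
                for r, n in zip(results, names)
            ],
            ignore_index=True,
        )
        _write_csv(all_cells, out / "cells.csv")
        manifest["stats"]["n_cells_total"] = int(all_cells.shape[0])
        outputs.extend([out / "apoptotic_fractions.csv", out / "cells.csv"])

    _run_stage("pseudocytometry", _pseudocyto)

    # -- stage 3: biochem ---------------------------------------------------
    def _biochem() -> None:
        pools = pd.read_csv(out / "pools.csv")
        mda = pools[pools["readout"] == "mda"].reset_index(drop=True)
        # Reconstruct plausible raw assay inputs from the centred μM g⁻¹ pool
        # values (+2 shifts them onto a positive raw scale; 3 mg protein per
        # homogenate), then convert back through the Beer–Lambert pipeline.
        protein_g = 0.003
        raw_um = (mda["value"] + 2.0) * protein_g
        a600 = 0.05
        epsilon = config.epsilon_tbars
        a532 = (
            raw_um / (1000.0 * biochem.DEFAULT_DILUTION) * epsilon * 1.0 + a600
        )
        table = pd.DataFrame(
            {
                "sample_id": [f"tbars{i:03d}" for i in range(len(mda))],
                "condition": mda["condition"],
                "a532": a532,
                "a600": a600,
                "protein_g": protein_g,
            }
        )
        table["mda_um"] = [
            biochem.mda_concentration(
                biochem.TbarsMeasurement(a532=row.a532, a600=row.a600, epsilon=epsilon)
            )
            for row in table.itertuples()
        ]
        table["mda_um_per_g"] = [
            biochem.normalize_to_protein(c, p)
            for c, p in zip(table["mda_um"], table["protein_g"])
        ]
        ctrl_mean = table.loc[table["condition"] == config.control, "mda_um_per_g"].mean()
        table["mda_centered"] = biochem.center_to_control(
            table["mda_um_per_g"], ctrl_mean
        )
        _write_csv(table, out / "mda.csv")
        manifest["stats"]["mda_ctrl_mean_um_per_g"] = float(ctrl_mean)
        outputs.append(out / "mda.csv")

    _run_stage("biochem", _biochem)

    # -- stage 4: gene scores ----------------------------------------------
    def _genescores() -> None:
        counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col=0)
        samples = pd.read_csv(out / "samples.csv")
        truth = pd.read_csv(out / "gene_truth.csv")
        vst_matrix = genescores.vst(counts)
        labels = samples.set_index("sample").loc[counts.columns, "condition"].to_numpy()
        de = genescores.rank_de(vst_matrix, labels, "HemeAlb", config.control)
        _write_csv(de, out / "de_hemealb_vs_ctrl.csv")
        heme_set = genescores.build_score_set(de, k=config.k_top_genes)
        metab_genes = truth.loc[truth["program"] == "heme_metab", "gene"].tolist()
        stress_genes = truth.loc[truth["program"] == "heme_stress", "gene"].tolist()
        genescores.write_gmt(
            {
                "heme_response": heme_set,
                "heme_metab_truth": metab_genes,
                "heme_stress_truth": stress_genes,
            },
            out / "gene_sets.gmt",
        )
        scores = {
            "heme_stress": genescores.score_samples(vst_matrix, heme_set, "heme_stress"),
            "nrf2_proxy": genescores.score_samples(
                vst_matrix, stress_genes, "nrf2_proxy"
            ),
            "heme_metab": genescores.score_samples(
                vst_matrix, metab_genes, "heme_metab"
            ),
        }
        long = pd.concat(
            [
                pd.DataFrame(
                    {
                        "sample": s.per_sample_score.index,
                        "condition": labels,
                        "set_name": name,
                        "score": s.per_sample_score.to_numpy(),
                    }
                )
                for name, s in scores.items()
            ],
            ignore_index=True,
        )
        _write_csv(long, out / "scores.csv")
        manifest["stats"]["r2_stress_vs_program"] = genescores.score_correlation(
            scores["heme_stress"], scores["nrf2_proxy"]
        )
        manifest["stats"]["r2_stress_vs_metab"] = genescores.score_correlation(
            scores["heme_stress"], scores["heme_metab"]
        )
        manifest["stats"]["heme_set_size"] = len(heme_set)
        outputs.extend(
            [out / "de_hemealb_vs_ctrl.csv", out / "gene_sets.gmt", out / "scores.csv"]
        )

    _run_stage("genescores", _genescores)

    # -- stage 5: bootstrap PCA --------------------------------------------
    def _bootpca() -> None:
        pools = bootpca.ReadoutPools.from_frame(pd.read_csv(out / "pools.csv"))
        matrix = bootpca.make_pseudoslices(
            pools, B=config.replicates, seed=seeds["bootpca"]
        )
        _write_csv(matrix.frame, out / "pseudoslices.csv")
        result = bootpca.orient_components(bootpca.run_pca(bootpca.zscale(matrix)))
        bootpca.loadings_frame(result).to_csv(
            out / "loadings.csv", float_format=_FLOAT_FORMAT
        )
        _write_csv(
            pd.DataFrame(
                {
                    "component": [f"PC{i + 1}" for i in range(5)],
                    "explained_fraction": result.explained_fraction,
                }
            ),
            out / "explained.csv",
        )
        centroids = bootpca.condition_centroids(result)
        _write_csv(centroids, out / "centroids.csv")
        states = bootpca.classify_attractors(centroids, config.control)
        _write_csv(states, out / "attractors.csv")
        manifest["stats"]["pseudoslice_rows"] = int(matrix.values.shape[0])
        manifest["stats"]["pc1_explained"] = float(result.explained_fraction[0])
        manifest["stats"]["pc2_explained"] = float(result.explained_fraction[1])
        outputs.extend(
            [
                out / "pseudoslices.csv",
                out / "loadings.csv",
                out / "explained.csv",
                out / "centroids.csv",
                out / "attractors.csv",
            ]
        )

    _run_stage("bootpca", _bootpca)

    manifest["outputs"] = {str(p.relative_to(out)): _sha256(p) for p in outputs}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
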