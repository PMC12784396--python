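"""Negative-binomial count-matrix generator with spiked gene programs.

Emulates the bulk RNA-seq arm of the slice experiments: a gene × sample
count matrix over the five exposure conditions, with two disjoint gene
programs differentially expressed on top of a common baseline:

* ``heme_stress`` — the oxidative heme-stress response program, induced by
  free toxins and super-induced by HbHp, suppressed below control by
  heme-Hpx;
* ``heme_metab`` — the Nrf2-centred heme-metabolism/adaptation program,
  strongly induced only by HbHp.

Counts are NB(mean μ, dispersion α) with var = μ + αμ²; program genes get
their condition's log2 fold change applied multiplicatively to μ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .readouts import CONDITIONS

_DEFAULT_LFC: dict[str, dict[str, float]] = {
    "heme_stress": {"Ctrl": 0.0, "HemeAlb": 1.5, "HemeHpx": -0.3, "Hb": 2.0, "HbHp": 2.5},
    "heme_metab": {"Ctrl": 0.0, "HemeAlb": 0.2, "HemeHpx": 0.0, "Hb": 0.3, "HbHp": 2.0},
}


@dataclass
class SyntheticCountDesign:
    """Design of the synthetic RNA-seq experiment.

    ``program_log2fc`` maps program name → {condition → log2 fold change
    versus baseline}; the defaults encode the published ordinal structure
    (heme-stress: HemeHpx < Ctrl < HemeAlb < Hb < HbHp; heme-metabolism
    elevated only for HbHp relative to the free toxins).
    """

    n_genes: int = 2000
    samples_per_condition: int = 8
    library_size: float = 2_000_000.0
    dispersion: float = 0.1
    program_gene_counts: tuple[int, int] = (100, 80)
    program_log2fc: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_LFC.items()}
    )
    conditions: tuple[str, ...] = CONDITIONS
    seed: int = 0

    def __post_init__(self) -> None:
        n_stress, n_metab = self.program_gene_counts
        if min(n_stress, n_metab) < 50:
            raise ValueError("each program needs >= 50 genes")
        if n_stress + n_metab > self.n_genes:
            raise ValueError("programs exceed n_genes — gene sets would overlap")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.samples_per_condition < 2:
            raise ValueError("need >= 2 samples per condition")
        for program in ("heme_stress", "heme_metab"):
            lfc = self.program_log2fc[program]
            missing = set(self.conditions) - set(lfc)
            if missing:
                raise ValueError(f"{program} log2fc missing conditions {missing}")
        # ordinal structure is enforced only for non-null programs; an
        # all-zero design is a legal null for calibration experiments
        stress = self.program_log2fc["heme_stress"]
        metab = self.program_log2fc["heme_metab"]
        order = ["HemeHpx", "Ctrl", "HemeAlb", "Hb", "HbHp"]
        if set(order) <= set(self.conditions):
            values = [stress[c] for c in order]
            if any(values) and not all(a < b for a, b in zip(values, values[1:])):
                raise ValueError(
                    "heme_stress log2fc must increase over "
                    "HemeHpx < Ctrl < HemeAlb < Hb < HbHp"
                )
            if any(metab.values()) and not (
                metab["HbHp"] > metab["Hb"] and metab["HbHp"] > metab["HemeAlb"]
            ):
                raise ValueError("heme_metab log2fc must be highest for HbHp")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"gene{i:0{width}d}" for i in range(n)]


def generate_counts(
    design: SyntheticCountDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (counts, sample sheet, truth labels).

    ``counts`` is genes × samples; ``samples`` has columns
    ``sample, condition``; ``truth`` has ``gene, program`` where program is
    ``heme_stress``, ``heme_metab`` or ``none``.
    """
    rng = np.random.default_rng(design.seed)
    genes = _gene_names(design.n_genes)
    n_stress, n_metab = design.program_gene_counts
    program = np.array(
        ["heme_stress"] * n_stress
        + ["heme_metab"] * n_metab
        + ["none"] * (design.n_genes - n_stress - n_metab)
    )

    # baseline gene abundances: lognormal profile scaled to the library size
    base = rng.lognormal(mean=0.0, sigma=1.0, size=design.n_genes)
    base = base / base.sum() * design.library_size

    samples, conditions = [], []
    columns = {}
    lfc_columns = {}
    n_nb = 1.0 / design.dispersion
    for condition in design.conditions:
        lfc = np.zeros(design.n_genes)
        lfc[program == "heme_stress"] = design.program_log2fc["heme_stress"][condition]
        lfc[program == "heme_metab"] = design.program_log2fc["heme_metab"][condition]
        lfc_columns[f"log2fc_{condition}"] = lfc
        mu = base * np.exp2(lfc)
        for rep in range(design.samples_per_condition):
            name = f"{condition}_{rep + 1:02d}"
            p = n_nb / (n_nb + mu)
            columns[name] = rng.negative_binomial(n_nb, p)
            samples.append(name)
            conditions.append(condition)

    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    sample_sheet = pd.DataFrame({"sample": samples, "condition": conditions})
    truth = pd.DataFrame({"gene": genes, "program": program, **lfc_columns})
    return counts, sample_sheet, truth
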