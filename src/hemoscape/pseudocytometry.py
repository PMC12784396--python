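"""Pseudocytometric neuronal-death quantification.

Flow-cytometry-style analysis of segmented fluorescence images: nuclei are
segmented by Otsu thresholding and connected components, per-cell mean NeuN
and cleaved-Caspase-3 intensities are extracted, and cells are classified
into apoptotic (Casp3-high/NeuN-low) versus viable (Casp3-low/NeuN-high)
populations by k-means (k = 2) on log-transformed intensities.  The
per-image apoptotic fraction is the neuronal cell-death index fed into the
downstream multivariate integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from sklearn.cluster import KMeans

APOPTOTIC = "apoptotic"
VIABLE = "viable"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell with its intensity features.

    ``log_neun``/``log_casp3`` are log10(intensity + 1); the pseudocount
    keeps zero-intensity cells finite.  Coordinates are 0-based (row, col).
    """

    cell_id: int
    centroid: tuple[float, float]
    area: int
    neun_mean: float
    casp3_mean: float
    label: str = UNASSIGNED

    @property
    def log_neun(self) -> float:
        return math.log10(self.neun_mean + 1.0)

    @property
    def log_casp3(self) -> float:
        return math.log10(self.casp3_mean + 1.0)


@dataclass(frozen=True)
class ClassificationResult:
    """k-means classification of one image's cells into two populations."""

    cells: tuple[CellRecord, ...]
    k: int
    cluster_centers: dict[str, tuple[float, float]]  # label -> (log_neun, log_casp3)
    apoptotic_fraction: float
    n_cells: int


def segment_cells(
    nuclei_image: np.ndarray,
    neun_image: np.ndarray,
    casp3_image: np.ndarray,
    min_area: int = 20,
) -> list[CellRecord]:
    """Segment nuclei and measure per-cell channel intensities.

    Otsu threshold on the nuclei channel → connected components → minimum
    size filter → per-component mean intensity in the NeuN and Casp3
    channels.  Deterministic.  A blank (constant) nuclei image yields an
    empty list; a channel shape mismatch raises ``ValueError``.
    """
    nuclei = np.asarray(nuclei_image, dtype=float)
    neun = np.asarray(neun_image, dtype=float)
    casp3 = np.asarray(casp3_image, dtype=float)
    if not (nuclei.shape == neun.shape == casp3.shape):
        raise ValueError(
            f"channel shapes differ: {nuclei.shape}, {neun.shape}, {casp3.shape}"
        )
    if nuclei.max() == nuclei.min():
        return []
    mask = nuclei > threshold_otsu(nuclei)
    labeled = cc_label(mask)
    records: list[CellRecord] = []
    cell_id = 0
    for region in regionprops(labeled):
        if region.area < min_area:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        records.append(
            CellRecord(
                cell_id=cell_id,
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                area=int(region.area),
                neun_mean=float(neun[rr, cc].mean()),
                casp3_mean=float(casp3[rr, cc].mean()),
            )
        )
        cell_id += 1
    return records


def _canonical_order(features: np.ndarray) -> np.ndarray:
    """Sort rows by (log_neun, log_casp3) so clustering ignores input order."""
    return np.lexsort((features[:, 1], features[:, 0]))


def classify_cells(cells: list[CellRecord], seed: int = 0) -> ClassificationResult:
    """k-means (k = 2) classification on (log NeuN, log Casp3) features.

    The cluster with the higher mean log Casp3 is labeled apoptotic (ties
    broken toward the lower mean log NeuN).  Features are processed in a
    canonical sort order, so the result is invariant to cell ordering.
    Raises on fewer than 2 cells or on all-identical feature vectors.
    """
    if len(cells) < 2:
        raise ValueError(f"need >= 2 cells to cluster, got {len(cells)}")
    features = np.array([(c.log_neun, c.log_casp3) for c in cells])
    if np.allclose(features, features[0]):
        raise ValueError("all cells have identical features; k-means is degenerate")

    order = _canonical_order(features)
    km = KMeans(n_clusters=2, n_init=10, init="k-means++", random_state=seed)
    sorted_labels = km.fit_predict(features[order])
    raw_labels = np.empty(len(cells), dtype=int)
    raw_labels[order] = sorted_labels

    centers = km.cluster_centers_  # columns: (log_neun, log_casp3)
    if centers[0, 1] > centers[1, 1]:
        apoptotic_cluster = 0
    elif centers[0, 1] < centers[1, 1]:
        apoptotic_cluster = 1
    else:  # Casp3 tie: apoptotic is the NeuN-low cluster
        apoptotic_cluster = int(centers[1, 0] < centers[0, 0])

    labeled = tuple(
        replace(cell, label=APOPTOTIC if raw == apoptotic_cluster else VIABLE)
        for cell, raw in zip(cells, raw_labels)
    )
    n_apoptotic = sum(c.label == APOPTOTIC for c in labeled)
    return ClassificationResult(
        cells=labeled,
        k=2,
        cluster_centers={
            APOPTOTIC: tuple(centers[apoptotic_cluster]),
            VIABLE: tuple(centers[1 - apoptotic_cluster]),
        },
        apoptotic_fraction=n_apoptotic / len(labeled),
        n_cells=len(labeled),
    )


def apoptotic_fraction_by_image(
    results: list[ClassificationResult],
    image_names: list[str] | None = None,
) -> pd.DataFrame:
    """One row per image: apoptotic fraction and cell count."""
    if not results:
        raise ValueError("no classification results given")
    if image_names is None:
        image_names = [f"image{i:02d}" for i in range(len(results))]
    return pd.DataFrame(
        {
            "image": image_names,
            "fraction": [r.apoptotic_fraction for r in results],
            "n_cells": [r.n_cells for r in results],
        }
    )


def summarize_fractions(table: pd.DataFrame) -> tuple[float, float]:
    """Pooled condition summary: mean ± SD of per-image fractions."""
    return float(table["fraction"].mean()), float(table["fraction"].std(ddof=1))


def cells_to_frame(result: ClassificationResult) -> pd.DataFrame:
    """Flatten a classification result for CSV export."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in result.cells],
            "row": [c.centroid[0] for c in result.cells],
            "col": [c.centroid[1] for c in result.cells],
            "area": [c.area for c in result.cells],
            "neun_mean": [c.neun_mean for c in result.cells],
            "casp3_mean": [c.casp3_mean for c in result.cells],
            "label": [c.label for c in result.cells],
        }
    )
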