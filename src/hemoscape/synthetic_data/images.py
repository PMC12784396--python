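"""Synthetic two-channel fluorescence images for the pseudocytometry stage.

Renders non-overlapping disk-shaped cells on a flat background in three
16-bit channels (nuclei, NeuN, cleaved Caspase-3).  Two intensity
populations are mixed at a known fraction: apoptotic cells are
Casp3-high/NeuN-low, viable cells are Casp3-low/NeuN-high.  Per-cell
intensities vary normally around the population mean (coefficient of
variation per channel) and pixels carry additive Gaussian shot-like noise.

This is a fixture generator, not a microscope model: no PSF, no
autofluorescence, no overlapping or irregular cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk

_U16_MAX = 65535

#: Default population means as (NeuN, Casp3) intensity pairs.
_DEFAULT_MEANS = {"viable": (3000.0, 300.0), "apoptotic": (300.0, 3000.0)}


class PackingError(ValueError):
    """Requested cell count cannot be placed without overlap."""


@dataclass
class SyntheticImageSpec:
    """Parameters of one synthetic slice image.

    ``channel_means`` maps population → (NeuN, Casp3) mean intensities; the
    apoptotic population must be Casp3-brighter and NeuN-dimmer than the
    viable one.  ``channel_cv`` is the per-cell coefficient of variation for
    (NeuN, Casp3).  Pixel noise has SD = 5% of the cell intensity.
    """

    n_cells: int = 100
    apoptotic_fraction: float = 0.5
    image_shape: tuple[int, int] = (512, 512)
    channel_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MEANS)
    )
    channel_cv: tuple[float, float] = (0.10, 0.10)
    background_level: float = 100.0
    cell_radius: int = 6
    nuclei_mean: float = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.apoptotic_fraction <= 1.0:
            raise ValueError("apoptotic_fraction must lie in [0, 1]")
        va, vc = self.channel_means["viable"]
        aa, ac = self.channel_means["apoptotic"]
        if not (ac > vc and aa < va):
            raise ValueError(
                "apoptotic population must have higher Casp3 and lower NeuN "
                "mean than the viable population"
            )
        for value in (va, vc, aa, ac, self.background_level, self.nuclei_mean):
            if not 0 <= value <= _U16_MAX:
                raise ValueError("intensities must fit the 16-bit range")


def _apoptotic_count(fraction: float, n_cells: int) -> int:
    """Round-half-up mixing count."""
    return int(math.floor(fraction * n_cells + 0.5))


def _place_centers(
    rng: np.random.Generator, spec: SyntheticImageSpec
) -> np.ndarray:
    """Rejection-sample non-overlapping disk centers; error when infeasible."""
    h, w = spec.image_shape
    r = spec.cell_radius
    min_dist = 2 * r + 2
    # crude square-packing capacity bound, refused up front
    capacity = max(0, (h - 2 * r) // min_dist) * max(0, (w - 2 * r) // min_dist)
    if spec.n_cells > capacity:
        raise PackingError(
            f"cannot pack {spec.n_cells} cells of radius {r} into "
            f"{h}x{w} (capacity ~{capacity})"
        )
    centers: list[tuple[int, int]] = []
    max_attempts = 200 * spec.n_cells
    attempts = 0
    while len(centers) < spec.n_cells:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed only {len(centers)}/{spec.n_cells} cells after "
                f"{max_attempts} attempts; reduce density"
            )
        attempts += 1
        row = int(rng.integers(r + 1, h - r - 1))
        col = int(rng.integers(r + 1, w - r - 1))
        if all(
            (row - cr) ** 2 + (col - cc) ** 2 >= min_dist**2 for cr, cc in centers
        ):
            centers.append((row, col))
    return np.asarray(centers, dtype=int)


def generate_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one synthetic field.

    Returns ``(nuclei, neun, casp3, truth)`` where the three images are
    uint16 arrays of ``spec.image_shape`` and ``truth`` has one row per cell
    with columns ``cell_id, row, col, population, true_fraction``.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(rng, spec)
    n_apo = _apoptotic_count(spec.apoptotic_fraction, spec.n_cells)
    populations = np.array(
        ["apoptotic"] * n_apo + ["viable"] * (spec.n_cells - n_apo)
    )

    h, w = spec.image_shape
    nuclei = np.full((h, w), spec.background_level, dtype=float)
    neun = np.full((h, w), spec.background_level, dtype=float)
    casp3 = np.full((h, w), spec.background_level, dtype=float)

    cv_neun, cv_casp3 = spec.channel_cv
    for (row, col), pop in zip(centers, populations):
        rr, cc = disk((row, col), spec.cell_radius, shape=(h, w))
        mean_neun, mean_casp3 = spec.channel_means[pop]
        # per-cell intensity heterogeneity, then per-pixel noise
        cell_nuc = max(rng.normal(spec.nuclei_mean, 0.1 * spec.nuclei_mean), 1.0)
        cell_neun = max(rng.normal(mean_neun, cv_neun * mean_neun), 0.0)
        cell_casp3 = max(rng.normal(mean_casp3, cv_casp3 * mean_casp3), 0.0)
        nuclei[rr, cc] = cell_nuc + rng.normal(0.0, 0.05 * cell_nuc, rr.size)
        neun[rr, cc] = cell_neun + rng.normal(0.0, 0.05 * max(cell_neun, 1.0), rr.size)
        casp3[rr, cc] = cell_casp3 + rng.normal(
            0.0, 0.05 * max(cell_casp3, 1.0), rr.size
        )

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(spec.n_cells),
            "row": centers[:, 0],
            "col": centers[:, 1],
            "population": populations,
            "true_fraction": n_apo / spec.n_cells,
        }
    )

    def _to_u16(img: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(img), 0, _U16_MAX).astype(np.uint16)

    return _to_u16(nuclei), _to_u16(neun), _to_u16(casp3), truth


def write_image_channels(
    prefix, nuclei: np.ndarray, neun: np.ndarray, casp3: np.ndarray
) -> list:
    """Write the three channels as 16-bit grayscale TIFFs, one per channel."""
    import tifffile

    paths = []
    for name, img in (("nuclei", nuclei), ("neun", neun), ("casp3", casp3)):
        path = f"{prefix}_{name}.tif"
        tifffile.imwrite(path, img)
        paths.append(path)
    return paths
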