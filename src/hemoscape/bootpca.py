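"""Bootstrap-pseudoslice PCA: the multivariate integrator.

Each destructive assay (iron deposition, lipid peroxidation, heme-stress
score, heme-metabolism score, neuronal death) consumes the slice it
measures, so no slice carries all five readouts.  The integrator builds
*pseudoslices*: for each condition, B bootstrap replicates are assembled by
drawing one value per readout, with replacement, from that condition's
empirical pool.  The resulting (5·B) × 5 matrix is z-scaled globally and
decomposed by PCA, yielding an oxidative-toxicity axis (PC1: iron, MDA,
cell death, heme-stress score co-loading) and a metabolic-adaptation axis
(PC2: dominated by the heme-metabolism score).  Component signs are
oriented so the iron loading on PC1 and the heme-metabolism loading on PC2
are non-negative.  Condition centroids with percentile bootstrap intervals
are then classified into attractor states (Baseline, Toxic, Adaptive,
Sequestered) relative to the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synthetic_data.readouts import CONDITIONS, READOUTS

DEFAULT_B = 250

BASELINE = "Baseline"
TOXIC = "Toxic"
ADAPTIVE = "Adaptive"
SEQUESTERED = "Sequestered"


@dataclass(frozen=True)
class ReadoutPools:
    """Per-(condition, readout) empirical value pools."""

    pools: dict[tuple[str, str], np.ndarray]
    conditions: tuple[str, ...] = CONDITIONS
    readouts: tuple[str, ...] = READOUTS

    def __post_init__(self) -> None:
        for condition in self.conditions:
            for readout in self.readouts:
                pool = self.pools.get((condition, readout))
                if pool is None or len(pool) == 0:
                    raise ValueError(f"empty pool for ({condition}, {readout})")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        conditions: tuple[str, ...] | None = None,
        readouts: tuple[str, ...] | None = None,
    ) -> "ReadoutPools":
        """Build pools from a long table with columns condition, readout, value."""
        conditions = conditions or tuple(
            c for c in CONDITIONS if c in set(frame["condition"])
        ) or tuple(pd.unique(frame["condition"]))
        readouts = readouts or tuple(
            r for r in READOUTS if r in set(frame["readout"])
        ) or tuple(pd.unique(frame["readout"]))
        pools = {
            (c, r): g["value"].to_numpy(dtype=float)
            for (c, r), g in frame.groupby(["condition", "readout"], sort=False)
        }
        return cls(pools=pools, conditions=tuple(conditions), readouts=tuple(readouts))


@dataclass(frozen=True)
class PseudosliceMatrix:
    """Bootstrap pseudoslice matrix: (conditions × B) rows, one column per readout."""

    values: np.ndarray
    condition_labels: np.ndarray
    readouts: tuple[str, ...]
    B: int
    scaled: bool = False
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.readouts))
        df.insert(0, "condition", self.condition_labels)
        return df


@dataclass(frozen=True)
class PCAResult:
    """PCA of the scaled pseudoslice matrix.

    ``loadings`` is readouts × components (orthonormal columns);
    ``explained_fraction`` sums to 1 and is non-increasing; ``scores`` is
    pseudoslices × components; ``orientation`` records the sign applied to
    each component by :func:`orient_components`.
    """

    loadings: np.ndarray
    explained_fraction: np.ndarray
    scores: np.ndarray
    readouts: tuple[str, ...]
    condition_labels: np.ndarray
    orientation: tuple[int, ...] = field(default=(1, 1, 1, 1, 1))


def make_pseudoslices(
    pools: ReadoutPools, B: int = DEFAULT_B, seed: int = 0
) -> PseudosliceMatrix:
    """Assemble B bootstrap pseudoslices per condition.

    Each pseudoslice draws one value per readout, independently and with
    replacement, from that condition's pools.  One seeded stream is consumed
    in fixed (condition-major, replicate, readout) order, so a fixed seed
    reproduces the matrix exactly.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n_readouts = len(pools.readouts)
    blocks, labels = [], []
    for condition in pools.conditions:
        uniforms = rng.random((B, n_readouts))  # row-major: replicate then readout
        block = np.empty((B, n_readouts))
        for j, readout in enumerate(pools.readouts):
            pool = np.asarray(pools.pools[(condition, readout)], dtype=float)
            idx = np.minimum((uniforms[:, j] * len(pool)).astype(int), len(pool) - 1)
            block[:, j] = pool[idx]
        blocks.append(block)
        labels.extend([condition] * B)
    return PseudosliceMatrix(
        values=np.vstack(blocks),
        condition_labels=np.asarray(labels),
        readouts=pools.readouts,
        B=B,
    )


def zscale(m: PseudosliceMatrix) -> PseudosliceMatrix:
    """Z-scale every column globally (over all conditions' rows).

    Centering/scaling uses the grand column mean and SD (ddof = 1) of the
    full matrix — one matrix-level operation, not per condition.  Raises if
    the matrix is already scaled or if any column has zero variance.
    """
    if m.scaled:
        raise ValueError("matrix is already z-scaled")
    means = m.values.mean(axis=0)
    sds = m.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [m.readouts[j] for j in zero]
        raise ValueError(f"zero-variance readout column(s): {names}")
    return replace(
        m,
        values=(m.values - means) / sds,
        scaled=True,
        column_means=means,
        column_sds=sds,
    )


def run_pca(m: PseudosliceMatrix) -> PCAResult:
    """PCA of the scaled matrix via SVD.

    Equivalent to the eigendecomposition of the sample covariance matrix
    (divisor n − 1): loadings are the covariance eigenvectors sorted by
    descending eigenvalue, explained fractions are eigenvalue / trace, and
    scores are the scaled data projected onto the loadings.
    """
    if not m.scaled:
        raise ValueError("matrix must be z-scaled before PCA")
    n, p = m.values.shape
    if n < p:
        raise ValueError(f"need at least as many rows ({n}) as columns ({p})")
    # columns already have mean 0; SVD of X gives cov eigenvectors in V
    _, singular, vt = np.linalg.svd(m.values, full_matrices=False)
    eigenvalues = singular**2 / (n - 1)
    return PCAResult(
        loadings=vt.T,
        explained_fraction=eigenvalues / eigenvalues.sum(),
        scores=m.values @ vt.T,
        readouts=m.readouts,
        condition_labels=m.condition_labels,
        orientation=tuple([1] * p),
    )


def orient_components(
    p: PCAResult, pc1_anchor: str = "fe58", pc2_anchor: str = "heme_metab"
) -> PCAResult:
    """Fix the arbitrary PCA signs to the biplot convention.

    Flips component signs so the ``pc1_anchor`` loading on PC1 and the
    ``pc2_anchor`` loading on PC2 are non-negative (toxicity increases
    rightward, adaptation upward).  Scores flip consistently; applied signs
    are recorded in ``orientation``.  A zero anchor loading leaves that
    component untouched.
    """
    signs = np.array(p.orientation, dtype=int)
    flips = np.ones(p.loadings.shape[1], dtype=int)
    anchors = {0: p.readouts.index(pc1_anchor), 1: p.readouts.index(pc2_anchor)}
    for component, row in anchors.items():
        if p.loadings[row, component] < 0:
            flips[component] = -1
    return replace(
        p,
        loadings=p.loadings * flips,
        scores=p.scores * flips,
        orientation=tuple(signs * flips),
    )


def condition_centroids(
    p: PCAResult,
    labels: np.ndarray | None = None,
    conditions: tuple[str, ...] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-condition centroid on PC1/PC2 with percentile bootstrap intervals.

    Returns one row per condition with the mean score and the
    (2.5–97.5 by default) percentile interval over that condition's
    pseudoslices, for each of the first two components.
    """
    labels = p.condition_labels if labels is None else np.asarray(labels)
    if labels.shape[0] != p.scores.shape[0]:
        raise ValueError("labels must align with the score rows")
    if conditions is None:
        conditions = tuple(dict.fromkeys(labels))
    unknown = set(labels) - set(conditions)
    if unknown:
        raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    tail = 100 * (1 - level) / 2
    rows = []
    for condition in conditions:
        scores = p.scores[labels == condition, :2]
        lo, hi = np.percentile(scores, [tail, 100 - tail], axis=0)
        rows.append(
            {
                "condition": condition,
                "pc1_mean": scores[:, 0].mean(),
                "pc1_lo": lo[0],
                "pc1_hi": hi[0],
                "pc2_mean": scores[:, 1].mean(),
                "pc2_lo": lo[1],
                "pc2_hi": hi[1],
            }
        )
    return pd.DataFrame(rows)


def _overlaps(lo1: float, hi1: float, lo2: float, hi2: float) -> bool:
    return lo1 <= hi2 and lo2 <= hi1


def classify_attractors(
    centroids: pd.DataFrame, control_label: str = "Ctrl"
) -> pd.DataFrame:
    """Map each condition to an attractor state relative to the control.

    Rule (deterministic, interval-based):

    * **Baseline** — the control itself;
    * **Toxic** — PC1 interval entirely above the control's;
    * **Adaptive** — not Toxic, PC2 interval entirely above the control's;
    * **Sequestered** — any other treated condition (intervals overlap the
      control's despite toxin exposure, or sit below it).
    """
    indexed = centroids.set_index("condition")
    if control_label not in indexed.index:
        raise ValueError(f"control condition {control_label!r} missing")
    ctrl = indexed.loc[control_label]
    rows = []
    for condition, row in indexed.iterrows():
        if condition == control_label:
            state = BASELINE
        elif row["pc1_lo"] > ctrl["pc1_hi"]:
            state = TOXIC
        elif row["pc2_lo"] > ctrl["pc2_hi"]:
            state = ADAPTIVE
        else:
            state = SEQUESTERED
        rows.append({"condition": condition, "state": state})
    return pd.DataFrame(rows)


def loadings_frame(p: PCAResult) -> pd.DataFrame:
    """Loadings as a readout × PC table for export."""
    return pd.DataFrame(
        p.loadings,
        index=pd.Index(p.readouts, name="readout"),
        columns=[f"PC{i + 1}" for i in range(p.loadings.shape[1])],
    )
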