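"""Transcriptional stress/adaptation scoring on bulk RNA-seq counts.

The pipeline: variance-stabilizing transform (median-of-ratios size factors
then log2(normalized + 1)), a minimal differential-expression ranker
(per-gene Welch t-test on VST values with Benjamini–Hochberg adjustment —
a documented stand-in for DESeq2/apeglm, which is deliberately not
reimplemented), construction of the top-K up-regulated gene set (the
"heme response score" set), per-sample mean VST scoring over a gene set,
and squared Pearson correlation between two scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style).

    The geometric mean per gene is taken over genes expressed in every
    sample; each sample's factor is the median ratio of its counts to those
    geometric means.
    """
    if counts.empty:
        raise ValueError("empty count matrix")
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene is expressed in every sample; cannot normalize")
    log_values = np.log(values[positive])
    log_geo_mean = log_values.mean(axis=1)
    factors = np.exp(np.median(log_values - log_geo_mean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def vst(counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilized matrix: log2(count / size_factor + 1).

    Genes with all-zero counts pass through as zero rows.  Raises on an
    empty matrix or negative counts.
    """
    if counts.empty:
        raise ValueError("empty count matrix")
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    factors = size_factors(counts)
    return pd.DataFrame(
        np.log2(values / factors.to_numpy() + 1.0),
        index=counts.index,
        columns=counts.columns,
    )


def rank_de(
    vst_matrix: pd.DataFrame,
    group_labels,
    treatment: str,
    control: str,
) -> pd.DataFrame:
    """Per-gene Welch t-test of treatment vs control on VST values.

    Returns a DataFrame with columns ``gene, log2fc, p_value, adj_p,
    mean_expr`` (one row per gene).  ``log2fc`` is the group-mean difference
    on the log2 VST scale; ``adj_p`` is Benjamini–Hochberg.  Genes with zero
    variance in both groups get p = 1.  Deterministic and invariant to
    sample order within groups.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != vst_matrix.shape[1]:
        raise ValueError("group_labels must align with the matrix columns")
    treat = vst_matrix.loc[:, labels == treatment].to_numpy(dtype=float)
    ctrl = vst_matrix.loc[:, labels == control].to_numpy(dtype=float)
    for name, block in ((treatment, treat), (control, ctrl)):
        if block.shape[1] < 2:
            raise ValueError(f"group {name!r} has < 2 samples")

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(treat, ctrl, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    adj_p = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene": vst_matrix.index,
            "log2fc": treat.mean(axis=1) - ctrl.mean(axis=1),
            "p_value": p,
            "adj_p": adj_p,
            "mean_expr": np.concatenate([treat, ctrl], axis=1).mean(axis=1),
        }
    ).reset_index(drop=True)


def build_score_set(
    de: pd.DataFrame, k: int = 50, alpha: float = 0.05
) -> list[str]:
    """Top-k up-regulated differentially expressed genes.

    Filters to adj_p < ``alpha`` and log2fc > 0, sorts by log2fc descending
    (ties broken by gene identifier, ascending), and returns exactly ``k``
    gene names.  Raises reporting the attainable count when fewer qualify.
    """
    qualifying = de[(de["adj_p"] < alpha) & (de["log2fc"] > 0)]
    if len(qualifying) < k:
        raise ValueError(
            f"only {len(qualifying)} significant up-regulated genes available, "
            f"need k={k}"
        )
    ranked = qualifying.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
    )
    return ranked["gene"].head(k).tolist()


@dataclass(frozen=True)
class GeneSetScore:
    """Per-sample mean VST expression over a gene set."""

    set_name: str
    genes: tuple[str, ...]
    per_sample_score: pd.Series  # index: sample names


def score_samples(
    vst_matrix: pd.DataFrame, genes, set_name: str = "score"
) -> GeneSetScore:
    """Unweighted per-sample mean over the gene rows of ``genes``."""
    genes = list(genes)
    if not genes:
        raise ValueError("gene set is empty")
    missing = sorted(set(genes) - set(vst_matrix.index))
    if missing:
        raise KeyError(f"genes absent from the expression matrix: {missing}")
    scores = vst_matrix.loc[genes].mean(axis=0)
    scores.name = set_name
    return GeneSetScore(set_name=set_name, genes=tuple(genes), per_sample_score=scores)


def score_correlation(s1: GeneSetScore, s2: GeneSetScore) -> float:
    """Squared Pearson correlation (r²) of two scores over shared samples."""
    samples1, samples2 = set(s1.per_sample_score.index), set(s2.per_sample_score.index)
    if samples1 != samples2:
        raise ValueError("scores cover different sample sets")
    if len(samples1) < 3:
        raise ValueError("need >= 3 samples for a correlation")
    aligned = s2.per_sample_score.reindex(s1.per_sample_score.index)
    r, _ = stats.pearsonr(s1.per_sample_score.to_numpy(), aligned.to_numpy())
    return float(r**2)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "hemoscape") -> None:
    """Write gene sets to a GMT file."""
    with open(path, "w") as handle:
        for name, genes in sets.items():
            handle.write("\t".join([name, description, *genes]) + "\n")
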