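"""Per-tissue activity statistics, gene filtering and sample/tissue clustering.

A gene with FPKM below 1 in every sample of a tissue is treated as inactive
in that tissue — the conventional FPKM < 1 inactivity rule for bulk RNA-seq.
Tissue-level summaries (mean and median over the tissue's replicate samples)
feed housekeeping- and tissue-specific-gene detection; the median drives
tissue clustering and the log2(FPKM + 1) matrix drives sample PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = [
    "TissueSummary",
    "summarize_by_tissue",
    "gene_activity",
    "activity_report",
    "filter_min_expressed_samples",
    "tissue_correlation_clustering",
    "sample_pca",
]


@dataclass
class TissueSummary:
    """Per-gene per-tissue expression summaries.

    ``mean`` and ``median`` are genes × tissues DataFrames; ``n_samples``
    gives the design's sample count per tissue.
    """

    mean: pd.DataFrame
    median: pd.DataFrame
    n_samples: pd.Series

    @property
    def tissues(self) -> list[str]:
        return list(self.mean.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mean.index)

    def to_long_frame(self) -> pd.DataFrame:
        """One row per (gene, tissue) with mean/median/n_samples columns."""
        long = (
            self.mean.stack().rename("mean_fpkm").to_frame()
            .join(self.median.stack().rename("median_fpkm"))
            .reset_index()
        )
        long.columns = ["gene_id", "tissue", "mean_fpkm", "median_fpkm"]
        long["n_samples"] = self.n_samples.loc[long["tissue"]].to_numpy()
        return long


def summarize_by_tissue(matrix: ExpressionMatrix) -> TissueSummary:
    """Mean and median FPKM per (gene, tissue) over that tissue's samples."""
    if matrix.design is None:
        raise ValueError("summarize_by_tissue requires an attached design")
    groups = matrix.tissue_groups()
    means = {}
    medians = {}
    for tissue, samples in groups.items():
        block = matrix.values[samples].to_numpy()
        means[tissue] = block.mean(axis=1)
        medians[tissue] = np.median(block, axis=1)
    tissues = list(groups)
    mean = pd.DataFrame(means, index=matrix.values.index, columns=tissues)
    median = pd.DataFrame(medians, index=matrix.values.index, columns=tissues)
    n = pd.Series({t: len(s) for t, s in groups.items()}, name="n_samples")
    return TissueSummary(mean, median, n.loc[tissues])


def gene_activity(matrix: ExpressionMatrix,
                  active_threshold: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene per-tissue detection and inactivity status.

    Returns ``(detected, inactive)`` boolean genes × tissues DataFrames:
    detected = FPKM > 0 in at least one sample of the tissue; inactive =
    detected and FPKM < ``active_threshold`` (strict) in every sample.
    """
    if active_threshold <= 0:
        raise ValueError("active_threshold must be positive")
    groups = matrix.tissue_groups()
    detected = {}
    inactive = {}
    for tissue, samples in groups.items():
        block = matrix.values[samples].to_numpy()
        det = (block > 0).any(axis=1)
        detected[tissue] = det
        inactive[tissue] = det & (block < active_threshold).all(axis=1)
    idx = matrix.values.index
    return (pd.DataFrame(detected, index=idx), pd.DataFrame(inactive, index=idx))


def activity_report(matrix: ExpressionMatrix,
                    active_threshold: float = 1.0) -> pd.DataFrame:
    """Per-tissue counts of detected and inactive genes.

    The inactive fraction uses genes detected in the tissue (any positive
    value) as its denominator.
    """
    detected, inactive = gene_activity(matrix, active_threshold)
    n_det = detected.sum(axis=0)
    n_inact = inactive.sum(axis=0)
    frac = np.where(n_det > 0, n_inact / n_det.replace(0, 1), 0.0)
    return pd.DataFrame(
        {
            "tissue": detected.columns,
            "n_detected": n_det.to_numpy(),
            "n_inactive": n_inact.to_numpy(),
            "fraction_inactive": frac,
        }
    )


def filter_min_expressed_samples(matrix: ExpressionMatrix,
                                 min_samples: int = 2) -> ExpressionMatrix:
    """Retain genes expressed (FPKM > 0) in >= ``min_samples`` replicate
    samples of at least one tissue; gene order is preserved."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if matrix.design is None:
        raise ValueError("filter requires an attached design")
    keep = np.zeros(matrix.n_genes, dtype=bool)
    for samples in matrix.tissue_groups().values():
        block = matrix.values[samples].to_numpy()
        keep |= (block > 0).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("no genes pass the replicate-expression filter")
    return ExpressionMatrix(matrix.values.loc[keep], matrix.design)


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(link):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(link) - 1] + ";"


def tissue_correlation_clustering(
    summary: TissueSummary,
    statistic: str = "median",
) -> tuple[pd.DataFrame, np.ndarray, str]:
    """Pearson correlation among tissues and an average-linkage dendrogram.

    Tissue vectors are log2(x + 1)-transformed per-tissue summaries
    (median by default); the dendrogram clusters 1 − r with average
    linkage. Returns (correlation matrix, linkage matrix, Newick string).
    Tissues with a constant vector have undefined correlations and are
    excluded with a warning.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    table = getattr(summary, statistic)
    if table.shape[1] < 2:
        raise ValueError("need at least 2 tissues to cluster")
    logged = np.log2(table + 1.0)
    sd = logged.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"tissues with constant profiles excluded: {constant}")
        logged = logged.drop(columns=constant)
    if logged.shape[1] < 2:
        raise ValueError("fewer than 2 tissues with non-constant profiles")
    corr = logged.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    newick = _linkage_to_newick(link, list(corr.columns))
    return corr, link, newick


def sample_pca(matrix: ExpressionMatrix, n_components: int = 10,
               active_threshold: float = 1.0,
               random_state: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2(FPKM + 1) over genes active somewhere.

    Genes are filtered to FPKM > ``active_threshold`` in at least one
    sample, then centred; returns per-sample scores on the top components
    and the variance-explained fractions.
    """
    from sklearn.decomposition import PCA

    keep = (matrix.values.to_numpy() > active_threshold).any(axis=1)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes pass the PCA activity filter")
    logged = np.log2(matrix.values.loc[keep].to_numpy() + 1.0)
    X = logged.T  # samples × genes; PCA centres features (genes)
    k = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=k, svd_solver="auto", random_state=random_state)
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    frame = pd.DataFrame(scores, index=matrix.values.columns, columns=cols)
    return frame, pca.explained_variance_ratio_
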