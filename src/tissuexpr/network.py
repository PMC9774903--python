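"""Weighted gene co-expression network analysis, written from first principles.

The stages follow the standard unsigned weighted-network construction:

* adjacency ``a_ij = |cor(x_i, x_j)|**beta`` with the soft threshold beta
  chosen as the smallest candidate whose connectivity distribution fits a
  scale-free law with signed R² above a target (default 0.8);
* topological overlap
  ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`` where
  ``L_ij = Σ_u a_iu a_uj`` and ``k_i = Σ_u a_iu``;
* average-linkage hierarchical clustering of ``1 − TOM`` with a
  static-height cut (a quantile of the merge heights) and a minimum module
  size; clusters below the size floor stay unassigned;
* module eigengenes (first principal component of the standardized module
  submatrix, sign-anchored to the member genes), iterative merging of
  modules whose eigengenes are closer than ``merge_cut_height``;
* module–tissue association by Pearson correlation of eigengenes with
  binary tissue indicators, and hub-gene calling by gene significance
  (|GS| > 0.2) and module membership (|MM| > 0.8) inside tissue-specific
  modules (r > 0.65).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = [
    "NetworkConfig",
    "ModuleSet",
    "NetworkResult",
    "filter_for_network",
    "correlation_matrix",
    "adjacency_matrix",
    "scale_free_fit_index",
    "pick_soft_threshold",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "merge_close_modules",
    "module_trait_association",
    "call_hub_genes",
    "build_network",
]

MAX_NETWORK_GENES = 20_000


@dataclass
class NetworkConfig:
    """Thresholds of the network stage (defaults as used throughout)."""

    beta_candidates: tuple[int, ...] = tuple(range(1, 21))
    rsq_target: float = 0.8
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    tissue_module_r: float = 0.65
    gs_min: float = 0.2
    mm_min: float = 0.8
    cut_height_fraction: float = 0.99
    signed: bool = False
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not (0 < self.rsq_target <= 1):
            raise ValueError("rsq_target must lie in (0, 1]")
        if not (0 < self.cut_height_fraction <= 1):
            raise ValueError("cut_height_fraction must lie in (0, 1]")


@dataclass
class ModuleSet:
    """Module assignments plus eigengene summaries.

    ``modules`` maps module id → member gene list (a partition of the
    assigned genes); ``unassigned`` holds the leftover genes ("grey").
    ``eigengenes`` is samples × modules, each column unit-norm.
    """

    modules: dict[str, list[str]]
    unassigned: list[str]
    eigengenes: pd.DataFrame | None = None
    var_explained: dict[str, float] = field(default_factory=dict)
    beta_used: int | None = None
    rsq_achieved: float | None = None

    @property
    def assignment(self) -> pd.Series:
        """Gene → module id Series ('grey' for unassigned)."""
        pairs = {g: m for m, genes in self.modules.items() for g in genes}
        pairs.update({g: "grey" for g in self.unassigned})
        return pd.Series(pairs, name="module_id")

    def module_of(self, gene: str) -> str:
        for m, genes in self.modules.items():
            if gene in genes:
                return m
        return "grey"


# ---------------------------------------------------------------------------
# filtering and adjacency
# ---------------------------------------------------------------------------

def filter_for_network(matrix: ExpressionMatrix, mode: str = "any_tissue",
                       threshold: float = 1.0,
                       min_genes: int = 30) -> ExpressionMatrix:
    """Keep well-expressed genes for network construction.

    ``mode="any_tissue"`` (default) keeps genes with FPKM > threshold in
    every sample of at least one tissue; ``mode="strict"`` requires every
    sample of every tissue. The strict reading leaves very few genes on
    real atlases, hence the default.
    """
    if mode not in ("any_tissue", "strict"):
        raise ValueError("mode must be 'any_tissue' or 'strict'")
    groups = matrix.tissue_groups()
    per_tissue = np.column_stack(
        [
            (matrix.values[samples].to_numpy() > threshold).all(axis=1)
            for samples in groups.values()
        ]
    )
    keep = per_tissue.all(axis=1) if mode == "strict" else per_tissue.any(axis=1)
    if keep.sum() < min_genes:
        raise ValueError(
            f"only {int(keep.sum())} genes pass the '{mode}' network filter "
            f"(need >= {min_genes}); consider mode='any_tissue' or a lower threshold"
        )
    return ExpressionMatrix(matrix.values.loc[keep], matrix.design)


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between gene rows of a genes × samples matrix.

    Constant genes have undefined correlations and are dropped with a
    warning.
    """
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant genes excluded from the network"
        )
        expr = expr.loc[~constant]
        X = X[~constant]
    corr = np.corrcoef(X)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=expr.index, columns=expr.index)


def adjacency_matrix(corr: pd.DataFrame, beta: int,
                     signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded adjacency with zero diagonal.

    Unsigned: |r|^beta. Signed: ((1 + r)/2)^beta.
    """
    r = corr.to_numpy()
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def scale_free_fit_index(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R² of the scale-free topology fit.

    Connectivities are split into ``n_bins`` equal-width bins; within each
    non-empty bin the empirical frequency and mean connectivity are taken,
    and log10(frequency) is regressed on log10(mean k). The R² carries the
    negative of the slope's sign, so a decreasing (power-law-like)
    distribution scores positively.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        raise ValueError("need at least 2 positive connectivities")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            freqs.append(sel.mean())
            means.append(k[sel].mean())
    if len(freqs) < 2:
        raise ValueError("degenerate connectivity distribution: fewer than 2 bins")
    x = np.log10(np.asarray(means))
    y = np.log10(np.asarray(freqs))
    slope, _, r_value, _, _ = stats.linregress(x, y)
    return float(-np.sign(slope) * r_value**2)


def pick_soft_threshold(
    expr: pd.DataFrame, config: NetworkConfig | None = None
) -> tuple[int, float, pd.DataFrame]:
    """Choose the soft threshold beta by scale-free topology fit.

    Returns the smallest candidate beta whose fit index exceeds
    ``rsq_target``; if none qualifies, the beta with the maximal fit is
    returned with a warning. The fit table reports the index and mean
    connectivity per candidate.
    """
    config = config or NetworkConfig()
    if expr.shape[0] < 2 or expr.shape[1] < 3:
        raise ValueError("soft-threshold selection needs >= 2 genes and >= 3 samples")
    corr = correlation_matrix(expr)
    r = corr.to_numpy()
    rows = []
    for beta in config.beta_candidates:
        a = ((1 + r) / 2) ** beta if config.signed else np.abs(r) ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        try:
            fit = scale_free_fit_index(k, config.n_bins)
        except ValueError:
            fit = np.nan
        rows.append({"beta": beta, "fit_index": fit, "mean_k": float(k.mean()),
                     "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    ok = table[table["fit_index"] > config.rsq_target]
    if len(ok):
        best = ok.iloc[0]
    else:
        warnings.warn(
            f"no candidate beta reaches fit R^2 > {config.rsq_target}; "
            "using the best-fitting candidate"
        )
        best = table.loc[table["fit_index"].idxmax()]
    return int(best["beta"]), float(best["fit_index"]), table


# ---------------------------------------------------------------------------
# topological overlap and module detection
# ---------------------------------------------------------------------------

def topological_overlap(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Unsigned topological overlap matrix.

    ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`` for i ≠ j, with
    ``L = A @ A`` restricted to shared neighbours and ``k`` the row sums;
    the diagonal is 1. Input must be symmetric with zero diagonal and
    entries in [0, 1].
    """
    is_frame = isinstance(adjacency, pd.DataFrame)
    A = adjacency.to_numpy(dtype=float) if is_frame else np.asarray(adjacency, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if A.min() < 0 or A.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if is_frame:
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def detect_modules(tom: pd.DataFrame, config: NetworkConfig | None = None) -> ModuleSet:
    """Cluster 1 − TOM with average linkage and a static-height cut.

    The tree is cut at ``cut_height_fraction`` × (maximum merge height):
    on TOM dissimilarities the unrelated bulk of the tree saturates just
    below 1, so a cut slightly under the top isolates the tight subtrees
    while leaving the unrelated bulk in fragments. Clusters smaller than
    ``min_module_size`` stay unassigned. Modules are labelled M1, M2, … in
    decreasing size (ties broken by gene order).
    """
    config = config or NetworkConfig()
    genes = list(tom.index)
    D = 1.0 - tom.to_numpy()
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(D, checks=False), method="average")
    heights = link[:, 2]
    cut = float(config.cut_height_fraction * heights.max())
    labels = hierarchy.fcluster(link, t=cut, criterion="distance")
    modules: dict[str, list[str]] = {}
    unassigned: list[str] = []
    sizes: list[tuple[int, int]] = []  # (size, first-gene position) per raw label
    by_label: dict[int, list[int]] = {}
    for pos, lab in enumerate(labels):
        by_label.setdefault(int(lab), []).append(pos)
    kept = [
        (len(poss), poss[0], lab)
        for lab, poss in by_label.items()
        if len(poss) >= config.min_module_size
    ]
    kept.sort(key=lambda t: (-t[0], t[1]))
    assigned: set[int] = set()
    for rank, (_, _, lab) in enumerate(kept, start=1):
        poss = by_label[lab]
        modules[f"M{rank}"] = [genes[p] for p in poss]
        assigned.update(poss)
    unassigned = [genes[p] for p in range(len(genes)) if p not in assigned]
    if not modules:
        warnings.warn("no cluster reaches min_module_size; all genes unassigned")
    return ModuleSet(modules=modules, unassigned=unassigned)


def module_eigengene(expr: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component of a gene-standardized module submatrix.

    ``expr`` is genes × samples for one module. Returns the unit-norm
    eigengene over samples (sign fixed so the mean correlation with the
    member genes is non-negative) and the fraction of variance explained.
    Zero-variance genes are dropped with a warning.
    """
    if expr.shape[0] < 2:
        raise ValueError("module eigengene needs >= 2 genes")
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} zero-variance genes dropped "
                      "from eigengene computation")
        X = X[sd > 0]
        if X.shape[0] < 2:
            raise ValueError("fewer than 2 non-constant genes in module")
        sd = sd[sd > 0]
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    # right singular vector of the standardized matrix = PC over samples
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    corr_sign = np.sign(np.mean([np.corrcoef(row, eig)[0, 1] for row in Z]))
    if corr_sign < 0:
        eig = -eig
    eig = eig / np.linalg.norm(eig)
    return pd.Series(eig, index=expr.columns, name="eigengene"), var_explained


def _compute_eigengenes(modules: dict[str, list[str]],
                        expr: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    eigs = {}
    var = {}
    for mid, genes in modules.items():
        eig, ve = module_eigengene(expr.loc[genes])
        eigs[mid] = eig
        var[mid] = ve
    frame = pd.DataFrame(eigs)
    frame.index = expr.columns
    return frame, var


def merge_close_modules(modules: ModuleSet, expr: pd.DataFrame,
                        config: NetworkConfig | None = None) -> ModuleSet:
    """Iteratively merge modules whose eigengenes are highly correlated.

    The closest pair with eigengene dissimilarity 1 − cor below
    ``merge_cut_height`` is merged and eigengenes recomputed, until no
    pair qualifies. Module ids are re-assigned by size after merging.
    """
    config = config or NetworkConfig()
    current = {m: list(g) for m, g in modules.modules.items()}
    if len(current) >= 2:
        while True:
            eigs, _ = _compute_eigengenes(current, expr)
            ids = list(eigs.columns)
            if len(ids) < 2:
                break
            C = np.corrcoef(eigs.to_numpy().T)
            np.fill_diagonal(C, -np.inf)
            i, j = np.unravel_index(np.argmax(C), C.shape)
            if 1.0 - C[i, j] >= config.merge_cut_height:
                break
            a, b = ids[min(i, j)], ids[max(i, j)]
            current[a] = current[a] + current.pop(b)
    # relabel by size, recompute final eigengenes
    order = sorted(current.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    relabeled = {f"M{r}": genes for r, (_, genes) in enumerate(order, start=1)}
    if relabeled:
        eigs, var = _compute_eigengenes(relabeled, expr)
    else:
        eigs, var = None, {}
    return ModuleSet(
        modules=relabeled,
        unassigned=list(modules.unassigned),
        eigengenes=eigs,
        var_explained=var,
        beta_used=modules.beta_used,
        rsq_achieved=modules.rsq_achieved,
    )


# ---------------------------------------------------------------------------
# trait association and hubs
# ---------------------------------------------------------------------------

def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and the two-sided p from the Student t transform."""
    n = len(x)
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


def module_trait_association(modules: ModuleSet, design: pd.Series,
                             config: NetworkConfig | None = None) -> pd.DataFrame:
    """Correlate each module eigengene with each binary tissue indicator.

    p-values come from the Student t transform with S − 2 degrees of
    freedom and are reported raw, with a Benjamini–Hochberg column added
    for transparency. A module is tissue-specific when r exceeds the
    configured threshold (one-sided positive).
    """
    from statsmodels.stats.multitest import multipletests

    config = config or NetworkConfig()
    if modules.eigengenes is None:
        raise ValueError("modules have no eigengenes; run merge_close_modules first")
    eigs = modules.eigengenes
    design = design.loc[eigs.index]
    tissues: list[str] = []
    for t in design:
        if t not in tissues:
            tissues.append(t)
    rows = []
    for mid in eigs.columns:
        e = eigs[mid].to_numpy()
        for tissue in tissues:
            ind = (design == tissue).to_numpy(dtype=float)
            r, p = _pearson_with_p(e, ind)
            rows.append({"module_id": mid, "tissue": tissue, "r": r, "p": p})
    table = pd.DataFrame(rows)
    valid = table["p"].notna()
    fdr = np.full(len(table), np.nan)
    if valid.any():
        fdr[valid.to_numpy()] = multipletests(
            table.loc[valid, "p"], method="fdr_bh"
        )[1]
    table["fdr"] = fdr
    table["is_tissue_specific"] = table["r"] > config.tissue_module_r
    return table


def call_hub_genes(modules: ModuleSet, expr: pd.DataFrame, design: pd.Series,
                   trait_table: pd.DataFrame,
                   config: NetworkConfig | None = None) -> pd.DataFrame:
    """Call hub genes inside tissue-specific modules.

    For every gene of each tissue-specific (module, tissue) pair:
    GS = cor(gene, tissue indicator), MM = cor(gene, module eigengene);
    a hub satisfies |GS| > gs_min and |MM| > mm_min.
    """
    config = config or NetworkConfig()
    spec = trait_table[trait_table["is_tissue_specific"]]
    if spec.empty:
        warnings.warn("no tissue-specific module; empty hub table")
        return pd.DataFrame(
            columns=["gene_id", "module_id", "tissue", "gs", "mm", "is_hub"]
        )
    design = design.loc[expr.columns]
    rows = []
    for _, trait_row in spec.iterrows():
        mid, tissue = trait_row["module_id"], trait_row["tissue"]
        genes = modules.modules[mid]
        eig = modules.eigengenes[mid].to_numpy()
        ind = (design == tissue).to_numpy(dtype=float)
        X = expr.loc[genes].to_numpy()
        gs = _row_cor(X, ind)
        mm = _row_cor(X, eig)
        for g, gsv, mmv in zip(genes, gs, mm):
            rows.append(
                {
                    "gene_id": g,
                    "module_id": mid,
                    "tissue": tissue,
                    "gs": gsv,
                    "mm": mmv,
                    "is_hub": bool(abs(gsv) > config.gs_min and abs(mmv) > config.mm_min),
                }
            )
    return pd.DataFrame(rows)


def _row_cor(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with the vector y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / denom
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# one-call orchestration
# ---------------------------------------------------------------------------

@dataclass
class NetworkResult:
    """Everything the network stage produces."""

    modules: ModuleSet
    trait_table: pd.DataFrame
    hub_table: pd.DataFrame
    soft_threshold_table: pd.DataFrame
    expr: pd.DataFrame  # the log-space matrix the network was built on


def build_network(matrix: ExpressionMatrix,
                  config: NetworkConfig | None = None,
                  filter_mode: str = "any_tissue",
                  log_transform: bool = True,
                  beta: int | None = None) -> NetworkResult:
    """Run the full network stage on an expression matrix with design.

    Filters to well-expressed genes, log2(FPKM + 1)-transforms, picks the
    soft threshold (unless ``beta`` is forced), builds adjacency and TOM,
    detects and merges modules, associates modules with tissues and calls
    hub genes. A hard cap guards against quadratic blow-up on very large
    inputs.
    """
    config = config or NetworkConfig()
    filtered = filter_for_network(matrix, mode=filter_mode,
                                  min_genes=config.min_module_size)
    if filtered.n_genes > MAX_NETWORK_GENES:
        raise ValueError(
            f"{filtered.n_genes} genes exceed the network cap of "
            f"{MAX_NETWORK_GENES}; pre-filter or subsample first"
        )
    expr = filtered.log2p1() if log_transform else filtered.values
    # constant genes cannot enter correlations
    sd = expr.to_numpy().std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} constant genes excluded")
        expr = expr.loc[sd > 0]
    if beta is None:
        beta_used, rsq, fit_table = pick_soft_threshold(expr, config)
    else:
        beta_used, rsq, fit_table = beta, np.nan, pd.DataFrame()
    corr = correlation_matrix(expr)
    adj = adjacency_matrix(corr, beta_used, signed=config.signed)
    tom = topological_overlap(adj)
    premerge = detect_modules(tom, config)
    premerge.beta_used = beta_used
    premerge.rsq_achieved = rsq
    modules = merge_close_modules(premerge, expr, config)
    trait = module_trait_association(modules, filtered.design, config)
    hubs = call_hub_genes(modules, expr, filtered.design, trait, config)
    return NetworkResult(modules, trait, hubs, fit_table, expr)
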