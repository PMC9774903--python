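"""Housekeeping-gene detection and tiering.

A preliminary housekeeping gene (HKG) is constitutively expressed: its mean
FPKM exceeds 1 in every tissue. Expression stability is quantified by the
coefficient of variation CV = sigma/mu across per-tissue means, and genes
are tiered by the quartiles of the CV distribution (low: CV <= Q1, high:
CV >= Q3, medium otherwise). Low-variability genes are further tiered by
their grand-mean expression level: low (1 < FPKM <= 10), medium
(10 < FPKM <= 50), high (FPKM > 50).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .profile import TissueSummary

__all__ = [
    "detect_preliminary_hkg",
    "compute_cv",
    "tier_by_variability",
    "tier_by_expression",
    "build_hkg_table",
    "HkgResult",
]


def detect_preliminary_hkg(summary: TissueSummary, threshold: float = 1.0) -> list[str]:
    """Genes with mean FPKM strictly above ``threshold`` in every tissue."""
    mask = (summary.mean > threshold).all(axis=1)
    return list(summary.mean.index[mask])


def compute_cv(values, ddof: int = 1) -> float | np.ndarray:
    """Coefficient of variation sd/mean.

    ``values`` is a vector of positive reals (one gene) or a 2-D array /
    DataFrame with one row per gene, in which case the CV is computed
    row-wise. The standard deviation uses the sample (n − 1) denominator
    by default (``ddof=0`` gives the population form).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        if arr.size < 2:
            raise ValueError("CV needs at least 2 values")
        return float(arr.std(ddof=ddof) / arr.mean())
    if arr.shape[1] < 2:
        raise ValueError("CV needs at least 2 values per gene")
    return arr.std(axis=1, ddof=ddof) / arr.mean(axis=1)


def tier_by_variability(cv: pd.Series) -> tuple[pd.Series, float, float]:
    """Assign low/medium/high variability tiers by CV quartiles.

    Quartiles use linear interpolation between order statistics (the
    common "type 7" rule). Boundaries are closed as stated: low iff
    CV <= Q1, high iff CV >= Q3. In the degenerate case Q1 == Q3 (e.g. all
    CVs identical) the low tier takes precedence.
    """
    if len(cv) < 4:
        raise ValueError("need at least 4 genes to tier by quartiles")
    q1 = float(np.quantile(cv.to_numpy(), 0.25))
    q3 = float(np.quantile(cv.to_numpy(), 0.75))
    tier = pd.Series("medium", index=cv.index, dtype=object)
    tier[cv >= q3] = "high"
    tier[cv <= q1] = "low"  # low wins when q1 == q3
    return tier, q1, q3


def tier_by_expression(grand_mean: pd.Series) -> pd.Series:
    """Expression-level tier from the grand mean of tissue means.

    low: 1 < FPKM <= 10; medium: 10 < FPKM <= 50; high: FPKM > 50.
    """
    tier = pd.Series("low", index=grand_mean.index, dtype=object)
    tier[(grand_mean > 10) & (grand_mean <= 50)] = "medium"
    tier[grand_mean > 50] = "high"
    return tier


@dataclass
class HkgResult:
    """HKG table plus the quartile cut points used for tiering."""

    table: pd.DataFrame
    q1: float
    q3: float
    cv_mode: str

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def shortlist(self) -> pd.DataFrame:
        """Low-variability, high-expression genes — the most stable,
        strongly expressed constitutive genes."""
        t = self.table
        return t[(t["variability_tier"] == "low") & (t["expression_tier"] == "high")]


def build_hkg_table(
    summary: TissueSummary,
    threshold: float = 1.0,
    cv_mode: str = "tissue_means",
    matrix: ExpressionMatrix | None = None,
    ddof: int = 1,
) -> HkgResult:
    """Full HKG stage: detect constitutive genes, tier by CV and by level.

    ``cv_mode`` selects the CV substrate: ``"tissue_means"`` (default;
    CV across the per-tissue mean vector) or ``"samples"`` (CV across all
    individual samples; requires ``matrix``).
    """
    genes = detect_preliminary_hkg(summary, threshold)
    if len(genes) < 4:
        raise ValueError(f"only {len(genes)} preliminary HKGs; need >= 4 to tier")
    means = summary.mean.loc[genes]
    if cv_mode == "tissue_means":
        cv = pd.Series(compute_cv(means.to_numpy(), ddof=ddof), index=genes)
    elif cv_mode == "samples":
        if matrix is None:
            raise ValueError("cv_mode='samples' requires the expression matrix")
        cv = pd.Series(
            compute_cv(matrix.values.loc[genes].to_numpy(), ddof=ddof), index=genes
        )
    else:
        raise ValueError("cv_mode must be 'tissue_means' or 'samples'")
    var_tier, q1, q3 = tier_by_variability(cv)
    grand_mean = means.mean(axis=1)
    expr_tier = pd.Series(pd.NA, index=genes, dtype=object)
    low = var_tier == "low"
    expr_tier[low] = tier_by_expression(grand_mean[low])
    table = pd.DataFrame(
        {
            "cv": cv,
            "variability_tier": var_tier,
            "expression_tier": expr_tier,
            "grand_mean_fpkm": grand_mean,
        }
    ).join(means.add_prefix("mean_"))
    table.index.name = "gene_id"
    return HkgResult(table, q1, q3, cv_mode)
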