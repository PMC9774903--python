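"""Synthetic FPKM matrices with planted ground truth.

The generator emulates a multi-tissue bulk RNA-seq atlas (14 tissues with
replicate samples by default) containing five planted gene classes:

* constitutive genes ("hkg"): one base level per gene, log-uniform in
  [5, 200] FPKM, identical across tissues, with multiplicative log-normal
  replicate noise — low cross-tissue CV by construction;
* single-tissue genes ("tsg"): a target-tissue level log-uniform in
  [20, 500], all other samples uniform in [0, 0.5] — below the FPKM < 1
  activity rule;
* co-expressed module genes ("module"): each module is tied to one tissue;
  genes share a per-module latent sample vector (tissue indicator plus
  0.3 × standard-normal noise) entering log2 space with a gene-specific
  loading in [0.5, 1]; assigned-tissue levels are log-uniform in [20, 200]
  and off-tissue baselines uniform in [0.05, 0.5], so modules are both
  internally correlated and tissue-associated while staying out of the
  constitutive set;
* background genes: independent per-tissue levels, log-uniform in
  [0.2, 50], with replicate noise;
* inactive genes: every sample uniform in [0, 0.9], below the activity
  threshold everywhere.

All values are rounded to 4 decimals and fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["SynthConfig", "generate", "truth_eval", "paper_scale_config",
           "PAPER_TISSUE_SAMPLES"]

# Per-tissue sample counts of the 626-sample, 14-tissue pig atlas design.
PAPER_TISSUE_SAMPLES: dict[str, int] = {
    "heart": 28,
    "spleen": 46,
    "muscle": 28,
    "liver": 63,
    "backfat": 31,
    "lung": 77,
    "kidney": 16,
    "longissimus_dorsi": 96,
    "skeletal_muscle": 91,
    "ovary": 56,
    "gallbladder": 19,
    "ileum": 27,
    "jejunum": 21,
    "endocrine_brain": 27,
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic atlas.

    Defaults produce 3,740 genes × 70 samples: large enough that every
    decision boundary of the pipeline is exercised, small enough to run in
    seconds.
    """

    n_tissues: int = 14
    samples_per_tissue: int = 5
    n_hkg: int = 500
    n_tsg: int = 500
    n_modules: int = 4
    module_size: int = 60
    n_background: int = 2000
    n_inactive: int = 500
    noise_sd_log2: float = 0.25
    seed: int = 0
    # optional explicit per-tissue sample counts (overrides the two fields above)
    tissue_samples: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for name in ("n_hkg", "n_tsg", "n_modules", "module_size",
                     "n_background", "n_inactive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be positive")
        if self.total_genes == 0:
            raise ValueError("configuration generates zero genes")

    @property
    def total_genes(self) -> int:
        return (self.n_hkg + self.n_tsg + self.n_modules * self.module_size
                + self.n_background + self.n_inactive)

    @property
    def tissue_layout(self) -> dict[str, int]:
        if self.tissue_samples is not None:
            return dict(self.tissue_samples)
        return {f"T{i + 1:02d}": self.samples_per_tissue
                for i in range(self.n_tissues)}

    def to_dict(self) -> dict:
        return asdict(self)


def paper_scale_config(seed: int = 0) -> SynthConfig:
    """A 28,000-gene preset with the atlas's per-tissue sample counts.

    Role proportions mirror the real atlas's broad strokes (roughly a
    third inactive, a few thousand constitutive and single-tissue genes).
    """
    return SynthConfig(
        n_tissues=len(PAPER_TISSUE_SAMPLES),
        tissue_samples=dict(PAPER_TISSUE_SAMPLES),
        n_hkg=2400,
        n_tsg=3000,
        n_modules=4,
        module_size=60,
        n_background=13360,
        n_inactive=9000,
        seed=seed,
    )


def _loguniform(rng: np.random.Generator, low: float, high: float, size) -> np.ndarray:
    return np.exp(rng.uniform(np.log(low), np.log(high), size))


def generate(config: SynthConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate the planted FPKM matrix and its ground-truth table.

    Returns an :class:`ExpressionMatrix` with design attached, and a
    truth table with one row per gene: gene_id, role, target_tissue
    (tsg/module genes), module_id and loading (module genes).
    """
    rng = np.random.default_rng(config.seed)
    layout = config.tissue_layout
    tissues = list(layout)
    sample_ids: list[str] = []
    tissue_of: list[str] = []
    for t, n in layout.items():
        for j in range(n):
            sample_ids.append(f"{t}_r{j + 1}")
            tissue_of.append(t)
    tissue_arr = np.asarray(tissue_of)
    S = len(sample_ids)
    noise = config.noise_sd_log2

    blocks: list[np.ndarray] = []
    truth_rows: list[dict] = []
    counter = 0

    def next_ids(n: int) -> list[str]:
        nonlocal counter
        ids = [f"g{counter + i + 1:05d}" for i in range(n)]
        counter += n
        return ids

    # constitutive genes
    if config.n_hkg:
        ids = next_ids(config.n_hkg)
        base = _loguniform(rng, 5, 200, config.n_hkg)
        vals = base[:, None] * 2.0 ** rng.normal(0, noise, (config.n_hkg, S))
        blocks.append(vals)
        truth_rows += [{"gene_id": g, "role": "hkg"} for g in ids]

    # single-tissue genes
    if config.n_tsg:
        ids = next_ids(config.n_tsg)
        targets = [tissues[i % len(tissues)] for i in range(config.n_tsg)]
        vals = rng.uniform(0, 0.5, (config.n_tsg, S))
        level = _loguniform(rng, 20, 500, config.n_tsg)
        for i, t in enumerate(targets):
            cols = tissue_arr == t
            vals[i, cols] = level[i] * 2.0 ** rng.normal(0, noise, cols.sum())
        blocks.append(vals)
        truth_rows += [
            {"gene_id": g, "role": "tsg", "target_tissue": t}
            for g, t in zip(ids, targets)
        ]

    # co-expressed modules, one per tissue (cycling if more modules than tissues)
    for m in range(config.n_modules):
        ids = next_ids(config.module_size)
        tissue = tissues[m % len(tissues)]
        mid = f"PM{m + 1}"
        indicator = (tissue_arr == tissue).astype(float)
        latent = indicator + 0.3 * rng.normal(0, 1, S)
        loading = rng.uniform(0.5, 1.0, config.module_size)
        high = _loguniform(rng, 20, 200, config.module_size)
        low = rng.uniform(0.05, 0.5, config.module_size)
        # log2 level per sample: off-tissue baseline, assigned-tissue high level,
        # plus the shared latent's noise component scaled by the loading
        base_log2 = (np.where(indicator > 0, np.log2(high)[:, None],
                              np.log2(low)[:, None])
                     + loading[:, None] * (latent - indicator)[None, :]
                     + rng.normal(0, noise, (config.module_size, S)))
        vals = 2.0 ** base_log2
        # guarantee FPKM > 1 in every assigned-tissue sample (rare rescue)
        assigned = indicator > 0
        min_assigned = vals[:, assigned].min(axis=1)
        rescue = min_assigned <= 1.0
        if rescue.any():
            vals[rescue] *= (2.0 / min_assigned[rescue])[:, None]
        blocks.append(vals)
        truth_rows += [
            {"gene_id": g, "role": "module", "target_tissue": tissue,
             "module_id": mid, "loading": float(l)}
            for g, l in zip(ids, loading)
        ]

    # background genes with independent per-tissue levels
    if config.n_background:
        ids = next_ids(config.n_background)
        levels = _loguniform(rng, 0.2, 50, (config.n_background, len(tissues)))
        col_of_tissue = {t: i for i, t in enumerate(tissues)}
        per_sample = levels[:, [col_of_tissue[t] for t in tissue_arr]]
        vals = per_sample * 2.0 ** rng.normal(0, noise, (config.n_background, S))
        blocks.append(vals)
        truth_rows += [{"gene_id": g, "role": "background"} for g in ids]

    # inactive genes: below the FPKM < 1 rule in every sample
    if config.n_inactive:
        ids = next_ids(config.n_inactive)
        vals = rng.uniform(0, 0.9, (config.n_inactive, S))
        blocks.append(vals)
        truth_rows += [{"gene_id": g, "role": "inactive"} for g in ids]

    values = np.round(np.vstack(blocks), 4)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "role", "target_tissue",
                                              "module_id", "loading"])
    frame = pd.DataFrame(values, index=truth["gene_id"].tolist(), columns=sample_ids)
    design = pd.Series(tissue_of, index=sample_ids, name="tissue")
    return ExpressionMatrix(frame, design), truth


def truth_eval(calls, truth: pd.DataFrame, role: str) -> tuple[float | None, float | None]:
    """Precision and recall of a call set against a planted role.

    ``calls`` is any iterable of gene ids called positive. Returns
    ``(precision, recall)``; precision is ``None`` when nothing was
    called, recall is ``None`` when the role has no planted positives.
    """
    calls = set(calls)
    universe = set(truth["gene_id"])
    stray = calls - universe
    if stray:
        raise ValueError(f"calls outside the generated universe: {sorted(stray)[:3]}")
    positives = set(truth.loc[truth["role"] == role, "gene_id"])
    tp = len(calls & positives)
    precision = tp / len(calls) if calls else None
    recall = tp / len(positives) if positives else None
    return precision, recall
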