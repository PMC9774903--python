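"""End-to-end orchestration: run every stage, write TSVs and a manifest.

``run_all`` composes the stages in analysis order (profiling → HKG → TSG →
network → optional ORA); ``run_synthetic`` generates a planted dataset
first and appends planted-signal recovery metrics to the manifest. All
outputs are plain TSV/JSON; the manifest records the configuration, every
output file with a content hash, and any warnings — enough to re-run
identically. Nothing reads the wall clock, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import ExpressionMatrix, read_expression_matrix, attach_design, read_gmt
from .profile import (activity_report, filter_min_expressed_samples, sample_pca,
                      summarize_by_tissue, tissue_correlation_clustering)
from .hkg import build_hkg_table
from .tsg import detect_tsg, detect_particular_tsg, tsg_counts_by_tissue, top_particular_tsg
from .network import NetworkConfig, build_network
from .ora import enrich_gene_groups
from .simulate import SynthConfig, generate, truth_eval

__all__ = ["PipelineConfig", "run_all", "run_synthetic"]

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Thresholds of the full pipeline (all stages)."""

    active_threshold: float = 1.0
    min_expressed_samples: int = 2
    hkg_threshold: float = 1.0
    cv_mode: str = "tissue_means"
    top_fraction: float = 0.25
    sum_ratio: float = 0.5
    fold: float = 3.0
    silence_threshold: float = 1.0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    network_filter_mode: str = "any_tissue"
    network_max_genes: int | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "network"}
        d["network"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.network.__dict__.items()
        }
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_all(
    matrix: ExpressionMatrix | str | Path,
    design_path: str | Path | None,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    gmt_path: str | Path | None = None,
) -> dict:
    """Run every stage and write outputs plus ``manifest.json``.

    ``matrix`` may be an in-memory :class:`ExpressionMatrix` (design
    attached) or a path to a TSV, in which case ``design_path`` is
    required. Returns the manifest dict.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": [],
        "warnings": [],
        "outputs": {},
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if not isinstance(matrix, ExpressionMatrix):
            matrix = read_expression_matrix(matrix)
            if design_path is None:
                raise ValueError("design_path required when reading a matrix file")
            matrix = attach_design(matrix, design_path)
        if matrix.design is None:
            raise ValueError("expression matrix has no design attached")

        # --- tissue profiling -------------------------------------------
        act = activity_report(matrix, config.active_threshold)
        _write(act, out / "activity_report.tsv")
        filtered = filter_min_expressed_samples(matrix, config.min_expressed_samples)
        summary = summarize_by_tissue(filtered)
        _write(summary.to_long_frame(), out / "tissue_summary.tsv")
        corr, _, newick = tissue_correlation_clustering(summary)
        _write(corr, out / "tissue_correlation.tsv", index=True)
        (out / "tissue_dendrogram.nwk").write_text(newick + "\n")
        scores, var_ratio = sample_pca(filtered, random_state=config.seed)
        _write(scores.round(6), out / "sample_pca.tsv", index=True)
        manifest["stages"].append({"stage": "tissue_profile",
                                   "n_genes_retained": filtered.n_genes,
                                   "pca_variance_ratio": [round(float(v), 6)
                                                          for v in var_ratio[:5]]})

        # --- housekeeping genes -----------------------------------------
        hkg = build_hkg_table(summary, config.hkg_threshold, config.cv_mode,
                              matrix=filtered)
        _write(hkg.table, out / "hkg_table.tsv", index=True)
        _write(hkg.shortlist(), out / "hkg_shortlist.tsv", index=True)
        manifest["stages"].append({"stage": "hkg_detect", "n_hkg": len(hkg.genes),
                                   "q1": hkg.q1, "q3": hkg.q3,
                                   "cv_mode": hkg.cv_mode})

        # --- tissue-specific genes --------------------------------------
        tsg_table = detect_tsg(summary, config.top_fraction, config.sum_ratio,
                               config.fold)
        tsg_table = detect_particular_tsg(tsg_table, summary,
                                          config.silence_threshold)
        _write(tsg_table, out / "tsg_table.tsv")
        _write(tsg_counts_by_tissue(tsg_table), out / "tsg_counts.tsv")
        _write(top_particular_tsg(tsg_table), out / "tsg_top_particular.tsv")
        manifest["stages"].append({
            "stage": "tsg_detect",
            "n_tsg": int(tsg_table["is_tsg"].sum()),
            "n_particular": int(tsg_table["is_particular"].sum()),
        })

        # --- co-expression network --------------------------------------
        net_input = filtered
        from .network import filter_for_network
        well = filter_for_network(net_input, mode=config.network_filter_mode,
                                  min_genes=config.network.min_module_size)
        if (config.network_max_genes is not None
                and well.n_genes > config.network_max_genes):
            rng = np.random.default_rng(config.seed)
            pick = np.sort(rng.choice(well.n_genes, config.network_max_genes,
                                      replace=False))
            well = ExpressionMatrix(well.values.iloc[pick], well.design)
        net = build_network(well, config.network,
                            filter_mode="any_tissue", log_transform=True)
        _write(net.modules.assignment.rename_axis("gene_id").reset_index(),
               out / "module_assignment.tsv")
        if net.modules.eigengenes is not None:
            _write(net.modules.eigengenes.rename_axis("sample_id"),
                   out / "module_eigengenes.tsv", index=True)
        _write(net.trait_table, out / "module_trait.tsv")
        _write(net.hub_table, out / "hub_table.tsv")
        _write(net.soft_threshold_table, out / "soft_threshold.tsv")
        manifest["stages"].append({
            "stage": "coexpr_net",
            "n_network_genes": int(net.expr.shape[0]),
            "beta": net.modules.beta_used,
            "rsq": None if net.modules.rsq_achieved is None
            else float(net.modules.rsq_achieved),
            "n_modules": len(net.modules.modules),
            "n_hubs": int(net.hub_table["is_hub"].sum()) if len(net.hub_table) else 0,
        })

        # --- enrichment (optional) --------------------------------------
        if gmt_path is not None:
            sets = read_gmt(gmt_path)
            universe = filtered.gene_ids
            groups = {
                f"tsg_{t}": tsg_table.loc[
                    tsg_table["is_tsg"] & (tsg_table["tissue"] == t), "gene_id"
                ].tolist()
                for t in summary.tissues
            }
            groups = {k: v for k, v in groups.items() if v}
            tables = enrich_gene_groups(groups, sets, universe)
            for name, table in tables.items():
                _write(table, out / f"ora_{name}.tsv")
            manifest["stages"].append({"stage": "ora_enrich",
                                       "n_groups": len(tables)})

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.nwk")):
        manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest


def run_synthetic(
    synth_config: SynthConfig,
    out_dir: str | Path,
    pipeline_config: PipelineConfig | None = None,
    gmt_path: str | Path | None = None,
    write_matrix: bool = True,
) -> dict:
    """Generate a planted dataset, run the pipeline, score the recovery.

    Writes the matrix/design/truth TSVs next to the stage outputs and
    appends precision/recall for the planted hkg and tsg roles (and the
    inactive classification rate) to the manifest.
    """
    from .profile import gene_activity
    from .hkg import detect_preliminary_hkg
    from .simulate import generate

    pipeline_config = pipeline_config or PipelineConfig(seed=synth_config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate(synth_config)
    if write_matrix:
        matrix.to_tsv(out / "expression_matrix.tsv", float_format="%.4f")
        matrix.design_to_tsv(out / "design.tsv")
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    manifest = run_all(matrix, None, out, pipeline_config, gmt_path=gmt_path)

    summary = summarize_by_tissue(
        filter_min_expressed_samples(matrix, pipeline_config.min_expressed_samples)
    )
    hkg_calls = detect_preliminary_hkg(summary, pipeline_config.hkg_threshold)
    hkg_p, hkg_r = truth_eval(hkg_calls, truth, "hkg")
    tsg_table = detect_tsg(summary, pipeline_config.top_fraction,
                           pipeline_config.sum_ratio, pipeline_config.fold)
    tsg_calls = tsg_table.loc[tsg_table["is_tsg"], "gene_id"].tolist()
    tsg_p, tsg_r = truth_eval(tsg_calls, truth, "tsg")
    _, inactive = gene_activity(matrix, pipeline_config.active_threshold)
    planted_inactive = truth.loc[truth["role"] == "inactive", "gene_id"]
    frac_inactive_ok = (
        float(inactive.loc[planted_inactive].all(axis=1).mean())
        if len(planted_inactive) else None
    )
    manifest["recovery"] = {
        "hkg_precision": hkg_p, "hkg_recall": hkg_r,
        "tsg_precision": tsg_p, "tsg_recall": tsg_r,
        "inactive_fraction_correct": frac_inactive_ok,
    }
    for name in ("expression_matrix.tsv", "design.tsv", "ground_truth.tsv"):
        f = out / name
        if f.exists():
            manifest["outputs"][name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest
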