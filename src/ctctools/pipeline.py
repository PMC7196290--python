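"""End-to-end orchestration: preprocess -> EMT -> heterogeneity -> kinetics ->
survival -> concordance, with every stage output written to disk and a JSON
summary of the run (cells filtered, entries imputed, group scores, ΔCTC test,
cutoff grid, concordance)."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ctcio
from .concordance import concordance_rate, detect_emergent, table2_fixture
from .emt import MarkerPanel, compute_emt_scores, summarize_group_scores
from .heterogeneity import correlation_matrix, hierarchical_cluster, tsne_embed
from .kinetics import change_series, compare_response_groups, pair_delta_with_response
from .matrix import SENTINEL
from .preprocessing import (apply_quality_filter, delta_ct, impute_undetected,
                            relative_expression, zscore_transform)
from .survival import dichotomize, km_estimate, logrank_test, optimal_cutoff_search
from .synthetic import (SyntheticCohortConfig, generate_ct_matrix,
                        generate_ctc_trajectories, generate_mutation_table,
                        generate_survival_cohort)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """File locations plus every tunable threshold of the pipeline."""

    ct_path: str | None = None
    quality_path: str | None = None
    annotations_path: str | None = None
    counts_path: str | None = None
    assessments_path: str | None = None
    survival_path: str | None = None
    mutations_path: str | None = None
    quality_min: float = 0.65
    ct_max: float = 30.0
    reference_gene: str = "GAPDH"
    epithelial_markers: tuple[str, ...] = ("EPCAM", "KRT7", "KRT18", "KRT19")
    mesenchymal_markers: tuple[str, ...] = ("VIM", "CD44")
    hybrid_band: tuple[float, float] = (40.0, 60.0)
    cluster_metric: str = "euclidean"
    cluster_method: str = "complete"
    n_clusters: int | None = None
    tsne_dims: int = 2
    tsne_perplexity: float = 10.0
    pairing_window_days: int = 45
    min_group_frac: float = 0.1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("epithelial_markers", "mesenchymal_markers", "hybrid_band"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def marker_panel(self) -> MarkerPanel:
        return MarkerPanel(
            epithelial=tuple(self.epithelial_markers),
            mesenchymal=tuple(self.mesenchymal_markers),
            reference_gene=self.reference_gene,
        )


def _log_params(config: PipelineConfig) -> None:
    for f in dataclasses.fields(config):
        logger.info("config %s = %r", f.name, getattr(config, f.name))


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage for which inputs are configured; return the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _log_params(config)
    summary: dict = {"parameters": {
        f.name: getattr(config, f.name) for f in dataclasses.fields(config)
        if not f.name.endswith("_path")
    }}

    if config.ct_path:
        summary["expression"] = _run_expression_stages(config, out)
    if config.counts_path and config.assessments_path:
        summary["kinetics"] = _run_kinetics(config, out)
    if config.survival_path:
        summary["survival"] = _run_survival(config, out)
    if config.mutations_path:
        summary["concordance"] = _run_concordance(config.mutations_path, out)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _run_expression_stages(config: PipelineConfig, out: Path) -> dict:
    m = ctcio.read_ct_matrix(config.ct_path, config.quality_path,
                             config.annotations_path)
    filtered = apply_quality_filter(m, config.quality_min, config.ct_max)
    n_dropped = int(((filtered.ct == SENTINEL) & (m.ct != SENTINEL)).sum().sum())
    # cells whose reference gene failed QC cannot be ΔCt-normalized
    ref_undetected = []
    if config.reference_gene in filtered.ct.index:
        row = filtered.ct.loc[config.reference_gene]
        ref_undetected = list(row.index[row == SENTINEL])
        if ref_undetected:
            logger.warning("cells excluded from EMT scoring "
                           "(reference gene undetected): %s", ref_undetected)
    imputed = impute_undetected(filtered)
    zscores = zscore_transform(imputed)
    rel = relative_expression(delta_ct(imputed, config.reference_gene))
    ctcio.write_table(imputed.values, out / "imputed_ct.csv", "imputed_ct",
                      index=True)
    ctcio.write_table(zscores.values, out / "zscores.csv", "zscores", index=True)
    ctcio.write_table(rel.values, out / "relative_expression.csv",
                      "relative_expression", index=True)

    panel = config.marker_panel()
    scored_cells = [c for c in rel.cell_ids if c not in set(ref_undetected)]
    from .matrix import ExpressionMatrix
    rel_scored = ExpressionMatrix(rel.values[scored_cells], "relative_expr",
                                  validate=False)
    scores = compute_emt_scores(rel_scored, panel, config.hybrid_band)
    grouping = {cid: ann.source_group for cid, ann in m.annotations.items()}
    if not grouping:
        grouping = {cid: "all" for cid in scored_cells}
    scores_out = scores.copy()
    scores_out.insert(0, "group", pd.Series(grouping).reindex(scores.index))
    ctcio.write_table(scores_out.reset_index(names="cell_id"),
                      out / "emt_scores.csv", "emt_scores")
    group_summary = summarize_group_scores(scores, grouping)
    ctcio.write_table(group_summary, out / "emt_group_summary.csv",
                      "emt_group_summary")

    clus = hierarchical_cluster(zscores, config.cluster_metric,
                                config.cluster_method, config.n_clusters)
    link = pd.DataFrame(clus.linkage, columns=["left", "right", "height", "size"])
    ctcio.write_table(link, out / "linkage.csv", "linkage")
    n = len(zscores.cell_ids)
    perplexity = min(config.tsne_perplexity, max(2.0, (n - 1) / 3 - 1e-6))
    emb = tsne_embed(zscores, config.tsne_dims, perplexity, config.seed)
    ctcio.write_table(emb.to_frame().reset_index(names="cell_id"),
                      out / "tsne.csv", "tsne_embedding")
    corr = correlation_matrix(zscores)
    ctcio.write_table(corr.rho, out / "spearman_rho.csv", "spearman_rho",
                      index=True)
    ctcio.write_table(corr.p_raw, out / "spearman_p_raw.csv", "spearman_p_raw",
                      index=True)
    ctcio.write_table(corr.p_adjusted, out / "spearman_p_adjusted.csv",
                      "spearman_p_adjusted", index=True)
    return {
        "n_genes": m.n_genes,
        "n_cells": m.n_cells,
        "n_entries_quality_filtered": n_dropped,
        "n_entries_imputed": int((filtered.ct == SENTINEL).sum().sum()),
        "all_undetected_genes": imputed.flags.get("all_undetected_genes", []),
        "zero_variance_genes": zscores.flags.get("zero_variance_genes", []),
        "cells_excluded_from_emt": ref_undetected,
        "emt_group_summary": group_summary.to_dict(orient="records"),
        "tsne_perplexity_used": perplexity,
    }


def _run_kinetics(config: PipelineConfig, out: Path) -> dict:
    series_list = ctcio.read_counts(config.counts_path)
    assessments = ctcio.read_assessments(config.assessments_path)
    deltas = [d for s in series_list for d in change_series(s)]
    paired = pair_delta_with_response(deltas, assessments,
                                      config.pairing_window_days)
    rows = pd.DataFrame(
        [{"patient_id": d.patient_id, "day": d.day, "delta_ctc_pct": d.value,
          "matched_response": d.matched_response or ""} for d in paired]
    )
    ctcio.write_table(rows, out / "delta_ctc.csv", "delta_ctc")
    comparison = compare_response_groups(paired)
    result = {
        "t_statistic": comparison.statistic,
        "p_value": comparison.p_value,
        "group_means": comparison.group_means,
        "group_n": comparison.group_n,
        "n_unpaired": sum(d.matched_response is None for d in paired),
    }
    ctcio.write_table(pd.DataFrame([{
        "t_statistic": comparison.statistic, "p_value": comparison.p_value,
        **{f"mean_{k}": v for k, v in comparison.group_means.items()},
        **{f"n_{k}": v for k, v in comparison.group_n.items()},
    }]), out / "kinetics_test.csv", "kinetics_test")
    return result


def _run_survival(config: PipelineConfig, out: Path) -> dict:
    records = ctcio.read_survival(config.survival_path)
    search = optimal_cutoff_search(records, config.min_group_frac)
    ctcio.write_table(search.grid, out / "cutoff_grid.csv", "cutoff_grid")
    split = dichotomize(records, search.best_cutoff)
    km_all = km_estimate(records)
    ctcio.write_table(
        pd.DataFrame({"time": km_all.timeline, "survival": km_all.survival,
                      "at_risk": km_all.at_risk}),
        out / "km_overall.csv", "km_estimate")
    lr = logrank_test(split.high, split.low)
    return {
        "n": len(records),
        "best_cutoff": search.best_cutoff,
        "best_p": search.best_p,
        "n_high": split.n_high,
        "n_low": split.n_low,
        "frac_high_pct": 100.0 * split.frac_high,
        "logrank_statistic": lr.statistic,
        "median_days": km_all.median,
        "median_ci_days": list(km_all.median_ci),
        "note": search.note,
    }


def _run_concordance(mutations_path, out: Path) -> dict:
    table = ctcio.read_mutation_table(mutations_path)
    res = concordance_rate(table)
    events = detect_emergent(table)
    ctcio.write_table(pd.DataFrame([
        {"patient_id": e.patient_id, "locus": e.locus, "modality": e.modality}
        for e in events
    ]), out / "emergent_mutations.csv", "emergent_mutations")
    return {
        "n_samples": res.n_samples,
        "n_concordant": res.n_concordant,
        "rate_pct": res.rate,
        "per_locus_pct": res.per_locus,
        "emergent": [{"patient_id": e.patient_id, "locus": e.locus,
                      "modality": e.modality} for e in events],
    }


def simulate_inputs(out_dir, seed: int = 0,
                    config: SyntheticCohortConfig | None = None) -> dict:
    """Generate a full synthetic cohort and write every input CSV."""
    cfg = config or SyntheticCohortConfig(seed=seed)
    if config is not None and seed:
        cfg = dataclasses.replace(cfg, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m, labels = generate_ct_matrix(cfg)
    ctcio.write_ct_matrix(m, out / "ct_matrix.csv", out / "quality.csv",
                          out / "annotations.csv")
    ctcio.write_table(labels.to_frame().reset_index(names="cell_id"),
                      out / "true_groups.csv", "true_groups")
    trajectories = generate_ctc_trajectories(cfg)
    ctcio.write_counts([s for s, _ in trajectories], out / "counts.csv")
    ctcio.write_assessments([a for _, al in trajectories for a in al],
                            out / "assessments.csv")
    records = generate_survival_cohort(cfg, true_cutoff=66.0, hazard_ratio=2.0)
    ctcio.write_survival(records, out / "survival.csv")
    table = generate_mutation_table(cfg, n_emergent_pairs=2)
    ctcio.write_mutation_table(table, out / "mutations.csv")
    return {"dir": str(out), "seed": cfg.seed,
            "n_cells": m.n_cells, "n_patients": cfg.n_patients}


def run_demo(out_dir, seed: int = 0) -> dict:
    """One-command synthetic cohort end-to-end, plus the bundled call table."""
    out = Path(out_dir)
    inputs = out / "inputs"
    simulate_inputs(inputs, seed=seed)
    config = PipelineConfig(
        ct_path=str(inputs / "ct_matrix.csv"),
        quality_path=str(inputs / "quality.csv"),
        annotations_path=str(inputs / "annotations.csv"),
        counts_path=str(inputs / "counts.csv"),
        assessments_path=str(inputs / "assessments.csv"),
        survival_path=str(inputs / "survival.csv"),
        mutations_path=str(inputs / "mutations.csv"),
        seed=seed,
    )
    summary = run_pipeline(config, out / "results")
    fixture_summary = _run_concordance_fixture(out / "results")
    summary["fixture_concordance"] = fixture_summary
    with open(out / "results" / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return summary


def _run_concordance_fixture(out: Path) -> dict:
    table = table2_fixture()
    res = concordance_rate(table)
    events = detect_emergent(table)
    return {
        "n_samples": res.n_samples,
        "rate_pct": res.rate,
        "emergent": [{"patient_id": e.patient_id, "locus": e.locus,
                      "modality": e.modality} for e in events],
    }
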