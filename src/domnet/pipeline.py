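"""End-to-end pipeline: simulate -> assign -> network -> embed ->
coverage -> trend -> overlay, writing every stage's outputs as TSV plus
a machine-readable run report.

All randomness flows from the single seed in the configuration, so two
runs with the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, embedding, features, io, network, pathways, synthetic, trends
from .overlay import overlay as _overlay_op
from .config import PipelineConfig


def _stage(report: dict, name: str):
    report["stages"].append(name)
    return name


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on synthetic data and write outputs to ``out_dir``.

    Returns the run report (also written as ``report.json``). A stage
    failure raises with the stage name; outputs of earlier stages stay
    on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": _plain(dataclasses.asdict(config)),
        "stages": [],
        "counts": {},
    }
    state: dict = {}
    for name, fn in (
        ("simulate", _run_simulate),
        ("assign", _run_assign),
        ("network", _run_network),
        ("embed", _run_embed),
        ("coverage", _run_coverage),
        ("trend", _run_trend),
        ("overlay", _run_overlay),
    ):
        _stage(report, name)
        try:
            fn(config, out, state, report["counts"])
        except Exception as exc:  # noqa: BLE001 - annotate with the stage
            _write_report(report, out)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _run_simulate(config: PipelineConfig, out: Path, state: dict, counts: dict) -> None:
    design = dataclasses.replace(config.design, seed=config.seed)
    matrix, meta, truth = synthetic.generate_feature_matrix(
        design, config.structure, include_day0=config.include_day0
    )
    rng = np.random.default_rng(config.seed + 1)
    feature_mz = {synthetic.SumFormula.parse(f).mz_deprotonated for f in matrix.index}
    blank_masses = []
    while len(blank_masses) < config.n_blank_masses:
        m = float(rng.uniform(180.0, 900.0))
        if all(abs(m - fm) > 0.05 for fm in feature_mz):
            blank_masses.append(round(m, 4))
    peak_lists, blank = synthetic.generate_peak_lists(
        matrix,
        seed=config.seed + 2,
        ppm_jitter=config.ppm_jitter,
        sn_low_fraction=config.sn_low_fraction,
        blank_masses=tuple(blank_masses),
    )
    db = synthetic.generate_pathway_db(
        matrix.index,
        annotation_fraction=config.structure.annotation_fraction,
        multiplicity_poisson_mean=config.structure.multiplicity_poisson_mean,
        seed=config.seed + 3,
    )
    peak_dir = out / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for sample, df in peak_lists.items():
        io.write_peak_list(df, peak_dir / f"{sample}.tsv")
    io.write_peak_list(blank, out / "blanks.tsv")
    io.write_matrix(matrix, out / "true_features.tsv")
    io.write_table(meta, out / "metadata.tsv")
    io.write_table(truth.rename("block").reset_index(), out / "true_blocks.tsv")
    db.to_tsv(out / "pathway_db.tsv")
    state.update(
        true_matrix=matrix, meta=meta, truth=truth, peak_lists=peak_lists, blank=blank, db=db
    )
    counts["samples"] = int(len(meta))
    counts["features_simulated"] = int(matrix.shape[0])


def _run_assign(config: PipelineConfig, out: Path, state: dict, counts: dict) -> None:
    tables = {}
    n_in = n_kept = 0
    for sample, peaks in state["peak_lists"].items():
        n_in += len(peaks)
        kept = features.filter_peaks(
            peaks,
            blanks=state["blank"],
            sn_threshold=config.sn_threshold,
            mz_window=config.mz_window,
            blank_ppm_tolerance=config.blank_ppm_tolerance,
        )
        n_kept += len(kept)
        assignments = features.assign_formulas(
            kept,
            ranges=config.element_ranges,
            ppm_tolerance=config.ppm_tolerance,
            filters=config.filters,
        )
        tables[sample] = features.assignment_table(kept, assignments)
    matrix = features.build_feature_matrix(tables, normalization=config.normalization)
    io.write_matrix(matrix, out / "features.tsv")
    state["matrix"] = matrix
    counts["peaks_in"] = n_in
    counts["peaks_after_filters"] = n_kept
    counts["features_assigned"] = int(matrix.shape[0])


def _run_network(config: PipelineConfig, out: Path, state: dict, counts: dict) -> None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cor = network.correlation_matrix(state["matrix"])
    adj = network.signed_adjacency(cor, power=config.network.power)
    modules = network.detect_modules(adj, config.network)
    eig = network.module_eigenvalues(state["matrix"].loc[adj.index], modules)
    try:
        fit = network.scale_free_fit(adj)
        fit_info = {"r_squared": fit.r_squared, "slope": fit.slope, "n_bins": fit.n_bins}
    except ValueError as exc:
        fit_info = {"error": str(exc)}
    network.export_network(adj, modules, config.edge_threshold, str(out / "network.graphml"))
    network.export_network(adj, modules, config.edge_threshold, str(out / "edges.tsv"))
    io.write_matrix(adj, out / "adjacency.tsv")
    io.write_table(modules.labels.rename("module").reset_index(), out / "modules.tsv")
    io.write_matrix(eig.scores, out / "module_eigenvalues.tsv")
    with open(out / "scale_free_fit.json", "w") as fh:
        json.dump(fit_info, fh, indent=2, sort_keys=True)
        fh.write("\n")
    state.update(adjacency=adj, modules=modules, eigenvalues=eig, scale_free=fit_info)
    counts["network_nodes"] = int(adj.shape[0])
    counts["modules"] = int(len(modules.colors))


def _run_embed(config: PipelineConfig, out: Path, state: dict, counts: dict) -> None:
    diss = 1.0 - state["adjacency"]
    diss.values[np.diag_indices_from(diss.values)] = 0.0
    emb = embedding.classical_mds(diss, k=config.embedding_k)
    coords = emb.coordinates.copy()
    coords["module"] = state["modules"].labels.reindex(coords.index)
    coords.index.name = "formula"
    io.write_matrix(coords, out / "embedding.tsv")
    state["embedding"] = emb
    counts["embedding_axes"] = int(emb.coordinates.shape[1])


def _group_coverages(config: PipelineConfig, state: dict) -> dict[str, pd.Series]:
    """Per (litter, site, day) group coverage, using a relative-intensity
    detection threshold of ``coverage_detection_factor / n_features``."""
    matrix, meta, db = state["matrix"], state["meta"], state["db"]
    threshold = config.coverage_detection_factor / matrix.shape[0]
    meta_idx = meta.set_index("sample_id").loc[matrix.columns]
    out = {}
    for (litter, site, day), sub in meta_idx.groupby(["litter", "site", "day"]):
        group_mean = matrix[sub.index].mean(axis=1)
        present = group_mean.index[group_mean > threshold]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            matches = pathways.match_formulas(present, db)
            cov = pathways.pathway_coverage(matches, db, count=config.coverage_count)
        out[f"{litter}_{site}_d{day}"] = cov["coverage"]
    return out


def _run_coverage(config: PipelineConfig, out: Path, state: dict, counts: dict) -> None:
    matrix, db = state["matrix"], state["db"]
    matches = pathways.match_formulas(matrix.index, db)
    mean_intensity = matrix.mean(axis=1)
    result = pathways.coverage_result("dom", matches, db, mean_intensity, count=config.coverage_count)
    io.write_table(result.table.reset_index(), out / "coverage.tsv")
    group_cov = _group_coverages(config, state)
    dispersion, mean_sd = pathways.coverage_dispersion(group_cov)
    io.write_table(dispersion.reset_index(), out / "coverage_dispersion.tsv")
    stats = {
        "match_rate": matches.match_rate,
        "mean_multiplicity": matches.mean_multiplicity,
        "mean_coverage_sd": mean_sd,
        "n_groups": len(group_cov),
    }
    with open(out / "coverage_stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
    state.update(matches=matches, coverage=result, coverage_stats=stats)
    counts["pathways_covered"] = int(len(result.table))
    counts["matched_formulas"] = int(len(matches.matches))


def _run_trend(config: PipelineConfig, out: Path, state: dict, counts: dict) -> None:
    pca = trends.pca_trajectories(state["matrix"], state["meta"], group_col=config.trend_group)
    trend = trends.group_distance_trend(
        state["matrix"], state["meta"], group_col=config.trend_group, mode=config.trend_mode
    )
    io.write_matrix(pca.scores, out / "pca_scores.tsv")
    summary = trend.distances.copy()
    io.write_table(summary, out / "trend.tsv")
    with open(out / "trend_summary.json", "w") as fh:
        json.dump(
            {
                "percent_change": trend.percent_change,
                "mode": trend.mode,
                "per_day": {str(k): v for k, v in trend.per_day.items()},
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    state.update(pca=pca, trend=trend)
    counts["trend_pairs"] = int(trend.distances["pair"].nunique())


def _run_overlay(config: PipelineConfig, out: Path, state: dict, counts: dict) -> None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = _overlay_op(
            state["modules"].labels,
            state["matches"],
            ubiquity_threshold=config.ubiquity_threshold,
            enrichment=config.enrichment,
        )
    wide = table.counts.copy()
    wide["concentration"] = table.concentration
    wide["ubiquitous"] = table.ubiquitous
    io.write_table(wide.reset_index(), out / "overlay.tsv")
    if table.enrichment is not None:
        io.write_table(table.enrichment, out / "overlay_enrichment.tsv")
    state["overlay"] = table
    counts["pathways_in_overlay"] = int(len(table.counts))
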