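"""End-to-end orchestration: simulate/load -> DMRs -> annotation -> markers
-> distances -> expression integration -> lineage contrast -> enrichment ->
motifs, with one config, one seed and a machine-readable report.

The report (``report.json``) and all TSV/BED outputs are byte-deterministic
under a fixed seed; per-stage wall times are written to ``run.log`` only so
that reruns compare byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import annotation as ann
from . import contrast as ctr
from . import distance as dst
from . import dmr as dmrmod
from . import enrichment as enr
from . import expression as expr
from . import markers as mrk
from . import motifs as mot
from . import simulate as sim
from .methylome_io import filter_by_coverage

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS: dict[str, Any] = {
    "min_coverage": 5,
    "min_cpgs": 3,
    "min_diff": 0.25,
    "max_cpg_gap": 500,
    "dmr_max_p": 0.01,
    "promoter_halfwidth": 1000,
    "marker_min_diff": 0.40,
    "marker_top": 12,
    "contrast_min_diff": 0.5,
    "tss_window": 5000,
    "top_ledger": 75,
    "enrich_max_p": 0.01,
    "top_pathways": 40,
    "top_dmrs": 1000,
    "linkage": "complete",
    "motif_flank": 10,
    "motif_nmotifs": 20,
    "motif_max_e": 0.05,
    "motif_max_sequences": 80,
    "motif_widths": [6, 7, 8, 9, 10, 11, 12],
    "correlation_reference": "ILC2",
}


def default_config(seed: int = 0) -> dict[str, Any]:
    """Default run config: the 8-sample simulated study (5 ILC + 3 Th
    unicates) with lineage-discriminating blocks for the contrast stage."""
    return {
        "seed": seed,
        "simulation": {
            "seed": seed,
            "populations": ["ILC1", "ILC2", "ILC3", "LTi", "NK", "Th1", "Th2", "Th17"],
            "groups": {
                "ILC": ["ILC1", "ILC2", "ILC3", "LTi", "NK"],
                "Th": ["Th1", "Th2", "Th17"],
            },
            "lineage_blocks_per_direction": 12,
        },
        "thresholds": dict(DEFAULT_THRESHOLDS),
    }


def _sim_config_from_dict(block: dict[str, Any]) -> sim.SimulationConfig:
    kwargs = dict(block)
    for key in ("populations", "expression_populations", "shared_pair"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    for key in (
        "island_cpgs", "cpg_spacing", "gene_length", "block_cpgs", "delta_range",
        "marker_delta_range", "lineage_delta_range", "background_beta", "gene_set_size",
    ):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if kwargs.get("groups"):
        kwargs["groups"] = {k: tuple(v) for k, v in kwargs["groups"].items()}
    return sim.SimulationConfig(**kwargs)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"unserialisable {type(obj)}")


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run all stages; returns the report dict (also written to report.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    report: dict[str, Any] = {"parameters": config, "stages": {}}
    t_all = time.perf_counter()

    def stage_done(name: str, t0: float) -> None:
        log_lines.append(f"{name}\t{time.perf_counter() - t0:.2f}s")

    th = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    seed = int(config.get("seed", 0))

    # -- simulate or load -------------------------------------------------
    t0 = time.perf_counter()
    if "simulation" not in config:
        raise ValueError("config must contain a 'simulation' block (file inputs: use the CLI stages)")
    sim_cfg = _sim_config_from_dict(config["simulation"])
    study = sim.simulate_study(sim_cfg)
    sim_dir = outdir / "sim"
    manifest = sim.write_study(study, sim_dir)
    report["stages"]["simulate"] = {
        "n_cpgs": int(study.matrix.n_cpgs),
        "n_genes": len(study.genome.genes),
        "n_planted_blocks": len(study.truth.blocks),
        "populations": list(study.config.populations),
        "files": manifest,
    }
    stage_done("simulate", t0)

    # -- coverage filter --------------------------------------------------
    t0 = time.perf_counter()
    matrix = filter_by_coverage(study.matrix, min_cov=th["min_coverage"], min_samples=1)
    report["stages"]["coverage_filter"] = {
        "n_cpgs_before": int(study.matrix.n_cpgs),
        "n_cpgs_after": int(matrix.n_cpgs),
    }
    stage_done("coverage_filter", t0)

    # -- pairwise DMR tables ----------------------------------------------
    t0 = time.perf_counter()
    tables = dmrmod.pairwise_dmr_tables(
        matrix,
        min_cpgs=th["min_cpgs"],
        min_diff=th["min_diff"],
        max_cpg_gap=th["max_cpg_gap"],
        max_p=th["dmr_max_p"],
    )
    dmr_dir = outdir / "dmrs"
    dmr_dir.mkdir(exist_ok=True)
    for (a, b), dmrs in tables.items():
        dmrmod.write_dmr_bed(dmrs, dmr_dir / f"dmrs_{a}_vs_{b}.bed")
    report["stages"]["dmr_calling"] = {
        "pairwise_counts": {f"{a}_vs_{b}": len(d) for (a, b), d in tables.items()}
    }
    stage_done("dmr_calling", t0)

    # -- genomic annotation -----------------------------------------------
    t0 = time.perf_counter()
    genes = study.genome.genes
    ilc_pops = [p for p in study.config.populations if not p.startswith("Th")]
    ilc_tables = {
        pair: d for pair, d in tables.items() if pair[0] in ilc_pops and pair[1] in ilc_pops
    }
    pooled = [d for dmrs in ilc_tables.values() for d in dmrs]
    annotated = ann.annotate_dmrs(pooled, genes, promoter_halfwidth=th["promoter_halfwidth"])
    ann.write_annotated_bed(annotated, outdir / "dmrs_annotated.bed")
    composition = ann.location_composition(annotated) if annotated else {}
    hist = ann.tss_distance_histogram(annotated, bin_width=1000)
    hist.to_csv(outdir / "tss_distance_histogram.tsv", sep="\t", index=False)
    report["stages"]["annotation"] = {
        "n_annotated": len(annotated),
        "location_composition": {k: round(v, 4) for k, v in composition.items()},
    }
    stage_done("annotation", t0)

    # -- marker regions ----------------------------------------------------
    t0 = time.perf_counter()
    marker_lists: dict[str, list[mrk.MarkerRegion]] = {}
    for pop in ilc_pops:
        marker_lists[pop] = mrk.select_markers(
            ilc_tables,
            matrix,
            genes,
            target=pop,
            min_diff=th["marker_min_diff"],
            top=th["marker_top"],
            per_cpg_min_diff=th["min_diff"],
            max_cpg_gap=th["max_cpg_gap"],
            promoter_halfwidth=th["promoter_halfwidth"],
            assoc_tss_window=th["tss_window"],
        )
        mrk.write_markers_tsv(marker_lists[pop], outdir / f"markers_{pop}.tsv")
    all_markers = [m for ms in marker_lists.values() for m in ms]
    if all_markers:
        mrk.marker_matrix(all_markers, matrix).round(6).to_csv(
            outdir / "marker_matrix.tsv", sep="\t"
        )
    report["stages"]["markers"] = {
        "per_population_counts": {p: len(ms) for p, ms in marker_lists.items()},
        "marker_genes": {
            p: [m.gene_name or m.gene_id for m in ms] for p, ms in marker_lists.items()
        },
    }
    stage_done("markers", t0)

    # -- sample distances ---------------------------------------------------
    t0 = time.perf_counter()
    spans = dst.unique_spans(tables)
    if spans:
        region_means = dst.region_mean_matrix(spans, matrix)
        top = dst.top_variable_dmrs(region_means, n=th["top_dmrs"])
        distmat = dst.euclidean_distances(top)
        dendro = dst.hierarchical_cluster(distmat, linkage=th["linkage"])
        distmat.to_frame().round(6).to_csv(outdir / "sample_distances.tsv", sep="\t")
        (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        report["stages"]["distance"] = {
            "n_unique_regions": len(spans),
            "n_top_regions": int(top.shape[1]),
            "newick": dendro.to_newick(),
        }
    else:
        report["stages"]["distance"] = {"skipped": "no DMRs called"}
    stage_done("distance", t0)

    # -- expression integration --------------------------------------------
    t0 = time.perf_counter()
    table = expr.CountTable(
        counts=study.counts, groups=study.sample_groups, lengths=study.gene_lengths
    )
    reference = th["correlation_reference"]
    expr_pops = study.config.expression_population_list()
    correlations: dict[str, Any] = {}
    de_counts: dict[str, int] = {}
    for pop in expr_pops:
        if pop == reference or reference not in expr_pops:
            continue
        records = expr.differential_expression(table, pop, reference)
        de_counts[f"{pop}_vs_{reference}"] = int(len(expr.de_filter(records)))
        markers_pair = marker_lists.get(pop, []) + marker_lists.get(reference, [])
        try:
            res = expr.methylation_expression_correlation(
                markers_pair, records["log2_fold_change"], target=pop, other=reference
            )
        except ValueError:
            continue
        correlations[f"{pop}_vs_{reference}"] = {
            "r": round(res.r, 4),
            "r_squared": round(res.r_squared, 4),
            "p_value": float(f"{res.p_value:.3g}"),
            "label": res.label,
            "n_pairs": int(len(res.pairs)),
        }
        res.pairs.round(6).to_csv(
            outdir / f"correlation_{pop}_vs_{reference}.tsv", sep="\t", index=False
        )
    report["stages"]["expression"] = {
        "de_counts": de_counts,
        "correlations": correlations,
    }
    stage_done("expression", t0)

    # -- lineage contrast ---------------------------------------------------
    t0 = time.perf_counter()
    groups = study.config.groups
    if groups:
        names = sorted(groups)
        group_a, group_b = list(groups[names[0]]), list(groups[names[1]])
        cross_tables = {
            pair: d
            for pair, d in tables.items()
            if (pair[0] in group_a) != (pair[1] in group_a)
        }
        merged = ctr.unique_dmrs(cross_tables) if cross_tables else []
        entries = ctr.filter_contrast(
            merged,
            matrix,
            genes,
            group_a,
            group_b,
            min_abs_diff=th["contrast_min_diff"],
            tss_window=th["tss_window"],
        )
        hyper, hypo, plot_table = ctr.top_hyper_hypo(
            entries, group_a, group_b, n=th["top_ledger"]
        )
        ctr.write_ledger_tsv(hyper, outdir / "ledger_hyper.tsv")
        ctr.write_ledger_tsv(hypo, outdir / "ledger_hypo.tsv")
        plot_table.to_csv(outdir / "ledger_plot_table.tsv", sep="\t", index=False)
        report["stages"]["contrast"] = {
            "groups": {names[0]: group_a, names[1]: group_b},
            "n_unique_cross_dmrs": len(merged),
            "n_filtered": len(entries),
            "hyper_genes": [e.gene_name for e in hyper.entries],
            "hypo_genes": [e.gene_name for e in hypo.entries],
        }
    else:
        report["stages"]["contrast"] = {"skipped": "no groups configured"}
    stage_done("contrast", t0)

    # -- pathway enrichment -------------------------------------------------
    t0 = time.perf_counter()
    universe = enr.cpg_assayed_universe(genes, matrix, th["promoter_halfwidth"])
    results_per_comp: dict[str, list[enr.EnrichmentResult]] = {}
    for (a, b), dmrs in sorted(ilc_tables.items()):
        comp = f"{a}_vs_{b}"
        annotated_pair = ann.annotate_dmrs(dmrs, genes, th["promoter_halfwidth"])
        query = [
            g for g in enr.dmr_gene_assignment(annotated_pair, th["min_diff"], th["dmr_max_p"])
            if g in set(universe)
        ]
        if not query:
            continue
        results_per_comp[comp] = enr.hypergeometric_enrichment(
            query, study.gene_sets, universe, comparison=comp
        )
    if results_per_comp:
        panel, ormatrix = enr.consensus_top_pathways(
            results_per_comp, max_p=th["enrich_max_p"], top_k=th["top_pathways"]
        )
        ormatrix.round(4).to_csv(outdir / "pathway_consensus.tsv", sep="\t")
        report["stages"]["enrichment"] = {
            "n_comparisons": len(results_per_comp),
            "universe_size": len(universe),
            "consensus_panel": panel,
        }
    else:
        report["stages"]["enrichment"] = {"skipped": "no query genes"}
    stage_done("enrichment", t0)

    # -- motif discovery ----------------------------------------------------
    t0 = time.perf_counter()
    motif_pop = study.config.motif_population
    motif_partners = [p for p in ("ILC1", "ILC3", "LTi") if p in study.config.populations]
    motif_spans: list[tuple[str, int, int, float]] = []
    for (a, b), dmrs in tables.items():
        if {a, b} & {motif_pop} and {a, b} & set(motif_partners):
            for d in dmrs:
                diff_t = d.mean_diff if a == motif_pop else -d.mean_diff
                if diff_t < 0:  # hypomethylated in the motif population
                    motif_spans.append((d.chrom, d.start, d.end, abs(d.mean_diff)))
    motif_spans.sort(key=lambda s: (-s[3], s[0], s[1]))
    motif_spans = motif_spans[: th["motif_max_sequences"]]
    if len(motif_spans) >= 10:
        seqs = mot.extract_dmr_sequences(
            [(c, s, e) for c, s, e, _ in motif_spans],
            sim_dir / "genome.fa",
            flank=th["motif_flank"],
        )
        found = mot.discover_motifs(
            seqs,
            widths=list(th["motif_widths"]),
            n_motifs=th["motif_nmotifs"],
            seed=seed,
        )
        kept = mot.filter_low_complexity(found, max_e=th["motif_max_e"])
        mot.write_meme_format(kept, outdir / "motifs.meme")
        matches = {}
        if kept:
            match_df = mot.match_pwm(kept[0].pwm, study.pwm_database, seed=seed)
            match_df.round(4).to_csv(outdir / "motif_matches.tsv", sep="\t", index=False)
            matches = {
                "top_match": str(match_df.iloc[0]["target"]),
                "top_score": round(float(match_df.iloc[0]["score"]), 4),
            }
        report["stages"]["motifs"] = {
            "n_sequences": len(seqs),
            "n_discovered": len(found),
            "n_after_filter": len(kept),
            "top_consensus": kept[0].pwm.consensus if kept else None,
            "top_e_value": float(f"{kept[0].e_value:.3g}") if kept else None,
            **matches,
        }
    else:
        report["stages"]["motifs"] = {"skipped": f"only {len(motif_spans)} candidate spans"}
    stage_done("motifs", t0)

    log_lines.append(f"total\t{time.perf_counter() - t_all:.2f}s")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report
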