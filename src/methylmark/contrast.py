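"""Between-lineage contrast ledgers (e.g. ILC group vs Th group).

The ledger collects unique DMRs (overlapping spans from different pairwise
tables merged) that are differentially methylated by at least 0.5 in *every*
cross-group sample comparison in a consistent direction, lie within 5 kb of
the TSS of an annotated gene, and whose nearest gene carries a canonical
name; the top entries of each direction, ranked by absolute group-mean
difference, form the hyper- and hypomethylated ledgers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import _signed_tss_distance
from .dmr import DMR
from .markers import region_mean_methylation
from .methylome_io import GeneModel, MethylMatrix

logger = logging.getLogger(__name__)

#: placeholder-name convention for mouse genes without a canonical symbol
NONCANONICAL_NAME_PATTERN = r"^(Gm\d+|.*Rik)$"


@dataclass
class ContrastEntry:
    chrom: str
    start: int
    end: int
    gene_id: str
    gene_name: str
    tss_distance: int
    group_diff: float  # mean over group A samples - mean over group B samples
    min_abs_cross_diff: float  # min |pairwise diff| over all A x B sample pairs
    sample_means: dict[str, float]

    @property
    def direction(self) -> str:
        return "hyper" if self.group_diff > 0 else "hypo"


@dataclass
class ContrastLedger:
    direction: str  # hyper / hypo with respect to group A
    group_a: list[str]
    group_b: list[str]
    entries: list[ContrastEntry]


def unique_dmrs(tables: dict[tuple[str, str], list[DMR]]) -> list[DMR]:
    """Merge overlapping DMR spans across tables into unique entries.

    Each merged entry keeps the union span, the union of member CpGs and the
    mean_diff of largest magnitude among its constituents.
    """
    if not tables:
        raise ValueError("need at least one DMR table")
    pool = sorted(
        (d for dmrs in tables.values() for d in dmrs),
        key=lambda d: (d.chrom, d.start, d.end),
    )
    merged: list[DMR] = []
    for d in pool:
        if merged and merged[-1].chrom == d.chrom and d.start < merged[-1].end:
            last = merged[-1]
            keep = last if abs(last.mean_diff) >= abs(d.mean_diff) else d
            positions = np.union1d(last.cpg_positions, d.cpg_positions)
            merged[-1] = DMR(
                chrom=last.chrom,
                start=min(last.start, d.start),
                end=max(last.end, d.end),
                n_cpgs=len(positions),
                mean_diff=keep.mean_diff,
                comparison=keep.comparison,
                cpg_positions=positions,
                p_value=keep.p_value,
            )
        else:
            merged.append(d)
    return merged


def _nearest_gene(
    chrom: str, start: int, end: int, genes: list[GeneModel]
) -> tuple[GeneModel, int] | None:
    best = None
    for g in genes:
        if g.chrom != chrom:
            continue
        d = _signed_tss_distance(start, end, g.tss, g.strand)
        key = (abs(d), g.gene_id)
        if best is None or key < (abs(best[1]), best[0].gene_id):
            best = (g, d)
    return best


def filter_contrast(
    dmrs: list[DMR],
    matrix: MethylMatrix,
    genes: list[GeneModel],
    group_a: list[str],
    group_b: list[str],
    min_abs_diff: float = 0.5,
    tss_window: int = 5000,
    require_canonical_name: bool = True,
    noncanonical_pattern: str = NONCANONICAL_NAME_PATTERN,
) -> list[ContrastEntry]:
    """Apply the three ledger filters to unique DMRs.

    A DMR survives when (a) recomputed region-mean differences satisfy
    |mean_s_a - mean_s_b| >= ``min_abs_diff`` in the same direction for
    *every* cross-group sample pair, (b) its nearest TSS lies within
    ``tss_window`` bp, and (c) the nearest gene has a canonical name.
    """
    pattern = re.compile(noncanonical_pattern)
    out: list[ContrastEntry] = []
    for d in dmrs:
        means = {
            s: region_mean_methylation(matrix, s, d.chrom, d.start, d.end)
            for s in group_a + group_b
        }
        if any(np.isnan(v) for v in means.values()):
            continue
        cross = [means[a] - means[b] for a in group_a for b in group_b]
        if min(cross) >= min_abs_diff:
            pass  # consistently hypermethylated in group A
        elif max(cross) <= -min_abs_diff:
            pass  # consistently hypomethylated in group A
        else:
            continue
        hit = _nearest_gene(d.chrom, d.start, d.end, genes)
        if hit is None:
            continue
        gene, dist = hit
        if abs(dist) > tss_window:
            continue
        if require_canonical_name and (not gene.gene_name or pattern.match(gene.gene_name)):
            continue
        group_diff = float(
            np.mean([means[a] for a in group_a]) - np.mean([means[b] for b in group_b])
        )
        out.append(
            ContrastEntry(
                chrom=d.chrom,
                start=d.start,
                end=d.end,
                gene_id=gene.gene_id,
                gene_name=gene.gene_name,
                tss_distance=dist,
                group_diff=group_diff,
                min_abs_cross_diff=float(min(abs(c) for c in cross)),
                sample_means=means,
            )
        )
    return out


def top_hyper_hypo(
    entries: list[ContrastEntry],
    group_a: list[str],
    group_b: list[str],
    n: int = 75,
) -> tuple[ContrastLedger, ContrastLedger, pd.DataFrame]:
    """Top-n ledgers per direction plus the per-sample plot table.

    A gene with k surviving DMRs contributes k x n_samples plot rows.
    Entries are sorted by |group mean difference| descending with
    deterministic (chrom, start) tie-breaking.
    """

    def ranked(direction: str) -> list[ContrastEntry]:
        sub = [e for e in entries if e.direction == direction]
        sub.sort(key=lambda e: (-abs(e.group_diff), e.chrom, e.start))
        if len(sub) < n:
            logger.info("only %d %smethylated entries (requested %d)", len(sub), direction, n)
        return sub[:n]

    hyper = ContrastLedger("hyper", group_a, group_b, ranked("hyper"))
    hypo = ContrastLedger("hypo", group_a, group_b, ranked("hypo"))
    rows = []
    for ledger in (hyper, hypo):
        for e in ledger.entries:
            for s, v in e.sample_means.items():
                rows.append(
                    {
                        "direction": ledger.direction,
                        "gene": e.gene_name or e.gene_id,
                        "chrom": e.chrom,
                        "start": e.start,
                        "end": e.end,
                        "sample": s,
                        "methylation": round(v, 6),
                        "group_diff": round(e.group_diff, 6),
                    }
                )
    plot_table = pd.DataFrame(
        rows,
        columns=[
            "direction", "gene", "chrom", "start", "end", "sample", "methylation",
            "group_diff",
        ],
    )
    return hyper, hypo, plot_table


def write_ledger_tsv(ledger: ContrastLedger, path) -> None:
    rows = []
    for e in ledger.entries:
        row = {
            "gene": e.gene_name or e.gene_id,
            "chrom": e.chrom,
            "start": e.start,
            "end": e.end,
            "tss_distance": e.tss_distance,
            "group_diff": round(e.group_diff, 6),
            "min_abs_cross_diff": round(e.min_abs_cross_diff, 6),
        }
        for s, v in e.sample_means.items():
            row[f"mean.{s}"] = round(v, 6)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
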