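"""Epigenetic marker-region selection and smoothed methylation profiles.

Marker regions are DMRs that are strongly (>40%) hypomethylated in one
target population, extended to include adjacent differentially methylated
CpGs, associable with an annotated gene, and ranked so that regions
demethylated *exclusively* in the target population come first.  The
exclusivity score of a candidate is the minimum, over all other
populations, of (region mean in the other population - region mean in the
target): large when every other population is much more methylated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .annotation import _signed_tss_distance, classify_dmr
from .dmr import DMR, MethDiffTrack, per_cpg_difference
from .methylome_io import GeneModel, MethylMatrix

logger = logging.getLogger(__name__)


@dataclass
class MarkerRegion:
    chrom: str
    start: int
    end: int
    population: str
    gene_id: str
    gene_name: str
    cpg_positions: np.ndarray
    pop_means: dict[str, float]  # region-mean methylation per population
    exclusivity: float
    max_abs_diff: float

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def min_pairwise_difference(self) -> float:
        return self.exclusivity


@dataclass
class SmoothedProfile:
    chrom: str
    start: int
    end: int
    positions: np.ndarray
    values: pd.DataFrame  # samples x positions, in [0, 1]
    bandwidth: int


def extend_region(
    dmr: DMR,
    track: MethDiffTrack,
    per_cpg_min_diff: float = 0.25,
    max_cpg_gap: int = 500,
) -> DMR:
    """Extend a DMR with flanking same-sign CpGs of |diff| >= threshold.

    Greedy in both directions; each absorbed CpG must lie within
    ``max_cpg_gap`` of the current edge.  Idempotent, and the result always
    contains the input DMR.
    """
    on_chrom = track.chroms == dmr.chrom
    positions = track.positions[on_chrom]
    diffs = track.diffs[on_chrom]
    defined = ~np.isnan(diffs)
    positions, diffs = positions[defined], diffs[defined]
    sign = 1.0 if dmr.mean_diff >= 0 else -1.0
    i = int(np.searchsorted(positions, dmr.cpg_positions[0]))
    j = int(np.searchsorted(positions, dmr.cpg_positions[-1], side="right"))
    while (
        i > 0
        and positions[i] - positions[i - 1] <= max_cpg_gap
        and sign * diffs[i - 1] >= per_cpg_min_diff
    ):
        i -= 1
    while (
        j < len(positions)
        and positions[j] - positions[j - 1] <= max_cpg_gap
        and sign * diffs[j] >= per_cpg_min_diff
    ):
        j += 1
    member = positions[i:j]
    return replace(
        dmr,
        start=int(member[0]),
        end=int(member[-1]) + 1,
        n_cpgs=len(member),
        mean_diff=float(np.mean(diffs[i:j])),
        cpg_positions=member.copy(),
        p_value=dmr.p_value,
    )


def _region_cpg_mask(matrix: MethylMatrix, chrom: str, start: int, end: int) -> np.ndarray:
    return (matrix.chroms == chrom) & (matrix.positions >= start) & (matrix.positions < end)


def region_mean_methylation(
    matrix: MethylMatrix, sample: str, chrom: str, start: int, end: int
) -> float:
    """Unweighted mean level over the region's CpGs with defined values.

    Returns NaN ("not determined") when no member CpG has a defined level,
    mirroring an invalid sequencing signal.
    """
    mask = _region_cpg_mask(matrix, chrom, start, end)
    values = matrix.levels[matrix.sample_index(sample), mask]
    values = values[~np.isnan(values)]
    if len(values) == 0:
        return float("nan")
    return float(np.mean(values))


def _associate_gene(
    dmr: DMR,
    genes: list[GeneModel],
    promoter_halfwidth: int,
    assoc_tss_window: int,
) -> GeneModel | None:
    """Gene a DMR is 'clearly associated' with: body/promoter overlap, else TSS <= window."""
    best: tuple[int, str, GeneModel] | None = None
    for g in genes:
        if g.chrom != dmr.chrom:
            continue
        in_body = dmr.start < g.gene_end and g.gene_start < dmr.end
        in_promoter = (
            dmr.start < g.tss + promoter_halfwidth and g.tss - promoter_halfwidth < dmr.end
        )
        d = abs(_signed_tss_distance(dmr.start, dmr.end, g.tss, g.strand))
        if in_body or in_promoter or d <= assoc_tss_window:
            key = (d, g.gene_id)
            if best is None or key < (best[0], best[1]):
                best = (d, g.gene_id, g)
    return best[2] if best else None


def select_markers(
    dmr_tables: dict[tuple[str, str], list[DMR]],
    matrix: MethylMatrix,
    genes: list[GeneModel],
    target: str,
    min_diff: float = 0.40,
    require_gene: bool = True,
    top: int = 12,
    per_cpg_min_diff: float = 0.25,
    max_cpg_gap: int = 500,
    promoter_halfwidth: int = 1000,
    assoc_tss_window: int = 5000,
) -> list[MarkerRegion]:
    """Ranked marker regions for one target population.

    Candidates are target-hypomethylated DMRs with |mean_diff| strictly
    above ``min_diff`` in at least one pairwise comparison involving the
    target; each is extended, gene-associated (dropped if impossible and
    ``require_gene``), merged with overlapping candidates from other
    comparisons, and ranked by (exclusivity, n_cpgs, max |mean_diff|)
    descending.
    """
    if target not in matrix.samples:
        raise KeyError(f"unknown population {target!r}")
    others = [s for s in matrix.samples if s != target]
    tracks = {o: per_cpg_difference(matrix, target, o) for o in others}

    candidates: list[tuple[DMR, float]] = []  # (extended dmr oriented target-other, |diff|)
    for (a, b), dmrs in dmr_tables.items():
        if target not in (a, b):
            continue
        other = b if a == target else a
        for d in dmrs:
            diff_t = d.mean_diff if a == target else -d.mean_diff  # target - other
            if not (diff_t < 0 and abs(diff_t) > min_diff):
                continue
            oriented = replace(d, mean_diff=diff_t, comparison=(target, other))
            extended = extend_region(
                oriented, tracks[other], per_cpg_min_diff, max_cpg_gap
            )
            candidates.append((extended, abs(diff_t)))

    # merge overlapping candidate spans picked up in different comparisons
    candidates.sort(key=lambda c: (c[0].chrom, c[0].start, c[0].end))
    merged: list[tuple[str, int, int, np.ndarray, float]] = []
    for ext, adiff in candidates:
        if merged and merged[-1][0] == ext.chrom and ext.start < merged[-1][2]:
            c, s, e, pos, best = merged[-1]
            merged[-1] = (
                c,
                s,
                max(e, ext.end),
                np.union1d(pos, ext.cpg_positions),
                max(best, adiff),
            )
        else:
            merged.append((ext.chrom, ext.start, ext.end, ext.cpg_positions, adiff))

    markers: list[MarkerRegion] = []
    for chrom, start, end, cpg_positions, max_abs_diff in merged:
        probe = DMR(
            chrom=chrom,
            start=start,
            end=int(cpg_positions[-1]) + 1,
            n_cpgs=len(cpg_positions),
            mean_diff=-max_abs_diff,
            comparison=(target, "*"),
            cpg_positions=cpg_positions,
        )
        gene = _associate_gene(probe, genes, promoter_halfwidth, assoc_tss_window)
        if gene is None and require_gene:
            continue
        pop_means = {
            s: region_mean_methylation(matrix, s, chrom, start, probe.end)
            for s in matrix.samples
        }
        mean_t = pop_means[target]
        others_means = [pop_means[o] for o in others if not np.isnan(pop_means[o])]
        if np.isnan(mean_t) or not others_means:
            continue
        markers.append(
            MarkerRegion(
                chrom=chrom,
                start=start,
                end=probe.end,
                population=target,
                gene_id=gene.gene_id if gene else "",
                gene_name=gene.gene_name if gene else "",
                cpg_positions=cpg_positions,
                pop_means=pop_means,
                exclusivity=float(min(m - mean_t for m in others_means)),
                max_abs_diff=max_abs_diff,
            )
        )
    markers.sort(
        key=lambda m: (-m.exclusivity, -m.n_cpgs, -m.max_abs_diff, m.chrom, m.start)
    )
    return markers[:top]


def marker_matrix(markers: list[MarkerRegion], matrix: MethylMatrix) -> pd.DataFrame:
    """Populations x markers matrix of region-mean methylation in [0, 1].

    For rendering, 0 maps to yellow, 0.5 to white and 1 to blue.
    """
    if not markers:
        raise ValueError("no markers")
    data = {}
    for m in markers:
        label = f"{m.gene_name or m.gene_id or 'region'}:{m.chrom}:{m.start}-{m.end}"
        data[label] = [
            region_mean_methylation(matrix, s, m.chrom, m.start, m.end)
            for s in matrix.samples
        ]
    return pd.DataFrame(data, index=matrix.samples)


def smooth_profile(
    matrix: MethylMatrix,
    chrom: str,
    start: int,
    end: int,
    bandwidth: int = 500,
) -> SmoothedProfile:
    """Coverage-weighted Gaussian-kernel smoothing of raw levels at each CpG.

    The kernel has standard deviation ``bandwidth / 2`` and is truncated at
    ``bandwidth`` bp, so each smoothed value is a convex combination of
    nearby raw values (hence bounded by their min/max); a CpG with no
    covered neighbour keeps NaN.
    """
    mask = _region_cpg_mask(matrix, chrom, start, end)
    if not mask.any():
        raise ValueError(f"window {chrom}:{start}-{end} contains no CpG")
    pos = matrix.positions[mask].astype(float)
    levels = matrix.levels[:, mask]
    cov = matrix.coverages[:, mask].astype(float)
    dist = np.abs(pos[None, :] - pos[:, None])
    kernel = np.exp(-0.5 * (dist / (bandwidth / 2.0)) ** 2)
    kernel[dist > bandwidth] = 0.0
    smoothed = np.full_like(levels, np.nan)
    for i in range(levels.shape[0]):
        ok = ~np.isnan(levels[i])
        w = kernel[:, ok] * cov[i, ok]
        denom = w.sum(axis=1)
        with np.errstate(invalid="ignore"):
            smoothed[i] = np.where(denom > 0, (w * levels[i, ok]).sum(axis=1) / denom, np.nan)
    values = pd.DataFrame(smoothed, index=matrix.samples, columns=pos.astype(int))
    return SmoothedProfile(
        chrom=chrom, start=start, end=end, positions=pos.astype(int), values=values,
        bandwidth=bandwidth,
    )


def write_markers_tsv(markers: list[MarkerRegion], path) -> None:
    rows = []
    for m in markers:
        row = {
            "population": m.population,
            "gene_id": m.gene_id,
            "gene_name": m.gene_name,
            "chrom": m.chrom,
            "start": m.start,
            "end": m.end,
            "n_cpgs": m.n_cpgs,
            "exclusivity": round(m.exclusivity, 6),
            "max_abs_diff": round(m.max_abs_diff, 6),
        }
        for s, v in m.pop_means.items():
            row[f"mean.{s}"] = round(v, 6) if not np.isnan(v) else "nd"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
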