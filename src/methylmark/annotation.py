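"""Genomic classification of DMRs and signed TSS-distance assignment.

A DMR is a *promoter* DMR if it overlaps the window of ``promoter_halfwidth``
bp on either side of any gene's TSS ("1 kb around the TSS"); otherwise
*intragenic* if it overlaps any gene body; otherwise *intergenic*.  TSS
distances are signed in transcript orientation: positive downstream of the
TSS, negative upstream, zero when the DMR span contains the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmr import DMR
from .methylome_io import GeneModel

GENOMIC_CLASSES = ("promoter", "intragenic", "intergenic")


@dataclass
class AnnotatedDMR:
    dmr: DMR
    genomic_class: str
    tss_distance: int
    nearest_gene_id: str
    nearest_gene_name: str


def _signed_tss_distance(start: int, end: int, tss: int, strand: str) -> int:
    """Distance from the TSS to the nearest DMR edge, signed in transcript orientation."""
    if start <= tss < end:
        return 0
    if tss < start:  # DMR right of the TSS in genome coordinates
        raw = start - tss
        return raw if strand == "+" else -raw
    raw = tss - end  # DMR left of the TSS
    return -raw if strand == "+" else raw


def tss_distance(dmr: DMR, genes: list[GeneModel]) -> tuple[int, GeneModel]:
    """Signed distance to the nearest TSS and the gene owning it.

    Nearest = minimal ``|distance|`` over all genes on the DMR's chromosome
    (all genes if none share the chromosome); ties broken by the
    lexicographically smaller gene_id for deterministic reruns.
    """
    if not genes:
        raise ValueError("gene list is empty")
    candidates = [g for g in genes if g.chrom == dmr.chrom] or genes
    best: tuple[int, str, int, GeneModel] | None = None
    for g in candidates:
        if g.chrom != dmr.chrom:
            continue
        d = _signed_tss_distance(dmr.start, dmr.end, g.tss, g.strand)
        key = (abs(d), g.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (abs(d), g.gene_id, d, g)
    if best is None:
        # no gene on this chromosome: fall back to an arbitrary but
        # deterministic assignment with an effectively infinite distance
        g = min(genes, key=lambda g: g.gene_id)
        return (np.iinfo(np.int64).max, g)
    return (best[2], best[3])


def classify_dmr(
    dmr: DMR, genes: list[GeneModel], promoter_halfwidth: int = 1000
) -> str:
    """Classify as promoter / intragenic / intergenic (precedence in that order)."""
    intragenic = False
    for g in genes:
        if g.chrom != dmr.chrom:
            continue
        if dmr.start < g.tss + promoter_halfwidth and g.tss - promoter_halfwidth < dmr.end:
            return "promoter"
        if dmr.start < g.gene_end and g.gene_start < dmr.end:
            intragenic = True
    return "intragenic" if intragenic else "intergenic"


def annotate_dmrs(
    dmrs: list[DMR], genes: list[GeneModel], promoter_halfwidth: int = 1000
) -> list[AnnotatedDMR]:
    out = []
    for d in dmrs:
        dist, gene = tss_distance(d, genes)
        out.append(
            AnnotatedDMR(
                dmr=d,
                genomic_class=classify_dmr(d, genes, promoter_halfwidth),
                tss_distance=dist,
                nearest_gene_id=gene.gene_id,
                nearest_gene_name=gene.gene_name,
            )
        )
    return out


def location_composition(annotated: list[AnnotatedDMR]) -> dict[str, float]:
    """Fractions of promoter / intragenic / intergenic DMRs (sum to 1)."""
    if not annotated:
        raise ValueError("no annotated DMRs")
    n = len(annotated)
    return {
        cls: sum(a.genomic_class == cls for a in annotated) / n for cls in GENOMIC_CLASSES
    }


def tss_distance_histogram(annotated: list[AnnotatedDMR], bin_width: int) -> pd.DataFrame:
    """Counts of DMRs in symmetric signed distance bins centred on 0.

    Bin k covers ``[(k - 0.5) * bin_width, (k + 0.5) * bin_width)`` so that
    distance 0 sits in the middle of the central bin.  The counts sum to the
    number of DMRs.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dists = np.array([a.tss_distance for a in annotated], dtype=float)
    # bin k covers [(k-0.5)*w, (k+0.5)*w); floor keeps the boundary half-open
    centers = np.floor(dists / bin_width + 0.5).astype(int)
    if len(centers) == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    lo, hi = centers.min(), centers.max()
    ks = np.arange(lo, hi + 1)
    counts = np.array([(centers == k).sum() for k in ks])
    return pd.DataFrame(
        {
            "bin_left": (ks - 0.5) * bin_width,
            "bin_right": (ks + 0.5) * bin_width,
            "count": counts,
        }
    )


def write_annotated_bed(annotated: list[AnnotatedDMR], path) -> None:
    with open(path, "w") as fh:
        for k, a in enumerate(annotated):
            d = a.dmr
            name = f"{d.comparison[0]}_vs_{d.comparison[1]}#{k}"
            score = int(round(1000 * abs(d.mean_diff)))
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{name}\t{score}\t.\t"
                f"{a.genomic_class}\t{a.tss_distance}\t{a.nearest_gene_id}\t"
                f"{a.nearest_gene_name}\n"
            )
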