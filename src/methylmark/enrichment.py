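"""Hypergeometric gene-set overrepresentation of DMR-associated genes.

For a universe of N genes, a set of K, a query of n and an overlap of k the
p-value is the upper tail P(X >= k) of the hypergeometric distribution; the
odds ratio comes from the 2x2 table (k, n-k; K-k, N-K-n+k) with a Haldane
0.5 correction when any cell is zero.  The consensus panel keeps pathways
overrepresented (p <= 0.01) in *every* pairwise comparison, ranked by the
minimum odds ratio across comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotatedDMR
from .expression import benjamini_hochberg
from .methylome_io import GeneModel, MethylMatrix


@dataclass
class EnrichmentResult:
    set_name: str
    universe_size: int  # N
    set_size: int  # K (after intersecting with the universe)
    query_size: int  # n
    overlap: int  # k
    p_value: float
    odds_ratio: float
    comparison: str = ""


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def dmr_gene_assignment(
    annotated: list[AnnotatedDMR], min_abs_diff: float = 0.25, max_p: float = 0.01
) -> list[str]:
    """Unique nearest-gene ids of DMRs passing |mean_diff| >= 0.25 and p <= 0.01."""
    genes = {
        a.nearest_gene_id
        for a in annotated
        if abs(a.dmr.mean_diff) >= min_abs_diff
        and a.dmr.p_value is not None
        and a.dmr.p_value <= max_p
        and a.nearest_gene_id
    }
    return sorted(genes)


def cpg_assayed_universe(
    genes: list[GeneModel], matrix: MethylMatrix, promoter_halfwidth: int = 1000
) -> list[str]:
    """Genes with at least one assayed CpG within gene body or promoter window."""
    out = []
    for g in genes:
        on_chrom = matrix.chroms == g.chrom
        pos = matrix.positions[on_chrom]
        lo = min(g.gene_start, g.tss - promoter_halfwidth)
        hi = max(g.gene_end, g.tss + promoter_halfwidth)
        if np.any((pos >= lo) & (pos < hi)):
            out.append(g.gene_id)
    return sorted(out)


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    a, b = k, n - k
    c, d = K - k, N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def hypergeometric_enrichment(
    query: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    universe: set[str] | list[str],
    comparison: str = "",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric overrepresentation of each set in the query.

    The query must be a subset of the universe; each gene set is intersected
    with the universe before testing.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        stray = sorted(query - universe)[:3]
        raise ValueError(f"query genes outside the universe, e.g. {stray}")
    N, n = len(universe), len(query)
    results = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                set_name=name,
                universe_size=N,
                set_size=K,
                query_size=n,
                overlap=k,
                p_value=min(max(p, 0.0), 1.0),
                odds_ratio=_odds_ratio(k, K, n, N),
                comparison=comparison,
            )
        )
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "set": r.set_name,
                "N": r.universe_size,
                "K": r.set_size,
                "n": r.query_size,
                "k": r.overlap,
                "p_value": r.p_value,
                "odds_ratio": r.odds_ratio,
                "comparison": r.comparison,
            }
            for r in results
        ]
    )
    if len(df):
        df["padj_bh"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df


def consensus_top_pathways(
    results_per_comparison: dict[str, list[EnrichmentResult]],
    max_p: float = 0.01,
    top_k: int = 40,
) -> tuple[list[str], pd.DataFrame]:
    """Pathways overrepresented in all comparisons, ranked by minimum odds ratio.

    Returns the ranked consensus panel (at most ``top_k`` pathways) and the
    pathways x comparisons odds-ratio matrix for the panel.
    """
    if not results_per_comparison:
        raise ValueError("need at least one comparison")
    per_comp: dict[str, dict[str, EnrichmentResult]] = {
        comp: {r.set_name: r for r in results} for comp, results in results_per_comparison.items()
    }
    comparisons = sorted(per_comp)
    common = set.intersection(*(set(d) for d in per_comp.values()))
    consensus = [
        name
        for name in common
        if all(per_comp[c][name].p_value <= max_p for c in comparisons)
    ]
    consensus.sort(
        key=lambda name: (-min(per_comp[c][name].odds_ratio for c in comparisons), name)
    )
    panel = consensus[:top_k]
    matrix = pd.DataFrame(
        {c: [per_comp[c][name].odds_ratio for name in panel] for c in comparisons},
        index=panel,
    )
    return panel, matrix
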