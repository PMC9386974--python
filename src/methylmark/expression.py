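"""Expression normalisation, fold-changes, RPKM and methylation-expression correlation.

The differential-expression stage here is deliberately simple: median-of-
ratios size factors, log2 fold-changes of normalised group means with a
pseudocount, Welch's t-test on log2(normalised + 1) with Benjamini-Hochberg
correction.  Externally computed DE tables can be supplied instead and take
precedence; the correlation analysis only consumes log2 fold-changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CountTable:
    """Gene-level raw counts with sample-to-group assignment and gene lengths.

    ``lengths`` are maximum-transcript exonic lengths in bp (the RPKM length
    convention).
    """

    counts: pd.DataFrame  # genes x samples, non-negative integers
    groups: dict[str, str]  # sample -> group label
    lengths: pd.Series  # per-gene bp

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        if (self.lengths.reindex(self.counts.index) <= 0).any():
            raise ValueError("gene lengths must be positive for all genes")

    def samples_in_group(self, group: str) -> list[str]:
        out = [s for s in self.counts.columns if self.groups[s] == group]
        if not out:
            raise KeyError(f"no samples in group {group!r}")
        return out


@dataclass
class CorrelationResult:
    pairs: pd.DataFrame  # gene, meth_diff, log2fc
    r: float
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    label: str


def normalize_counts(table: CountTable) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and normalised counts.

    The reference is the per-gene geometric mean over samples, computed on
    genes with nonzero counts everywhere; each sample's factor is the median
    ratio of its counts to the reference.
    """
    counts = table.counts.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; add a pseudocount upstream"
        )
    ref = np.exp(np.mean(np.log(counts[all_nonzero]), axis=1))
    factors = np.median(counts[all_nonzero] / ref[:, None], axis=0)
    size_factors = pd.Series(factors, index=table.counts.columns)
    normalized = table.counts / size_factors
    return size_factors, normalized


def log2_fold_change(
    normalized: pd.DataFrame,
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2((mean_a + pc) / (mean_b + pc)); antisymmetric in group swap."""
    cols_a = [s for s in normalized.columns if groups[s] == group_a]
    cols_b = [s for s in normalized.columns if groups[s] == group_b]
    if not cols_a or not cols_b:
        raise KeyError(f"groups {group_a!r}/{group_b!r} not both present")
    mean_a = normalized[cols_a].mean(axis=1)
    mean_b = normalized[cols_b].mean(axis=1)
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount))


def rpkm(table: CountTable) -> pd.DataFrame:
    """Reads per kilobase (maximum transcript length) per million mapped reads."""
    libsize = table.counts.sum(axis=0)
    if (libsize == 0).any():
        empty = list(libsize.index[libsize == 0])
        raise ValueError(f"zero library size for samples {empty}")
    length_kb = table.lengths.reindex(table.counts.index) / 1000.0
    return table.counts.div(length_kb, axis=0).div(libsize / 1e6, axis=1)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def differential_expression(
    table: CountTable, group_a: str, group_b: str, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene DE records between two groups.

    Columns: log2_fold_change, p_value (Welch t on log2(normalised+1)),
    p_adjusted (BH), mean_a, mean_b, rpkm_a, rpkm_b.
    """
    _, normalized = normalize_counts(table)
    cols_a = table.samples_in_group(group_a)
    cols_b = table.samples_in_group(group_b)
    lfc = log2_fold_change(normalized, table.groups, group_a, group_b, pseudocount)
    log_a = np.log2(normalized[cols_a].to_numpy() + 1.0)
    log_b = np.log2(normalized[cols_b].to_numpy() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    rpkm_all = rpkm(table)
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "p_adjusted": benjamini_hochberg(p),
            "mean_a": normalized[cols_a].mean(axis=1),
            "mean_b": normalized[cols_b].mean(axis=1),
            "rpkm_a": rpkm_all[cols_a].mean(axis=1),
            "rpkm_b": rpkm_all[cols_b].mean(axis=1),
        },
        index=table.counts.index,
    )


def de_filter(
    records: pd.DataFrame, min_abs_lfc: float = 2.0, max_padj: float = 0.05
) -> pd.DataFrame:
    """Keep records with |log2FC| >= min_abs_lfc AND adjusted p <= max_padj."""
    keep = (records["log2_fold_change"].abs() >= min_abs_lfc) & (
        records["p_adjusted"] <= max_padj
    )
    return records.loc[keep]


def classify_correlation(r: float) -> str:
    """Correlation-strength label on half-open |R| bins.

    negligible (|R| <= 0.3), low (0.3 < |R| <= 0.5), moderate
    (0.5 < |R| <= 0.7), high (0.7 < |R| <= 0.9), very high (0.9 < |R| <= 1);
    the bins are stated for negative R and applied symmetrically to
    positive values.
    """
    if abs(r) > 1:
        raise ValueError(f"|R| must be <= 1, got {r}")
    a = abs(r)
    if a <= 0.3:
        return "negligible"
    if a <= 0.5:
        return "low"
    if a <= 0.7:
        return "moderate"
    if a <= 0.9:
        return "high"
    return "very high"


def correlate_pairs(meth_diffs: np.ndarray, log2fcs: np.ndarray, genes=None) -> CorrelationResult:
    """Pearson correlation between methylation differences and log2 fold-changes."""
    x = np.asarray(meth_diffs, dtype=float)
    y = np.asarray(log2fcs, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired marker genes")
    res = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    r = float(res.statistic)
    pairs = pd.DataFrame(
        {"gene": genes if genes is not None else np.arange(len(x)), "meth_diff": x, "log2fc": y}
    )
    return CorrelationResult(
        pairs=pairs,
        r=r,
        r_squared=r * r,
        p_value=float(res.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        label=classify_correlation(r),
    )


def methylation_expression_correlation(
    markers,
    lfc: pd.Series,
    target: str,
    other: str,
) -> CorrelationResult:
    """Correlate marker-region methylation differences with expression changes.

    For each marker gene (of either compared population) the x value is the
    region-mean methylation difference ``target - other`` and the y value the
    gene's log2 fold-change ``target vs other``; hypomethylation coupled to
    up-regulation yields negative R.
    """
    xs, ys, genes = [], [], []
    for m in markers:
        gene = m.gene_id or m.gene_name
        if gene not in lfc.index:
            continue
        mt, mo = m.pop_means.get(target), m.pop_means.get(other)
        if mt is None or mo is None or np.isnan(mt) or np.isnan(mo):
            continue
        xs.append(mt - mo)
        ys.append(float(lfc[gene]))
        genes.append(gene)
    return correlate_pairs(np.array(xs), np.array(ys), genes=genes)
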