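"""Pairwise DMR detection on per-CpG methylation difference tracks.

A DMR is a contiguous run of >=3 CpGs whose mean methylation difference
between the two compared samples is >=25% in absolute value.  Detection is
deterministic recursive segmentation: within each chromosome block (blocks
are pre-split wherever adjacent CpGs lie more than ``max_cpg_gap`` apart)
the contiguous window of >= ``min_cpgs`` CpGs maximising ``|mean diff|`` is
located by a prefix-sum scan; if it reaches ``min_diff`` it is accepted,
greedily absorbs flanking CpGs whose own same-sign ``|diff|`` is >=
``min_diff``, and the two remainders are segmented recursively.  Ties in the
window scan are broken toward the longer, then the leftmost window.

Each DMR is scored with a two-sided exact Kolmogorov-Smirnov test between
the two samples' per-CpG level vectors within the region, an unreplicated
1-vs-1 analogue of distribution-level DMR testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy import stats

from .methylome_io import MethylMatrix

#: above this many CpGs per block the exact window scan hands over to a
#: split-and-recurse heuristic (split at the widest internal CpG gap)
EXACT_SCAN_LIMIT = 5000


@dataclass
class MethDiffTrack:
    """Per-CpG ``level_a - level_b`` for one sample pair (NaN where undefined)."""

    sample_a: str
    sample_b: str
    chroms: np.ndarray
    positions: np.ndarray
    diffs: np.ndarray

    @property
    def comparison(self) -> tuple[str, str]:
        return (self.sample_a, self.sample_b)


@dataclass
class DMR:
    """A contiguous differentially methylated region from one comparison.

    ``start``/``end`` are the 0-based half-open span from the first to the
    last member CpG (end = last position + 1); ``mean_diff`` is the mean of
    the member CpGs' diffs, positive when sample_a is more methylated.
    """

    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_diff: float
    comparison: tuple[str, str]
    cpg_positions: np.ndarray
    p_value: float | None = None

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def per_cpg_difference(matrix: MethylMatrix, sample_a: str, sample_b: str) -> MethDiffTrack:
    """Per-CpG methylation difference ``a - b``; antisymmetric under swap."""
    ia, ib = matrix.sample_index(sample_a), matrix.sample_index(sample_b)
    return MethDiffTrack(
        sample_a=sample_a,
        sample_b=sample_b,
        chroms=matrix.chroms,
        positions=matrix.positions,
        diffs=matrix.levels[ia] - matrix.levels[ib],
    )


def _iter_blocks(
    chroms: np.ndarray, positions: np.ndarray, max_cpg_gap: int
) -> Iterator[tuple[int, int]]:
    """Yield [i, j) index ranges of CpGs on one chromosome with gaps <= max_cpg_gap."""
    n = len(positions)
    if n == 0:
        return
    new_chrom = np.ones(n, dtype=bool)
    new_chrom[1:] = chroms[1:] != chroms[:-1]
    gap_break = np.zeros(n, dtype=bool)
    gap_break[1:] = (positions[1:] - positions[:-1]) > max_cpg_gap
    starts = np.flatnonzero(new_chrom | gap_break)
    bounds = np.append(starts, n)
    for i, j in zip(bounds[:-1], bounds[1:]):
        yield int(i), int(j)


def _best_window(values: np.ndarray, min_cpgs: int) -> tuple[int, int, float] | None:
    """Window of length >= min_cpgs maximising |mean|; ties -> longer, then leftmost.

    Returns (start, length, mean) in local indices, or None if too short.
    """
    n = len(values)
    if n < min_cpgs:
        return None
    prefix = np.concatenate(([0.0], np.cumsum(values)))
    best: tuple[float, int, int, float] | None = None  # (|mean|, length, -start, mean)
    for length in range(min_cpgs, n + 1):
        means = (prefix[length:] - prefix[:-length]) / length
        k = int(np.argmax(np.abs(means)))
        cand = (abs(float(means[k])), length, -k, float(means[k]))
        if best is None or cand > best:
            best = cand
    _, length, neg_start, mean = best
    return (-neg_start, length, mean)


def _segment_block(
    values: np.ndarray,
    gaps: np.ndarray,
    lo: int,
    hi: int,
    min_cpgs: int,
    min_diff: float,
    out: list[tuple[int, int]],
) -> None:
    """Recursively collect qualifying [i, j) windows within values[lo:hi].

    ``gaps[k]`` is the bp distance from CpG k-1 to CpG k (0 at index 0).
    """
    n = hi - lo
    if n < min_cpgs:
        return
    if n > EXACT_SCAN_LIMIT:
        split = lo + 1 + int(np.argmax(gaps[lo + 1 : hi]))
        _segment_block(values, gaps, lo, split, min_cpgs, min_diff, out)
        _segment_block(values, gaps, split, hi, min_cpgs, min_diff, out)
        return
    win = _best_window(values[lo:hi], min_cpgs)
    if win is None:
        return
    start, length, mean = win
    if abs(mean) < min_diff:
        return
    i, j = lo + start, lo + start + length
    sign = 1.0 if mean >= 0 else -1.0
    # a region must contain >= min_cpgs CpGs that are differentially
    # methylated on their own; a window carried over the threshold by two
    # extreme CpGs is not a DMR, but its flanks may still hold one
    qualifying = int(np.sum(sign * values[i:j] >= min_diff))
    if qualifying >= min_cpgs:
        # absorb flanking CpGs that are themselves differentially methylated
        # in the same direction: this is what makes accepted regions maximal
        while i > lo and sign * values[i - 1] >= min_diff:
            i -= 1
        while j < hi and sign * values[j] >= min_diff:
            j += 1
        out.append((i, j))
    _segment_block(values, gaps, lo, i, min_cpgs, min_diff, out)
    _segment_block(values, gaps, j, hi, min_cpgs, min_diff, out)


def segment_dmrs(
    track: MethDiffTrack,
    min_cpgs: int = 3,
    min_diff: float = 0.25,
    max_cpg_gap: int = 500,
) -> list[DMR]:
    """Segment a difference track into non-overlapping DMRs (unscored)."""
    if min_cpgs < 2:
        raise ValueError("min_cpgs must be >= 2")
    defined = ~np.isnan(track.diffs)
    chroms = track.chroms[defined]
    positions = track.positions[defined]
    values = track.diffs[defined]
    dmrs: list[DMR] = []
    gaps = np.zeros(len(values), dtype=np.int64)
    if len(values) > 1:
        gaps[1:] = positions[1:] - positions[:-1]
    for lo, hi in _iter_blocks(chroms, positions, max_cpg_gap):
        found: list[tuple[int, int]] = []
        _segment_block(values, gaps, lo, hi, min_cpgs, min_diff, found)
        for i, j in found:
            member = values[i:j]
            dmrs.append(
                DMR(
                    chrom=str(chroms[i]),
                    start=int(positions[i]),
                    end=int(positions[j - 1]) + 1,
                    n_cpgs=j - i,
                    mean_diff=float(np.mean(member)),
                    comparison=track.comparison,
                    cpg_positions=positions[i:j].copy(),
                )
            )
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return dmrs


def score_dmr(
    region_diffs: np.ndarray, levels_a: np.ndarray, levels_b: np.ndarray, min_cpgs: int = 3
) -> float:
    """Two-sided exact KS p-value between the region's two level vectors.

    Symmetric under sample swap; identical vectors give p = 1.
    """
    levels_a = np.asarray(levels_a, dtype=float)
    levels_b = np.asarray(levels_b, dtype=float)
    ok = ~(np.isnan(levels_a) | np.isnan(levels_b))
    if ok.sum() < min_cpgs:
        raise ValueError(
            f"region has {int(ok.sum())} paired CpGs, needs >= {min_cpgs}"
        )
    a, b = levels_a[ok], levels_b[ok]
    if np.array_equal(a, b):
        return 1.0
    method = "exact" if max(len(a), len(b)) <= 100 else "auto"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def _attach_scores(dmrs: list[DMR], matrix: MethylMatrix) -> list[DMR]:
    pos_index = {
        (c, p): k for k, (c, p) in enumerate(zip(matrix.chroms, matrix.positions.tolist()))
    }
    scored = []
    for dmr in dmrs:
        idx = np.array([pos_index[(dmr.chrom, int(p))] for p in dmr.cpg_positions])
        ia = matrix.sample_index(dmr.comparison[0])
        ib = matrix.sample_index(dmr.comparison[1])
        p = score_dmr(
            matrix.levels[ia, idx] - matrix.levels[ib, idx],
            matrix.levels[ia, idx],
            matrix.levels[ib, idx],
            min_cpgs=2,
        )
        scored.append(replace(dmr, p_value=p))
    return scored


def pairwise_dmr_tables(
    matrix: MethylMatrix,
    min_cpgs: int = 3,
    min_diff: float = 0.25,
    max_cpg_gap: int = 500,
    max_p: float | None = 0.01,
) -> dict[tuple[str, str], list[DMR]]:
    """DMR tables for every unordered sample pair (diff = first - second).

    ``max_p`` applies the DMR significance threshold used downstream of
    detection (p <= 0.01); pass ``None`` to keep all segmented regions.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least two samples")
    tables: dict[tuple[str, str], list[DMR]] = {}
    for a, b in combinations(matrix.samples, 2):
        track = per_cpg_difference(matrix, a, b)
        dmrs = _attach_scores(segment_dmrs(track, min_cpgs, min_diff, max_cpg_gap), matrix)
        if max_p is not None:
            dmrs = [d for d in dmrs if d.p_value is not None and d.p_value <= max_p]
        tables[(a, b)] = dmrs
    return tables


def write_dmr_bed(dmrs: list[DMR], path: str | Path) -> None:
    """Write DMRs as BED6+3: name, score=round(1000*|mean_diff|), n_cpgs, mean_diff, p."""
    with open(path, "w") as fh:
        for k, d in enumerate(dmrs):
            name = f"{d.comparison[0]}_vs_{d.comparison[1]}#{k}"
            score = int(round(1000 * abs(d.mean_diff)))
            p = "NA" if d.p_value is None else f"{d.p_value:.6g}"
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{name}\t{score}\t.\t"
                f"{d.n_cpgs}\t{d.mean_diff:.6f}\t{p}\n"
            )
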