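"""Reading, writing and filtering of per-CpG methylomes and gene annotation.

The on-disk methylation format is a bedGraph dialect: one CpG per line with
``chrom  start  end  meth_fraction  [meth_count  total_count]`` where
``end == start + 1`` and ``start`` is the 0-based position of the C of a CpG
on the plus strand (symmetric CpG methylation is strand-merged by the
upstream caller).  All coordinates are 0-based half-open internally; GTF's
1-based closed convention is converted on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["chrom", "pos", "level", "meth_count", "total_count"]


class MethylationParseError(ValueError):
    """Raised for malformed methylation-table lines (names the line number)."""


@dataclass(frozen=True)
class CpGMeasurement:
    """Methylation level and read coverage of one CpG in one sample.

    ``total_count`` may be ``-1`` when the input table carried no count
    columns ("unknown-positive" coverage: the CpG was observed but depth is
    not recorded).
    """

    chrom: str
    pos: int
    meth_level: float
    meth_count: int = -1
    total_count: int = -1

    def __post_init__(self) -> None:
        if not 0.0 <= self.meth_level <= 1.0:
            raise ValueError(f"meth_level {self.meth_level} outside [0, 1]")
        if self.total_count >= 0:
            if not 0 <= self.meth_count <= self.total_count:
                raise ValueError(
                    f"meth_count {self.meth_count} not in [0, total_count={self.total_count}]"
                )
            if self.total_count > 0:
                implied = self.meth_count / self.total_count
                if abs(self.meth_level - implied) > 1e-6:
                    raise ValueError(
                        f"meth_level {self.meth_level} inconsistent with "
                        f"{self.meth_count}/{self.total_count}"
                    )


@dataclass
class MethylMatrix:
    """Per-CpG methylation levels and coverages across samples.

    ``levels`` and ``coverages`` are ``(n_samples, n_cpgs)`` arrays on a
    shared catalog sorted by ``(chrom, pos)``.  A missing level is NaN and
    implies coverage 0.
    """

    chroms: np.ndarray  # (n_cpgs,) str
    positions: np.ndarray  # (n_cpgs,) int64
    samples: list[str]
    levels: np.ndarray  # (n_samples, n_cpgs) float64, NaN = missing
    coverages: np.ndarray  # (n_samples, n_cpgs) int64

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.levels = np.asarray(self.levels, dtype=np.float64)
        self.coverages = np.asarray(self.coverages, dtype=np.int64)
        if self.levels.shape != self.coverages.shape:
            raise ValueError("levels and coverages must have identical shape")
        if self.levels.shape != (len(self.samples), self.n_cpgs):
            raise ValueError("matrix shape does not match samples x catalog")
        order = np.lexsort((self.positions, self.chroms.astype(str)))
        if not np.array_equal(order, np.arange(self.n_cpgs)):
            raise ValueError("CpG catalog must be sorted by (chrom, pos)")

    @property
    def n_cpgs(self) -> int:
        return len(self.positions)

    @property
    def catalog(self) -> list[tuple[str, int]]:
        return list(zip(self.chroms.tolist(), self.positions.tolist()))

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"unknown sample {name!r}") from None

    def subset(self, mask: np.ndarray) -> "MethylMatrix":
        mask = np.asarray(mask)
        return MethylMatrix(
            chroms=self.chroms[mask],
            positions=self.positions[mask],
            samples=list(self.samples),
            levels=self.levels[:, mask],
            coverages=self.coverages[:, mask],
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene coordinates with the TSS of the longest annotated transcript.

    All coordinates 0-based half-open; ``tss`` is the 5' end of the
    representative (longest) transcript in transcript orientation, so for a
    minus-strand gene it is the maximum transcript coordinate minus one.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...] = ()
    transcript_length: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.gene_start <= self.tss < self.gene_end:
            raise ValueError(
                f"TSS {self.tss} outside gene span [{self.gene_start}, {self.gene_end})"
            )


def read_methylation_table(
    path: str | Path, sample_name: str, percent_scale: bool = False
) -> pd.DataFrame:
    """Read one sample's bedGraph-dialect methylation table.

    Returns a DataFrame with columns ``chrom, pos, level, meth_count,
    total_count`` sorted by (chrom, pos); count columns are ``-1`` when the
    file has only four columns.  ``percent_scale=True`` divides the printed
    fraction column by 100 (for 0-100 inputs).
    """
    path = Path(path)
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in (4, 6):
                raise MethylationParseError(
                    f"{path.name}:{lineno}: expected 4 or 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                frac = float(fields[3])
            except ValueError as exc:
                raise MethylationParseError(f"{path.name}:{lineno}: {exc}") from None
            if end != start + 1:
                raise MethylationParseError(
                    f"{path.name}:{lineno}: end must equal start+1 for per-CpG rows"
                )
            if percent_scale:
                frac /= 100.0
            if not 0.0 <= frac <= 1.0:
                raise MethylationParseError(
                    f"{path.name}:{lineno}: methylation fraction {frac} outside [0, 1]"
                )
            if len(fields) == 6:
                try:
                    mc, tc = int(fields[4]), int(fields[5])
                except ValueError as exc:
                    raise MethylationParseError(f"{path.name}:{lineno}: {exc}") from None
                if not 0 <= mc <= tc:
                    raise MethylationParseError(
                        f"{path.name}:{lineno}: meth_count {mc} not in [0, {tc}]"
                    )
            else:
                mc, tc = -1, -1
            rows.append((chrom, start, frac, mc, tc))
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    if len(df):
        sorted_df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if not df[["chrom", "pos"]].equals(sorted_df[["chrom", "pos"]]):
            logger.info("%s (%s): input not sorted; sorted on load", path.name, sample_name)
        df = sorted_df
    df.attrs["sample_name"] = sample_name
    return df


def build_matrix(per_sample: Mapping[str, pd.DataFrame]) -> MethylMatrix:
    """Assemble per-sample measurement tables into a MethylMatrix.

    The catalog is the sorted union of all samples' CpGs; a sample missing a
    CpG gets coverage 0 and a NaN level.  Unknown coverage (-1 sentinel from
    four-column input) is stored as coverage 1 ("observed at least once").
    """
    if not per_sample:
        raise ValueError("at least one sample required")
    keys: set[tuple[str, int]] = set()
    for name, df in per_sample.items():
        pairs = list(zip(df["chrom"], df["pos"]))
        if len(pairs) != len(set(pairs)):
            dup = pd.Series(pairs).value_counts()
            raise ValueError(
                f"sample {name!r} has duplicate CpG entries, e.g. {dup.index[0]}"
            )
        keys.update(pairs)
    catalog = sorted(keys)
    index = {key: i for i, key in enumerate(catalog)}
    n = len(catalog)
    samples = list(per_sample)
    levels = np.full((len(samples), n), np.nan)
    coverages = np.zeros((len(samples), n), dtype=np.int64)
    for row, name in enumerate(samples):
        df = per_sample[name]
        idx = np.fromiter(
            (index[key] for key in zip(df["chrom"], df["pos"])), dtype=np.int64, count=len(df)
        )
        levels[row, idx] = df["level"].to_numpy()
        cov = df["total_count"].to_numpy(dtype=np.int64)
        coverages[row, idx] = np.where(cov < 0, 1, cov)
    chroms = np.array([c for c, _ in catalog], dtype=object)
    positions = np.array([p for _, p in catalog], dtype=np.int64)
    return MethylMatrix(chroms, positions, samples, levels, coverages)


def filter_by_coverage(
    matrix: MethylMatrix, min_cov: int = 5, min_samples: int = 1
) -> MethylMatrix:
    """Keep CpGs with coverage >= ``min_cov`` in at least ``min_samples`` samples.

    Defaults implement the detection-input rule: coverage of at least five,
    present in at least one sample.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if not 1 <= min_samples <= len(matrix.samples):
        raise ValueError("min_samples must be in [1, n_samples]")
    mask = (matrix.coverages >= min_cov).sum(axis=0) >= min_samples
    return matrix.subset(mask)


def write_matrix(matrix: MethylMatrix, path: str | Path) -> None:
    """Write a MethylMatrix as one wide TSV (levels to 6 decimals, coverages exact)."""
    with open(path, "w") as fh:
        header = ["chrom", "pos"]
        for s in matrix.samples:
            header += [f"{s}.level", f"{s}.cov"]
        fh.write("\t".join(header) + "\n")
        for j in range(matrix.n_cpgs):
            row = [str(matrix.chroms[j]), str(int(matrix.positions[j]))]
            for i in range(len(matrix.samples)):
                lv = matrix.levels[i, j]
                row.append("NA" if math.isnan(lv) else f"{lv:.6f}")
                row.append(str(int(matrix.coverages[i, j])))
            fh.write("\t".join(row) + "\n")


def read_matrix(path: str | Path) -> MethylMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    samples = [c[:-6] for c in df.columns if c.endswith(".level")]
    levels = np.vstack([df[f"{s}.level"].to_numpy(dtype=float) for s in samples])
    coverages = np.vstack([df[f"{s}.cov"].to_numpy(dtype=np.int64) for s in samples])
    return MethylMatrix(
        chroms=df["chrom"].to_numpy(dtype=object),
        positions=df["pos"].to_numpy(dtype=np.int64),
        samples=samples,
        levels=levels,
        coverages=coverages,
    )


def write_methylation_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write one sample's measurements back to the bedGraph dialect."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            base = f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.level:.6f}"
            if row.total_count >= 0:
                fh.write(f"{base}\t{row.meth_count}\t{row.total_count}\n")
            else:
                fh.write(base + "\n")


def _transcript_length(exons: Sequence[tuple[int, int]], start: int, end: int) -> int:
    if exons:
        return sum(e - s for s, e in exons)
    return end - start


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read a GTF/GFF3 annotation into GeneModels (one per gene).

    The representative transcript of a gene is its longest one (exonic
    length; ties broken by transcript id); the gene TSS is that transcript's
    5' end.  Features without coordinates or strand are skipped with a
    warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in "+-":
            logger.warning("gene %s lacks strand; skipped", gene.id)
            continue
        gene_name = gene.attributes.get("gene_name", [""])[0]
        gene_id = gene.attributes.get("gene_id", [gene.id])[0]
        best: tuple[int, str, tuple, int, int] | None = None
        for tx in db.children(gene, featuretype=("transcript", "mRNA")):
            exons = tuple(
                sorted((e.start - 1, e.end) for e in db.children(tx, featuretype="exon"))
            )
            tx_start, tx_end = tx.start - 1, tx.end
            length = _transcript_length(exons, tx_start, tx_end)
            tx_id = tx.attributes.get("transcript_id", [tx.id])[0]
            # longest transcript wins; ties broken by lexicographically
            # smaller transcript id for deterministic reruns
            key = (length, tx_id)
            if best is None or (key[0], ) > (best[0], ) or (
                key[0] == best[0] and key[1] < best[1]
            ):
                best = (length, tx_id, exons, tx_start, tx_end)
        g_start, g_end = gene.start - 1, gene.end
        if best is None:
            exons, tx_start, tx_end, length = (), g_start, g_end, g_end - g_start
        else:
            length, _, exons, tx_start, tx_end = best
        tss = tx_start if gene.strand == "+" else tx_end - 1
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=gene_name,
                chrom=gene.seqid,
                strand=gene.strand,
                tss=tss,
                gene_start=g_start,
                gene_end=g_end,
                exons=exons,
                transcript_length=length,
            )
        )
    if not genes:
        raise ValueError(f"annotation {path} contains no gene features")
    genes.sort(key=lambda g: (g.chrom, g.gene_start, g.gene_id))
    return genes
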