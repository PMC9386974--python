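"""Shared fixtures: tiny hand-built methylomes and the session-wide simulated study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylmark.methylome_io import MethylMatrix, build_matrix, filter_by_coverage
from methylmark.simulate import SimulationConfig, simulate_study


def measurements(rows: list[tuple[str, int, float, int, int]]) -> pd.DataFrame:
    """Build a per-sample measurement table from (chrom, pos, level, mc, tc) rows."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "level", "meth_count", "total_count"])


def matrix_from_levels(
    levels: dict[str, list[float | None]],
    positions: list[int] | None = None,
    chrom: str = "chr1",
    coverage: int = 10,
) -> MethylMatrix:
    """A one-chromosome matrix from per-sample level lists (None = missing)."""
    n = len(next(iter(levels.values())))
    if positions is None:
        positions = [100 * (i + 1) for i in range(n)]
    samples = list(levels)
    lv = np.array(
        [[np.nan if v is None else v for v in levels[s]] for s in samples], dtype=float
    )
    cov = np.where(np.isnan(lv), 0, coverage).astype(np.int64)
    return MethylMatrix(
        chroms=np.array([chrom] * n, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        samples=samples,
        levels=lv,
        coverages=cov,
    )


@pytest.fixture(scope="session")
def default_study():
    """The default simulated study: 5 ILC populations, 50 planted blocks/pair."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_study):
    return filter_by_coverage(default_study.matrix, min_cov=5, min_samples=1)


@pytest.fixture(scope="session")
def default_dmr_tables(default_matrix):
    from methylmark.dmr import pairwise_dmr_tables

    return pairwise_dmr_tables(default_matrix)
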