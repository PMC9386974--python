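"""DMR segmentation, scoring and pairwise tables, checked against an
independent recursive exhaustive-window oracle."""

import math
from itertools import combinations

import numpy as np
import pytest

from conftest import matrix_from_levels
from methylmark.dmr import (
    MethDiffTrack,
    pairwise_dmr_tables,
    per_cpg_difference,
    score_dmr,
    segment_dmrs,
    write_dmr_bed,
)


def make_track(diffs, positions=None, chrom="chr1"):
    diffs = np.asarray(diffs, dtype=float)
    if positions is None:
        positions = np.arange(len(diffs)) * 100
    return MethDiffTrack(
        sample_a="A",
        sample_b="B",
        chroms=np.array([chrom] * len(diffs), dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        diffs=diffs,
    )


# --- independent oracle -----------------------------------------------------

def oracle_segment(values, positions, min_cpgs=3, min_diff=0.25, max_cpg_gap=500):
    """Plain recursive re-statement of the segmentation contract.

    Blocks split at gaps > max_cpg_gap; per block: scan every contiguous
    window of >= min_cpgs CpGs for the largest |mean| (ties: longer, then
    leftmost), accept if >= min_diff, absorb flanking same-sign CpGs with
    |diff| >= min_diff, recurse on the remainders.
    """
    out = []

    def recurse(lo, hi):
        n = hi - lo
        if n < min_cpgs:
            return
        best = None  # (|mean|, length, -start, mean)
        for length in range(min_cpgs, n + 1):
            for start in range(lo, hi - length + 1):
                mean = float(np.mean(values[start : start + length]))
                cand = (abs(mean), length, -(start - lo), mean)
                if best is None or cand > best:
                    best = cand
        _, length, neg_start, mean = best
        if abs(mean) < min_diff:
            return
        i = lo + (-neg_start)
        j = i + length
        sign = 1.0 if mean >= 0 else -1.0
        if sum(sign * values[k] >= min_diff for k in range(i, j)) >= min_cpgs:
            while i > lo and sign * values[i - 1] >= min_diff:
                i -= 1
            while j < hi and sign * values[j] >= min_diff:
                j += 1
            out.append((i, j))
        recurse(lo, i)
        recurse(j, hi)

    block_start = 0
    for k in range(1, len(values) + 1):
        if k == len(values) or positions[k] - positions[k - 1] > max_cpg_gap:
            recurse(block_start, k)
            block_start = k
    return sorted(out)


def random_track(rng, n):
    """Noise track with occasional planted shifted runs."""
    diffs = rng.normal(0, 0.12, size=n)
    for _ in range(rng.integers(0, 4)):
        length = int(rng.integers(3, 15))
        start = int(rng.integers(0, max(n - length, 1)))
        diffs[start : start + length] += rng.choice([-1, 1]) * rng.uniform(0.2, 0.7)
    positions = np.cumsum(rng.integers(10, 800, size=n))
    return np.clip(diffs, -1, 1), positions


class TestSegmentDmrs:
    def test_plateau_in_flat_background_yields_single_dmr(self):
        diffs = [0.05] * 4 + [0.6] * 5 + [0.05] * 4
        (dmr,) = segment_dmrs(make_track(diffs))
        assert dmr.n_cpgs == 5
        assert dmr.mean_diff == pytest.approx(0.6)
        assert dmr.start == 400 and dmr.end == 801

    def test_two_qualifying_cpgs_are_not_enough(self):
        assert segment_dmrs(make_track([0.0, 0.9, 0.9, 0.0])) == []

    def test_uniform_subthreshold_track_yields_nothing(self):
        assert segment_dmrs(make_track([0.10] * 20)) == []

    def test_min_cpgs_below_two_rejected(self):
        with pytest.raises(ValueError):
            segment_dmrs(make_track([0.5] * 5), min_cpgs=1)

    def test_accepted_region_absorbs_qualifying_flank(self):
        # the 0.3 neighbour qualifies on its own and must join the region
        diffs = [0.05, 0.3, 0.6, 0.6, 0.6, 0.6, 0.6, 0.05]
        (dmr,) = segment_dmrs(make_track(diffs))
        assert dmr.n_cpgs == 6
        assert dmr.mean_diff == pytest.approx((0.3 + 5 * 0.6) / 6)

    def test_gap_splits_candidate_region(self):
        positions = [0, 100, 200, 1000, 1100, 1200]
        dmrs = segment_dmrs(make_track([0.6] * 6, positions=positions))
        assert [d.n_cpgs for d in dmrs] == [3, 3]

    def test_sign_coherence_and_threshold_invariants(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            diffs, positions = random_track(rng, 120)
            for d in segment_dmrs(make_track(diffs, positions=positions)):
                member = diffs[np.searchsorted(positions, d.cpg_positions)]
                assert abs(np.mean(member)) >= 0.25
                assert np.sign(np.mean(member)) == np.sign(d.mean_diff)

    def test_matches_exhaustive_oracle_on_random_tracks(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(5, 120))
            diffs, positions = random_track(rng, n)
            called = segment_dmrs(make_track(diffs, positions=positions))
            expected = oracle_segment(diffs, positions)
            got = [
                (int(np.searchsorted(positions, d.cpg_positions[0])),
                 int(np.searchsorted(positions, d.cpg_positions[-1])) + 1)
                for d in called
            ]
            assert sorted(got) == expected


class TestPerCpGDifference:
    def test_difference_and_missing_propagation(self):
        m = matrix_from_levels({"A": [0.9, None], "B": [0.2, 0.5]})
        track = per_cpg_difference(m, "A", "B")
        assert track.diffs[0] == pytest.approx(0.7)
        assert np.isnan(track.diffs[1])

    def test_swap_negates_track(self):
        rng = np.random.default_rng(2)
        m = matrix_from_levels({"A": list(rng.random(20)), "B": list(rng.random(20))})
        fwd = per_cpg_difference(m, "A", "B").diffs
        rev = per_cpg_difference(m, "B", "A").diffs
        np.testing.assert_allclose(fwd, -rev)

    def test_unknown_sample_rejected(self):
        m = matrix_from_levels({"A": [0.5]})
        with pytest.raises(KeyError):
            per_cpg_difference(m, "A", "Z")


class TestScoreDmr:
    def test_identical_vectors_give_p_one(self):
        v = np.array([0.1, 0.5, 0.9, 0.3])
        assert score_dmr(v - v, v, v) == pytest.approx(1.0, abs=1e-9)

    def test_fully_separated_vectors_match_closed_form(self):
        # D = 1 at n = m = 10: exactly 2 of the C(20,10) interleavings
        a = np.full(10, 0.95)
        b = np.full(10, 0.05)
        p = score_dmr(a - b, a, b)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert p < 0.01

    def test_exact_p_matches_enumeration_at_n5(self):
        # enumerate all C(10,5) label assignments of the pooled sample
        rng = np.random.default_rng(3)
        a, b = rng.random(5), rng.random(5)
        pooled = np.concatenate([a, b])
        d_obs = _ks_stat(a, b)
        count = 0
        total = 0
        for idx in combinations(range(10), 5):
            mask = np.zeros(10, dtype=bool)
            mask[list(idx)] = True
            total += 1
            if _ks_stat(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
                count += 1
        assert score_dmr(a - b, a, b) == pytest.approx(count / total, rel=1e-9)

    def test_symmetric_under_sample_swap(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(8), rng.random(8)
        assert score_dmr(a - b, a, b) == pytest.approx(score_dmr(b - a, b, a))

    def test_too_few_paired_values_rejected(self):
        a = np.array([0.5, np.nan, 0.7])
        b = np.array([0.1, 0.2, np.nan])
        with pytest.raises(ValueError):
            score_dmr(a - b, a, b)


def _ks_stat(x, y):
    grid = np.sort(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
    fy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
    return np.max(np.abs(fx - fy))


class TestPairwiseTables:
    @pytest.mark.parametrize("n_samples,n_tables", [(2, 1), (5, 10)])
    def test_one_table_per_unordered_pair(self, n_samples, n_tables):
        rng = np.random.default_rng(5)
        levels = {f"S{i}": list(rng.random(30)) for i in range(n_samples)}
        m = matrix_from_levels(levels)
        assert len(pairwise_dmr_tables(m, max_p=None)) == n_tables

    def test_single_sample_rejected(self):
        m = matrix_from_levels({"A": [0.5] * 5})
        with pytest.raises(ValueError):
            pairwise_dmr_tables(m)

    def test_bed_output_round_trip_fields(self, tmp_path):
        m = matrix_from_levels(
            {"A": [0.9] * 6 + [0.5] * 3, "B": [0.1] * 6 + [0.5] * 3}
        )
        tables = pairwise_dmr_tables(m, max_p=0.05)
        dmrs = tables[("A", "B")]
        assert len(dmrs) == 1 and dmrs[0].p_value <= 0.05
        path = tmp_path / "d.bed"
        write_dmr_bed(dmrs, path)
        fields = path.read_text().strip().split("\t")
        assert fields[0] == "chr1"
        assert int(fields[6]) == 6  # n_cpgs
        assert float(fields[7]) == pytest.approx(0.8)
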