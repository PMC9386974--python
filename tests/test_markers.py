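"""Marker-region extension, region means, ranked selection and smoothing."""

import numpy as np
import pytest

from conftest import matrix_from_levels
from methylmark.dmr import DMR, per_cpg_difference
from methylmark.markers import (
    extend_region,
    marker_matrix,
    region_mean_methylation,
    select_markers,
    smooth_profile,
)
from methylmark.methylome_io import GeneModel
from test_dmr import make_track


def make_dmr_from_track(track, i, j):
    member = track.diffs[i:j]
    return DMR(
        chrom="chr1",
        start=int(track.positions[i]),
        end=int(track.positions[j - 1]) + 1,
        n_cpgs=j - i,
        mean_diff=float(np.mean(member)),
        comparison=("A", "B"),
        cpg_positions=track.positions[i:j].copy(),
    )


class TestExtendRegion:
    def test_stepwise_extension_stops_below_threshold(self):
        # CpGs 3 and 4 flank the DMR over 5..9: 0.30 qualifies, 0.10 does not
        diffs = [0.0, 0.0, 0.0, 0.10, 0.30] + [0.6] * 5 + [0.0]
        track = make_track(diffs)
        dmr = make_dmr_from_track(track, 5, 10)
        ext = extend_region(dmr, track)
        np.testing.assert_array_equal(ext.cpg_positions, track.positions[4:10])
        assert ext.mean_diff == pytest.approx(np.mean(diffs[4:10]))

    def test_no_qualifying_neighbours_leaves_region_unchanged(self):
        diffs = [0.0, 0.1] + [0.6] * 4 + [0.1, 0.0]
        track = make_track(diffs)
        dmr = make_dmr_from_track(track, 2, 6)
        ext = extend_region(dmr, track)
        assert (ext.start, ext.end) == (dmr.start, dmr.end)

    def test_opposite_sign_neighbour_not_included(self):
        diffs = [-0.5] + [0.6] * 4 + [0.0]
        track = make_track(diffs)
        ext = extend_region(make_dmr_from_track(track, 1, 5), track)
        assert ext.cpg_positions[0] == track.positions[1]

    def test_extension_is_monotone_and_idempotent(self):
        rng = np.random.default_rng(8)
        diffs = np.clip(rng.normal(0.3, 0.25, size=40), -1, 1)
        track = make_track(diffs)
        dmr = make_dmr_from_track(track, 15, 20)
        once = extend_region(dmr, track)
        assert once.start <= dmr.start and once.end >= dmr.end
        twice = extend_region(once, track)
        assert (twice.start, twice.end) == (once.start, once.end)

    def test_gap_limit_blocks_extension(self):
        positions = [0, 100, 200, 300, 2000]
        diffs = [0.6] * 5
        track = make_track(diffs, positions=positions)
        ext = extend_region(make_dmr_from_track(track, 0, 4), track, max_cpg_gap=500)
        assert ext.end == 301  # CpG at 2000 is beyond the gap limit


class TestRegionMean:
    def test_mean_of_defined_levels(self):
        m = matrix_from_levels({"A": [0.1, 0.2, 0.3]})
        assert region_mean_methylation(m, "A", "chr1", 0, 1000) == pytest.approx(0.2)

    def test_fully_methylated_region(self):
        m = matrix_from_levels({"A": [1.0, 1.0]})
        assert region_mean_methylation(m, "A", "chr1", 0, 1000) == 1.0

    def test_no_defined_cpgs_flagged_not_determined(self):
        m = matrix_from_levels({"A": [None, None]})
        assert np.isnan(region_mean_methylation(m, "A", "chr1", 0, 1000))

    def test_matches_bruteforce_mean(self):
        rng = np.random.default_rng(1)
        vals = list(rng.random(50))
        m = matrix_from_levels({"A": vals})
        lo, hi = 500, 3100  # positions are 100*(i+1)
        expected = np.mean([v for p, v in zip(m.positions, vals) if lo <= p < hi])
        assert region_mean_methylation(m, "A", "chr1", lo, hi) == pytest.approx(expected)


def _selection_fixture():
    """Four populations; two target-hypomethylated candidate regions with
    different exclusivity, one sub-threshold region, one region without a gene."""
    n = 45
    base = {s: [0.8] * n for s in ("T", "P1", "P2", "P3")}
    # candidate 1: CpGs 0-4, target 0.05, others ~0.5/0.6/0.7 -> exclusivity 0.45
    # candidate 2: CpGs 10-14, target 0.05, others 0.5/0.5/0.3 -> exclusivity 0.25
    # candidate 3: CpGs 20-24, max diff 0.30 -> fails the >40% rule
    # candidate 4: CpGs 35-39, strong but no gene nearby
    for i in range(5):
        base["T"][i] = 0.05
        base["P1"][i], base["P2"][i], base["P3"][i] = 0.5, 0.6, 0.7
        base["T"][10 + i] = 0.05
        base["P1"][10 + i], base["P2"][10 + i], base["P3"][10 + i] = 0.5, 0.5, 0.3
        base["T"][20 + i] = 0.50
        base["T"][35 + i] = 0.05
    m = matrix_from_levels(base)
    genes = [
        GeneModel("GENE_A", "GeneA", "chr1", "+", 150, 150, 550, ()),
        GeneModel("GENE_B", "GeneB", "chr1", "+", 1150, 1150, 1550, ()),
        GeneModel("GENE_C", "GeneC", "chr1", "+", 2150, 2150, 2550, ()),
    ]
    from methylmark.dmr import pairwise_dmr_tables

    tables = pairwise_dmr_tables(m, max_p=None)
    return m, genes, tables


class TestSelectMarkers:
    def test_exclusivity_orders_candidates(self):
        m, genes, tables = _selection_fixture()
        markers = select_markers(tables, m, genes, target="T", assoc_tss_window=300)
        assert [x.gene_id for x in markers[:2]] == ["GENE_A", "GENE_B"]
        assert markers[0].exclusivity == pytest.approx(0.45, abs=0.02)
        assert markers[1].exclusivity == pytest.approx(0.25, abs=0.02)

    def test_subthreshold_candidate_excluded(self):
        m, genes, tables = _selection_fixture()
        markers = select_markers(tables, m, genes, target="T", assoc_tss_window=300)
        assert "GENE_C" not in {x.gene_id for x in markers}

    def test_geneless_candidate_dropped_when_gene_required(self):
        m, genes, tables = _selection_fixture()
        markers = select_markers(tables, m, genes, target="T", assoc_tss_window=300)
        assert all(x.start < 3500 for x in markers)
        relaxed = select_markers(
            tables, m, genes, target="T", assoc_tss_window=300, require_gene=False
        )
        assert any(x.start >= 3500 for x in relaxed)

    def test_unknown_population_rejected(self):
        m, genes, tables = _selection_fixture()
        with pytest.raises(KeyError):
            select_markers(tables, m, genes, target="nope")

    def test_selection_is_deterministic(self):
        m, genes, tables = _selection_fixture()
        a = select_markers(tables, m, genes, target="T", assoc_tss_window=300)
        b = select_markers(tables, m, genes, target="T", assoc_tss_window=300)
        assert [(x.chrom, x.start, x.end) for x in a] == [
            (x.chrom, x.start, x.end) for x in b
        ]


class TestMarkerMatrix:
    def test_single_marker_single_sample_value(self):
        m, genes, tables = _selection_fixture()
        markers = select_markers(tables, m, genes, target="T", assoc_tss_window=300, top=1)
        mat = marker_matrix(markers, m)
        assert mat.shape == (4, 1)
        assert mat.loc["T"].iloc[0] == pytest.approx(0.05)

    def test_values_within_unit_interval_and_target_is_minimum(self):
        m, genes, tables = _selection_fixture()
        markers = select_markers(tables, m, genes, target="T", assoc_tss_window=300)
        mat = marker_matrix(markers, m)
        assert ((mat >= 0) & (mat <= 1)).all().all()
        assert (mat.loc["T"] == mat.min(axis=0)).all()


class TestSmoothProfile:
    def test_constant_input_stays_constant(self):
        m = matrix_from_levels({"A": [0.7] * 10})
        prof = smooth_profile(m, "chr1", 0, 2000)
        np.testing.assert_allclose(prof.values.loc["A"], 0.7)

    def test_isolated_cpg_equals_raw(self):
        m = matrix_from_levels({"A": [0.3, 0.9]}, positions=[100, 5000])
        prof = smooth_profile(m, "chr1", 0, 6000, bandwidth=500)
        np.testing.assert_allclose(prof.values.loc["A"], [0.3, 0.9])

    def test_step_profile_smoothed_monotone(self):
        m = matrix_from_levels({"A": [0.1] * 10 + [0.9] * 10}, positions=list(range(0, 2000, 100)))
        prof = smooth_profile(m, "chr1", 0, 2000)
        values = prof.values.loc["A"].to_numpy()
        assert np.all(np.diff(values) >= -1e-12)
        assert values.min() >= 0.1 - 1e-12 and values.max() <= 0.9 + 1e-12

    def test_matches_direct_kernel_computation(self):
        rng = np.random.default_rng(2)
        levels = list(rng.random(15))
        m = matrix_from_levels({"A": levels})
        m.coverages = rng.integers(1, 30, size=m.coverages.shape)
        bw = 500
        prof = smooth_profile(m, "chr1", 0, 5000, bandwidth=bw)
        pos = m.positions.astype(float)
        for k in range(len(pos)):
            d = np.abs(pos - pos[k])
            w = np.exp(-0.5 * (d / (bw / 2)) ** 2) * (d <= bw) * m.coverages[0]
            expected = np.sum(w * m.levels[0]) / np.sum(w)
            assert prof.values.loc["A"].iloc[k] == pytest.approx(expected)

    def test_empty_window_rejected(self):
        m = matrix_from_levels({"A": [0.5]})
        with pytest.raises(ValueError):
            smooth_profile(m, "chr1", 90000, 91000)
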