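"""Unique-DMR merging, the triple contrast filter and the top hyper/hypo ledgers."""

import numpy as np
import pytest

from conftest import matrix_from_levels
from methylmark.contrast import (
    filter_contrast,
    top_hyper_hypo,
    unique_dmrs,
)
from methylmark.dmr import DMR
from methylmark.methylome_io import GeneModel


def span_dmr(start, end, mean_diff=0.6, chrom="chr1", comparison=("A", "B")):
    step = max((end - start) // 3, 1)
    return DMR(
        chrom=chrom,
        start=start,
        end=end,
        n_cpgs=3,
        mean_diff=mean_diff,
        comparison=comparison,
        cpg_positions=np.array([start, start + step, end - 1]),
    )


class TestUniqueDmrs:
    def test_identical_span_in_three_tables_collapses_to_one(self):
        tables = {
            ("A", "X"): [span_dmr(100, 200)],
            ("A", "Y"): [span_dmr(100, 200)],
            ("B", "X"): [span_dmr(100, 200)],
        }
        assert len(unique_dmrs(tables)) == 1

    def test_disjoint_spans_stay_separate(self):
        tables = {("A", "X"): [span_dmr(100, 200), span_dmr(500, 600)]}
        assert len(unique_dmrs(tables)) == 2

    def test_overlap_takes_union_span_and_max_abs_diff(self):
        tables = {
            ("A", "X"): [span_dmr(100, 250, mean_diff=0.3)],
            ("A", "Y"): [span_dmr(200, 400, mean_diff=-0.9)],
        }
        (merged,) = unique_dmrs(tables)
        assert (merged.start, merged.end) == (100, 400)
        assert merged.mean_diff == -0.9

    def test_matches_interval_union_oracle(self):
        rng = np.random.default_rng(0)
        tables = {}
        intervals = []
        for t in range(4):
            dmrs = []
            for _ in range(30):
                s = int(rng.integers(0, 10000))
                e = s + int(rng.integers(50, 400))
                dmrs.append(span_dmr(s, e, mean_diff=float(rng.uniform(0.25, 1))))
                intervals.append((s, e))
            tables[("A", f"T{t}")] = dmrs
        merged = unique_dmrs(tables)
        # brute-force interval union
        intervals.sort()
        union = []
        for s, e in intervals:
            if union and s < union[-1][1]:
                union[-1] = (union[-1][0], max(union[-1][1], e))
            else:
                union.append((s, e))
        assert [(d.start, d.end) for d in merged] == union

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            unique_dmrs({})


def contrast_fixture():
    """Three group-A and two group-B unicates over four candidate regions.

    Region 1 (CpGs 0-2):   consistent hyper in A (all cross diffs >= 0.5)
    Region 2 (CpGs 10-12): one cross pair at 0.45 -> fails "in all comparisons"
    Region 3 (CpGs 20-22): consistent but near a placeholder-named gene
    Region 4 (CpGs 30-32): consistent hypo in A
    """
    n = 35
    lv = {s: [0.5] * n for s in ("A1", "A2", "A3", "B1", "B2")}
    for i in (0, 1, 2, 3, 4):  # CpGs 3-4 form a second block at the same locus
        for a in ("A1", "A2", "A3"):
            lv[a][i] = 0.9
        lv["B1"][i], lv["B2"][i] = 0.2, 0.3
    for i in (10, 11, 12):
        for a in ("A1", "A2", "A3"):
            lv[a][i] = 0.9
        lv["B1"][i], lv["B2"][i] = 0.2, 0.45  # A-B2 diff = 0.45 < 0.5
    for i in (20, 21, 22):
        for a in ("A1", "A2", "A3"):
            lv[a][i] = 0.9
        lv["B1"][i], lv["B2"][i] = 0.1, 0.1
    for i in (30, 31, 32):
        for a in ("A1", "A2", "A3"):
            lv[a][i] = 0.05
        lv["B1"][i], lv["B2"][i] = 0.8, 0.9
    matrix = matrix_from_levels(lv)
    # positions are 100*(i+1): regions at [100,300], [1100,1300], ...
    genes = [
        GeneModel("G1", "Alpha", "chr1", "+", 150, 150, 600, ()),
        GeneModel("G2", "Beta", "chr1", "+", 1150, 1150, 1600, ()),
        GeneModel("G3", "Gm9999", "chr1", "+", 2150, 2150, 2600, ()),
        GeneModel("G4", "Delta", "chr1", "+", 3150, 3150, 3600, ()),
    ]
    dmrs = [
        span_dmr(100, 301),
        span_dmr(1100, 1301),
        span_dmr(2100, 2301),
        span_dmr(3100, 3301, mean_diff=-0.8),
    ]
    groups_a = ["A1", "A2", "A3"]
    groups_b = ["B1", "B2"]
    return matrix, genes, dmrs, groups_a, groups_b


class TestFilterContrast:
    def test_one_failing_cross_comparison_excludes(self):
        matrix, genes, dmrs, ga, gb = contrast_fixture()
        entries = filter_contrast(dmrs, matrix, genes, ga, gb)
        assert all(e.start != 1100 for e in entries)

    def test_placeholder_gene_name_excludes(self):
        matrix, genes, dmrs, ga, gb = contrast_fixture()
        entries = filter_contrast(dmrs, matrix, genes, ga, gb)
        assert all(e.gene_name != "Gm9999" for e in entries)
        relaxed = filter_contrast(
            dmrs, matrix, genes, ga, gb, require_canonical_name=False
        )
        assert any(e.gene_name == "Gm9999" for e in relaxed)

    def test_distant_tss_excludes(self):
        matrix, genes, dmrs, ga, gb = contrast_fixture()
        far = [span_dmr(100, 301)]
        genes_far = [GeneModel("G1", "Alpha", "chr1", "+", 6501, 6501, 9000, ())]
        assert filter_contrast(far, matrix, genes_far, ga, gb) == []
        near = [GeneModel("G1", "Alpha", "chr1", "+", 5200, 5200, 9000, ())]
        assert len(filter_contrast(far, matrix, near, ga, gb)) == 1

    def test_directions_and_group_diff_signs(self):
        matrix, genes, dmrs, ga, gb = contrast_fixture()
        entries = filter_contrast(dmrs, matrix, genes, ga, gb)
        by_gene = {e.gene_name: e for e in entries}
        assert by_gene["Alpha"].direction == "hyper"
        assert by_gene["Delta"].direction == "hypo"

    def test_survivors_match_bruteforce_triple_filter(self):
        rng = np.random.default_rng(7)
        n = 200
        lv = {s: list(rng.random(n)) for s in ("A1", "A2", "B1", "B2")}
        matrix = matrix_from_levels(lv)
        genes = []
        for k in range(20):
            tss = int(rng.integers(0, 100 * n))
            name = rng.choice(["Canon%d" % k, "Gm%d" % k, "%dRik" % k])
            genes.append(GeneModel(f"G{k:02d}", str(name), "chr1", "+", tss, tss, tss + 500, ()))
        dmrs = []
        for _ in range(60):
            s = int(rng.integers(0, 100 * n - 500))
            dmrs.append(span_dmr(s, s + int(rng.integers(100, 500))))
        ga, gb = ["A1", "A2"], ["B1", "B2"]
        got = {(e.start, e.end) for e in filter_contrast(dmrs, matrix, genes, ga, gb)}
        # brute force
        import re
        from methylmark.annotation import _signed_tss_distance
        from methylmark.markers import region_mean_methylation

        expected = set()
        for d in dmrs:
            means = {
                s: region_mean_methylation(matrix, s, d.chrom, d.start, d.end)
                for s in ga + gb
            }
            if any(np.isnan(v) for v in means.values()):
                continue
            cross = [means[a] - means[b] for a in ga for b in gb]
            if not (min(cross) >= 0.5 or max(cross) <= -0.5):
                continue
            dists = [
                (abs(_signed_tss_distance(d.start, d.end, g.tss, g.strand)), g.gene_id, g)
                for g in genes
            ]
            _, _, gene = min(dists)
            dist = _signed_tss_distance(d.start, d.end, gene.tss, gene.strand)
            if abs(dist) > 5000:
                continue
            if re.match(r"^(Gm\d+|.*Rik)$", gene.gene_name):
                continue
            expected.add((d.start, d.end))
        assert got == expected


class TestTopHyperHypo:
    def test_plot_table_has_k_times_n_rows_per_gene(self):
        matrix, genes, dmrs, ga, gb = contrast_fixture()
        # second DMR at the same gene locus (k = 2)
        extra = span_dmr(400, 501)
        entries = filter_contrast(dmrs + [extra], matrix, genes, ga, gb)
        hyper, hypo, plot = top_hyper_hypo(entries, ga, gb, n=75)
        alpha_rows = plot[plot.gene == "Alpha"]
        assert len(alpha_rows) == 2 * len(ga + gb)

    def test_sign_partition_of_ledgers(self):
        matrix, genes, dmrs, ga, gb = contrast_fixture()
        entries = filter_contrast(dmrs, matrix, genes, ga, gb)
        hyper, hypo, _ = top_hyper_hypo(entries, ga, gb)
        assert all(e.group_diff > 0 for e in hyper.entries)
        assert all(e.group_diff < 0 for e in hypo.entries)

    def test_top_n_membership_matches_bruteforce_sort(self):
        rng = np.random.default_rng(8)
        from methylmark.contrast import ContrastEntry

        entries = [
            ContrastEntry(
                chrom="chr1",
                start=i * 100,
                end=i * 100 + 50,
                gene_id=f"G{i}",
                gene_name=f"G{i}",
                tss_distance=0,
                group_diff=float(rng.uniform(-1, 1)),
                min_abs_cross_diff=0.5,
                sample_means={},
            )
            for i in range(100)
        ]
        hyper, hypo, _ = top_hyper_hypo(entries, ["A"], ["B"], n=10)
        pos = sorted((e for e in entries if e.group_diff > 0),
                     key=lambda e: -abs(e.group_diff))[:10]
        assert [e.gene_id for e in hyper.entries] == [e.gene_id for e in pos]
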