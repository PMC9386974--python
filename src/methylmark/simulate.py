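"""Ground-truth simulation of multi-population methylomes and expression.

The generator emulates the statistical structure of a WGBS marker-region
study on innate lymphoid cells: a small genome whose CpGs sit in clustered
islands (the natural home of regulatory DMRs), gene models with promoter
islands, per-population methylomes that share a high Beta-distributed
background level and carry planted population-specific hypomethylated
blocks, binomial sampling noise at Poisson read coverage, expression counts
whose log2 fold-changes anticorrelate with planted methylation differences
at marker genes, and a sequence motif written into a fraction of one
population's hypomethylated regions.

Everything is deterministic under the config seed, and every emitted file
is a valid input for the corresponding analysis stage.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .methylome_io import GeneModel, MethylMatrix
from .motifs import PWM, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions.

    Defaults give ~20,000 CpGs on 2 x 2 Mb chromosomes, five unicate ILC
    populations, 25 exclusive hypomethylated blocks per population (50 per
    pairwise comparison) with depth Delta ~ U[0.4, 0.8], of which 8 are
    marker blocks in gene promoters at Delta ~ U[0.5, 0.8] coupled to
    expression with slope 4 and noise sigma 0.35 (latent methylation-
    expression correlation R ~ -0.8), and Poisson(20) read coverage.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 2_000_000
    islands_per_chromosome: int = 560
    far_islands_per_chromosome: int = 80  # intergenic islands > 5 kb from any TSS
    island_cpgs: tuple[int, int] = (5, 30)
    cpg_spacing: tuple[int, int] = (15, 45)
    genes_per_chromosome: int = 120
    gene_length: tuple[int, int] = (4000, 8000)
    noncanonical_gene_fraction: float = 0.1
    populations: tuple[str, ...] = ("ILC1", "ILC2", "ILC3", "LTi", "NK")
    groups: dict[str, tuple[str, ...]] | None = None
    exclusive_blocks_per_population: int = 25
    marker_genes_per_population: int = 8
    block_cpgs: tuple[int, int] = (5, 20)
    delta_range: tuple[float, float] = (0.4, 0.8)
    marker_delta_range: tuple[float, float] = (0.5, 0.8)
    shared_blocks: int = 0
    shared_pair: tuple[str, str] = ("ILC3", "LTi")
    lineage_blocks_per_direction: int = 0
    lineage_delta_range: tuple[float, float] = (0.5, 0.8)
    background_beta: tuple[float, float] = (8.0, 2.0)
    block_background_beta: tuple[float, float] = (25.0, 3.0)
    jitter_sd: float = 0.02
    coverage_mean: float = 20.0
    expression_populations: tuple[str, ...] | None = None
    expression_replicates: int = 3
    expression_mean: float = 200.0
    expression_log_sd: float = 1.0
    expression_dispersion: float = 0.1
    coupling_slope: float = 4.0
    coupling_sigma: float = 0.35
    motif_consensus: str = "TGACTCAG"
    motif_fraction: float = 0.8
    motif_population: str = "ILC2"
    n_random_gene_sets: int = 30
    gene_set_size: tuple[int, int] = (10, 50)

    def __post_init__(self) -> None:
        if not 0 < self.delta_range[0] <= self.delta_range[1] <= 1:
            raise ValueError("delta_range must satisfy 0 < lo <= hi <= 1")
        if min(self.background_beta) <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.exclusive_blocks_per_population < self.marker_genes_per_population:
            raise ValueError("marker blocks cannot exceed exclusive blocks")

    @property
    def expected_cpg_count(self) -> float:
        return (
            self.n_chromosomes
            * self.islands_per_chromosome
            * (self.island_cpgs[0] + self.island_cpgs[1]) / 2.0
        )

    def expression_population_list(self) -> list[str]:
        if self.expression_populations is not None:
            return list(self.expression_populations)
        default = [p for p in self.populations if p in ("ILC1", "ILC2", "ILC3", "LTi")]
        return default or list(self.populations)


@dataclass
class PlantedBlock:
    chrom: str
    start: int
    end: int
    cpg_indices: np.ndarray  # indices into the global catalog
    populations: frozenset[str]  # hypomethylated in these populations
    delta: float
    gene_id: str | None
    kind: str  # marker / exclusive / shared / lineage


@dataclass
class PlantedTruth:
    blocks: list[PlantedBlock]
    marker_genes: dict[str, list[tuple[str, float]]]  # pop -> [(gene_id, delta)]
    expression_lfc: dict[str, dict[str, float]]  # pop -> gene_id -> planted log2FC
    motif_sites: list[tuple[str, int, str]] = field(default_factory=list)

    def pair_truth(self, a: str, b: str) -> list[PlantedBlock]:
        """Blocks whose planted methylation differs between populations a and b."""
        return [
            blk for blk in self.blocks if (a in blk.populations) != (b in blk.populations)
        ]


@dataclass
class GenomeSim:
    sequences: dict[str, np.ndarray]  # chrom -> base-character array
    islands: list[tuple[str, np.ndarray]]  # (chrom, CpG positions)
    island_roles: list[str]  # promoter:<gene_id> / body:<gene_id> / intergenic
    genes: list[GeneModel]
    catalog_chroms: np.ndarray
    catalog_positions: np.ndarray
    island_catalog_slices: list[slice]

    def sequence_str(self, chrom: str) -> str:
        return "".join(self.sequences[chrom])


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: GenomeSim
    matrix: MethylMatrix
    truth: PlantedTruth
    counts: pd.DataFrame
    sample_groups: dict[str, str]
    gene_lengths: pd.Series
    gene_sets: dict[str, set[str]]
    pwm_database: list[PWM]


def _make_gene(
    rng: np.random.Generator,
    chrom: str,
    index: int,
    slot_start: int,
    slot_end: int,
    cfg: SimulationConfig,
    noncanonical: bool,
) -> GeneModel:
    length = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
    margin = slot_end - slot_start - length
    start = slot_start + int(rng.integers(0, max(margin, 1)))
    end = start + length
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(2, 6))
    bounds = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
    edges = np.concatenate(([0], bounds, [length]))
    exons = tuple(
        (start + int(edges[2 * k]), start + int(edges[2 * k + 1]))
        for k in range(n_exons)
    )
    num = index + 1
    if noncanonical:
        name = f"Gm{9000 + num}" if num % 2 else f"{4930400 + num}A{num % 10:02d}Rik"
    else:
        name = f"Mk{num:04d}"
    return GeneModel(
        gene_id=f"SIMG{num:05d}",
        gene_name=name,
        chrom=chrom,
        strand=strand,
        tss=start if strand == "+" else end - 1,
        gene_start=start,
        gene_end=end,
        exons=exons,
        transcript_length=sum(e - s for s, e in exons),
    )


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenomeSim:
    """Random genome with CpG islands at gene promoters, gene bodies and intergenic space."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mean_island_span = (
        (config.island_cpgs[0] + config.island_cpgs[1]) / 2
        * (config.cpg_spacing[0] + config.cpg_spacing[1]) / 2
    )
    if config.islands_per_chromosome * mean_island_span > 0.3 * config.chromosome_length:
        raise ValueError("island density incompatible with chromosome length")

    genes: list[GeneModel] = []
    islands: list[tuple[str, np.ndarray]] = []
    roles: list[str] = []
    sequences: dict[str, np.ndarray] = {}
    gene_counter = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        L = config.chromosome_length
        seq = _BASES[rng.integers(0, 4, size=L)].copy()
        # break every accidental CpG so the island catalog is exhaustive
        cg = np.flatnonzero((seq[:-1] == "C") & (seq[1:] == "G"))
        seq[cg + 1] = "A"

        slot = L // config.genes_per_chromosome
        chrom_genes = []
        for g in range(config.genes_per_chromosome):
            noncanonical = rng.random() < config.noncanonical_gene_fraction
            gene = _make_gene(
                rng, chrom, gene_counter, g * slot + 1000, (g + 1) * slot - 1000,
                config, noncanonical,
            )
            chrom_genes.append(gene)
            gene_counter += 1
        genes.extend(chrom_genes)

        def sample_island(anchor: int, align: str = "start") -> np.ndarray:
            n = int(rng.integers(config.island_cpgs[0], config.island_cpgs[1] + 1))
            gaps = rng.integers(config.cpg_spacing[0], config.cpg_spacing[1] + 1, size=n - 1)
            pos = np.concatenate(([0], np.cumsum(gaps))).astype(np.int64)
            if align == "end":
                return anchor - pos[-1] + pos
            return anchor + pos

        # islands are anchored in transcript orientation so that promoter
        # and gene-body islands of one gene can never overlap
        chrom_islands: list[np.ndarray] = []
        chrom_roles: list[str] = []
        for gene in chrom_genes:
            if gene.strand == "+":
                promoter = sample_island(max(gene.tss - 200, 2), "start")
                body = sample_island(gene.tss + 2000, "start")
            else:
                promoter = sample_island(min(gene.tss + 200, L - 2), "end")
                body = sample_island(gene.tss - 2000, "end")
            chrom_islands.append(promoter)
            chrom_roles.append(f"promoter:{gene.gene_id}")
            chrom_islands.append(body)
            chrom_roles.append(f"body:{gene.gene_id}")

        n_far = config.far_islands_per_chromosome
        n_plain = config.islands_per_chromosome - 2 * config.genes_per_chromosome - n_far
        if n_plain < 0:
            raise ValueError("islands_per_chromosome too small for genes + far islands")
        tss_list = np.array([g.tss for g in chrom_genes])
        gene_spans = [(g.gene_start, g.gene_end) for g in chrom_genes]
        # the left pad covers the maximum island span so that an anchor
        # passing the check can never grow an island into a neighbour
        max_span = config.island_cpgs[1] * config.cpg_spacing[1]
        occupied = sorted(
            (int(p[0]) - 800 - max_span, int(p[-1]) + 800) for p in chrom_islands
        )

        def place(n_target: int, role: str, tss_clearance: int) -> None:
            placed, attempts = 0, 0
            while placed < n_target and attempts < 200 * n_target:
                attempts += 1
                anchor = int(rng.integers(2000, L - 3000))
                if np.min(np.abs(tss_list - anchor)) <= tss_clearance:
                    continue
                if any(s - 1500 <= anchor < e + 1500 for s, e in gene_spans):
                    continue
                if any(s <= anchor < e for s, e in occupied):
                    continue
                island = sample_island(anchor)
                chrom_islands.append(island)
                chrom_roles.append(role)
                occupied.append((anchor - 800 - max_span, int(island[-1]) + 800))
                placed += 1
            if placed < n_target:
                raise ValueError(
                    f"could only place {placed}/{n_target} {role} islands; "
                    "reduce island or gene density"
                )

        # far islands host planted blocks that must stay un-associable with
        # genes: > 5 kb from every TSS even at the island edge
        place(n_far, "intergenic_far", 6500)
        place(n_plain, "intergenic", 2000)

        for pos in chrom_islands:
            pos = pos[pos < L - 1]
            seq[pos] = "C"
            seq[pos + 1] = "G"
        order = np.argsort([p[0] for p in chrom_islands], kind="stable")
        islands.extend((chrom, chrom_islands[i]) for i in order)
        roles.extend(chrom_roles[i] for i in order)
        sequences[chrom] = seq

    cat_chroms, cat_positions, slices = [], [], []
    cursor = 0
    for (chrom, pos) in islands:
        cat_chroms.append(np.full(len(pos), chrom, dtype=object))
        cat_positions.append(pos)
        slices.append(slice(cursor, cursor + len(pos)))
        cursor += len(pos)
    return GenomeSim(
        sequences=sequences,
        islands=islands,
        island_roles=roles,
        genes=genes,
        catalog_chroms=np.concatenate(cat_chroms),
        catalog_positions=np.concatenate(cat_positions),
        island_catalog_slices=slices,
    )


def _choose_blocks(
    config: SimulationConfig, genome: GenomeSim, rng: np.random.Generator
) -> tuple[list[PlantedBlock], dict[str, list[tuple[str, float]]]]:
    lo_n, hi_n = config.block_cpgs
    promoter_idx = [
        i for i, r in enumerate(genome.island_roles)
        if r.startswith("promoter:") and genome.islands[i][1].size >= lo_n
    ]
    intergenic_idx = [
        i for i, r in enumerate(genome.island_roles)
        if r == "intergenic_far" and genome.islands[i][1].size >= lo_n
    ]
    gene_by_id = {g.gene_id: g for g in genome.genes}
    canonical_promoters = [
        i for i in promoter_idx
        if not gene_by_id[genome.island_roles[i].split(":")[1]].gene_name.startswith("Gm")
        and not gene_by_id[genome.island_roles[i].split(":")[1]].gene_name.endswith("Rik")
    ]
    rng.shuffle(canonical_promoters)
    rng.shuffle(intergenic_idx)
    prom_pool = iter(canonical_promoters)
    inter_pool = iter(intergenic_idx)

    def take_block(island_index: int, delta: float, pops: frozenset[str], kind: str,
                   gene_id: str | None) -> PlantedBlock:
        chrom, pos = genome.islands[island_index]
        sl = genome.island_catalog_slices[island_index]
        n = min(len(pos), int(rng.integers(lo_n, hi_n + 1)))
        idx = np.arange(sl.start, sl.start + n)
        return PlantedBlock(
            chrom=chrom,
            start=int(pos[0]),
            end=int(pos[n - 1]) + 1,
            cpg_indices=idx,
            populations=pops,
            delta=float(delta),
            gene_id=gene_id,
            kind=kind,
        )

    blocks: list[PlantedBlock] = []
    marker_genes: dict[str, list[tuple[str, float]]] = {p: [] for p in config.populations}
    try:
        for pop in config.populations:
            for _ in range(config.marker_genes_per_population):
                i = next(prom_pool)
                gene_id = genome.island_roles[i].split(":")[1]
                delta = rng.uniform(*config.marker_delta_range)
                blocks.append(take_block(i, delta, frozenset([pop]), "marker", gene_id))
                marker_genes[pop].append((gene_id, delta))
            extra = config.exclusive_blocks_per_population - config.marker_genes_per_population
            for _ in range(extra):
                i = next(inter_pool)
                delta = rng.uniform(*config.delta_range)
                blocks.append(take_block(i, delta, frozenset([pop]), "exclusive", None))
        for _ in range(config.shared_blocks):
            i = next(inter_pool)
            delta = rng.uniform(*config.delta_range)
            blocks.append(
                take_block(i, delta, frozenset(config.shared_pair), "shared", None)
            )
        if config.groups:
            group_names = sorted(config.groups)
            for gname in group_names:
                members = frozenset(config.groups[gname])
                for _ in range(config.lineage_blocks_per_direction):
                    i = next(prom_pool)
                    gene_id = genome.island_roles[i].split(":")[1]
                    delta = rng.uniform(*config.lineage_delta_range)
                    blocks.append(take_block(i, delta, members, "lineage", gene_id))
    except StopIteration:
        raise ValueError("planted blocks exceed available CpG islands") from None
    return blocks, marker_genes


def simulate_methylomes(
    config: SimulationConfig,
    genome: GenomeSim,
    rng: np.random.Generator | None = None,
) -> tuple[MethylMatrix, PlantedTruth]:
    """Observed methylomes (binomial sampling at Poisson coverage) + planted truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(genome.catalog_positions)
    blocks, marker_genes = _choose_blocks(config, genome, rng)
    for blk in blocks:
        if blk.cpg_indices.max() >= n:
            raise ValueError("planted block exceeds available CpGs")
    alpha, beta = config.background_beta
    base = rng.beta(alpha, beta, size=n)
    # a hypomethylation block of depth Delta presupposes a methylated
    # baseline: block CpGs draw their shared base level from a
    # high-methylation Beta so the planted difference is realisable
    block_cpgs = np.unique(np.concatenate([b.cpg_indices for b in blocks])) if blocks else []
    if len(block_cpgs):
        ab, bb = config.block_background_beta
        base[block_cpgs] = rng.beta(ab, bb, size=len(block_cpgs))
    pops = list(config.populations)
    levels = np.empty((len(pops), n))
    coverages = np.empty((len(pops), n), dtype=np.int64)
    for i, pop in enumerate(pops):
        true_level = np.clip(base + rng.normal(0.0, config.jitter_sd, size=n), 0.01, 0.99)
        for blk in blocks:
            if pop in blk.populations:
                true_level[blk.cpg_indices] = np.maximum(
                    true_level[blk.cpg_indices] - blk.delta, 0.0
                )
        cov = rng.poisson(config.coverage_mean, size=n)
        meth = rng.binomial(cov, true_level)
        with np.errstate(invalid="ignore"):
            obs = np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)
        levels[i] = obs
        coverages[i] = cov
    matrix = MethylMatrix(
        chroms=genome.catalog_chroms,
        positions=genome.catalog_positions,
        samples=pops,
        levels=levels,
        coverages=coverages,
    )
    truth = PlantedTruth(blocks=blocks, marker_genes=marker_genes, expression_lfc={})
    return matrix, truth


def simulate_expression(
    config: SimulationConfig,
    genome: GenomeSim,
    truth: PlantedTruth,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, str], pd.Series]:
    """Negative-binomial counts with planted marker-gene fold-changes.

    Marker genes of population P are up-regulated in P's replicates by
    log2FC = slope * Delta + Normal(0, sigma) (hypomethylation -> higher
    expression).  Returns (counts, sample->group map, gene lengths).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    pops = config.expression_population_list()
    gene_ids = [g.gene_id for g in genome.genes]
    base_mean = config.expression_mean * np.exp(
        rng.normal(0.0, config.expression_log_sd, size=len(gene_ids))
    )
    lfc_by_pop: dict[str, dict[str, float]] = {p: {} for p in pops}
    for pop in pops:
        for gene_id, delta in truth.marker_genes.get(pop, []):
            lfc_by_pop[pop][gene_id] = float(
                config.coupling_slope * delta + rng.normal(0.0, config.coupling_sigma)
            )
    truth.expression_lfc = lfc_by_pop
    r = 1.0 / config.expression_dispersion
    samples, groups = [], {}
    columns = {}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for pop in pops:
        mu = base_mean.copy()
        for gene_id, lfc in lfc_by_pop[pop].items():
            mu[gene_index[gene_id]] *= 2.0 ** lfc
        for rep in range(1, config.expression_replicates + 1):
            name = f"{pop}_rep{rep}"
            p_nb = r / (r + mu)
            columns[name] = rng.negative_binomial(r, p_nb)
            samples.append(name)
            groups[name] = pop
    counts = pd.DataFrame(columns, index=gene_ids)
    lengths = pd.Series(
        [max(g.transcript_length, 1) for g in genome.genes], index=gene_ids
    )
    return counts, groups, lengths


def plant_motifs(
    config: SimulationConfig,
    genome: GenomeSim,
    truth: PlantedTruth,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, int, str]]:
    """Write the consensus (or its reverse complement) into planted spans.

    Targets the exclusive/marker blocks of ``motif_population``; the
    occurrence offset is chosen between member CpGs so planted sites never
    destroy a catalogued CpG.  Returns (chrom, offset, strand) site records
    and stores them on the truth object.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    consensus = config.motif_consensus.upper()
    w = len(consensus)
    sites: list[tuple[str, int, str]] = []
    target_blocks = [
        b for b in truth.blocks if b.populations == frozenset([config.motif_population])
    ]
    for blk in target_blocks:
        if rng.random() >= config.motif_fraction:
            continue
        pos = genome.catalog_positions[blk.cpg_indices]
        gaps = [
            (int(pos[k]) + 2, int(pos[k + 1]) - 1)
            for k in range(len(pos) - 1)
            if int(pos[k + 1]) - 1 - (int(pos[k]) + 2) >= w
        ]
        if not gaps:
            continue  # consensus longer than any inter-CpG gap in this span
        lo, hi = gaps[int(rng.integers(0, len(gaps)))]
        offset = int(rng.integers(lo, hi - w + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        written = consensus if strand == "+" else reverse_complement(consensus)
        seq = genome.sequences[blk.chrom]
        seq[offset : offset + w] = list(written)
        # restore CpG exclusivity around the edit
        for p in (offset - 1, offset + w - 1):
            if 0 <= p < len(seq) - 1 and seq[p] == "C" and seq[p + 1] == "G":
                in_catalog = np.any(
                    (genome.catalog_chroms == blk.chrom) & (genome.catalog_positions == p)
                )
                if not in_catalog:
                    seq[p + 1] = "A"
        sites.append((blk.chrom, offset, strand))
    truth.motif_sites = sites
    return sites


def _toy_gene_sets(
    config: SimulationConfig, genome: GenomeSim, truth: PlantedTruth, rng: np.random.Generator
) -> dict[str, set[str]]:
    all_genes = [g.gene_id for g in genome.genes]
    marker_union = {
        gid for pop_genes in truth.marker_genes.values() for gid, _ in pop_genes
    }
    sets: dict[str, set[str]] = {"PLANTED_MARKER_GENES": marker_union}
    for pop, pop_genes in truth.marker_genes.items():
        if pop_genes:
            sets[f"PLANTED_MARKERS_{pop}"] = {gid for gid, _ in pop_genes}
    lineage = {b.gene_id for b in truth.blocks if b.kind == "lineage" and b.gene_id}
    if lineage:
        sets["PLANTED_LINEAGE_GENES"] = lineage
    for k in range(config.n_random_gene_sets):
        size = int(rng.integers(config.gene_set_size[0], config.gene_set_size[1] + 1))
        members = rng.choice(all_genes, size=min(size, len(all_genes)), replace=False)
        sets[f"RANDOM_SET_{k + 1:03d}"] = set(members.tolist())
    return sets


def _toy_pwm_database(config: SimulationConfig, rng: np.random.Generator) -> list[PWM]:
    pwms = []
    for k in range(50):
        w = int(rng.integers(7, 13))
        counts = rng.dirichlet(np.ones(4) * 0.6, size=w).T * 100
        matrix = counts / counts.sum(axis=0, keepdims=True)
        pwms.append(PWM(name=f"SYN{k + 1:03d}", matrix=matrix, counts=np.round(counts)))
    consensus = config.motif_consensus.upper()
    idx = ["ACGT".index(c) for c in consensus]
    counts = np.full((4, len(idx)), 4.0)
    counts[idx, np.arange(len(idx))] = 88.0
    pwms.append(
        PWM(
            name="PLANTED_TF_SYNTHETIC",
            matrix=counts / counts.sum(axis=0, keepdims=True),
            counts=counts,
        )
    )
    return pwms


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run every generator stage under one seed."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    matrix, truth = simulate_methylomes(config, genome, rng)
    counts, groups, lengths = simulate_expression(config, genome, truth, rng)
    plant_motifs(config, genome, truth, rng)
    gene_sets = _toy_gene_sets(config, genome, truth, rng)
    pwms = _toy_pwm_database(config, rng)
    return SimulatedStudy(
        config=config,
        genome=genome,
        matrix=matrix,
        truth=truth,
        counts=counts,
        sample_groups=groups,
        gene_lengths=lengths,
        gene_sets=gene_sets,
        pwm_database=pwms,
    )


def simulate_methylation_expression_pairs(
    n: int = 30,
    slope: float = 4.0,
    sigma: float = 0.35,
    delta_range: tuple[float, float] = (0.4, 0.8),
    seed: int = 0,
) -> pd.DataFrame:
    """Marker-level (methylation difference, log2FC) pairs with planted coupling.

    ``meth_diff`` is target-minus-other (negative: target hypomethylated),
    ``log2fc`` is target-vs-other expression change slope * Delta + noise;
    with the defaults the latent Pearson correlation is -0.8.
    """
    rng = np.random.default_rng(seed)
    delta = rng.uniform(delta_range[0], delta_range[1], size=n)
    lfc = slope * delta + rng.normal(0.0, sigma, size=n)
    return pd.DataFrame({"delta": delta, "meth_diff": -delta, "log2fc": lfc})


# ---------------------------------------------------------------------------
# on-disk emission

def write_fasta(genome: GenomeSim, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome.sequences):
            fh.write(f">{chrom}\n")
            seq = genome.sequence_str(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(genes: list[GeneModel], path: str | Path) -> None:
    """Ensembl-dialect GTF with gene/transcript/exon features (1-based closed)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.gene_start + 1}\t{g.gene_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            tx = f'{attrs} transcript_id "{g.gene_id}.1";'
            fh.write(
                f"{g.chrom}\tsim\ttranscript\t{g.gene_start + 1}\t{g.gene_end}\t.\t"
                f"{g.strand}\t.\t{tx}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tx}\n"
                )


def write_truth_beds(truth: PlantedTruth, populations: list[str], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, a in enumerate(populations):
        for b in populations[i + 1 :]:
            rows = truth.pair_truth(a, b)
            with open(outdir / f"truth_{a}_vs_{b}.bed", "w") as fh:
                for blk in sorted(rows, key=lambda x: (x.chrom, x.start)):
                    sign = "-" if a in blk.populations else "+"
                    delta = blk.delta if sign == "+" else -blk.delta
                    fh.write(
                        f"{blk.chrom}\t{blk.start}\t{blk.end}\t{blk.kind}\t"
                        f"{int(1000 * blk.delta)}\t.\t{len(blk.cpg_indices)}\t"
                        f"{delta:.3f}\n"
                    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, str]:
    """Write every simulated artifact as plain text; returns a file manifest."""
    from .methylome_io import write_methylation_table
    from .enrichment import write_gmt
    from .motifs import write_pwm_database

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    write_fasta(study.genome, outdir / "genome.fa")
    manifest["genome"] = "genome.fa"
    write_gtf(study.genome.genes, outdir / "genes.gtf")
    manifest["annotation"] = "genes.gtf"
    m = study.matrix
    for i, sample in enumerate(m.samples):
        ok = ~np.isnan(m.levels[i])
        df = pd.DataFrame(
            {
                "chrom": m.chroms[ok],
                "pos": m.positions[ok],
                "level": m.levels[i, ok],
                "meth_count": np.rint(m.levels[i, ok] * m.coverages[i, ok]).astype(int),
                "total_count": m.coverages[i, ok],
            }
        )
        write_methylation_table(df, outdir / f"meth_{sample}.tsv")
        manifest[f"methylome:{sample}"] = f"meth_{sample}.tsv"
    write_truth_beds(study.truth, list(study.config.populations), outdir / "truth")
    manifest["truth"] = "truth/"
    study.counts.rename_axis("gene_id").to_csv(outdir / "counts.tsv", sep="\t")
    manifest["counts"] = "counts.tsv"
    pd.DataFrame(
        {"sample": list(study.sample_groups), "group": list(study.sample_groups.values())}
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    manifest["samples"] = "samples.tsv"
    study.gene_lengths.rename("length").rename_axis("gene_id").to_csv(
        outdir / "gene_lengths.tsv", sep="\t"
    )
    manifest["gene_lengths"] = "gene_lengths.tsv"
    write_gmt(study.gene_sets, outdir / "genesets.gmt")
    manifest["gene_sets"] = "genesets.gmt"
    write_pwm_database(study.pwm_database, outdir / "pwm_db.txt")
    manifest["pwm_database"] = "pwm_db.txt"
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(study.config), fh, indent=1, sort_keys=True, default=list)
    manifest["config"] = "config.json"
    with open(outdir / "motif_sites.tsv", "w") as fh:
        fh.write("chrom\toffset\tstrand\n")
        for chrom, offset, strand in study.truth.motif_sites:
            fh.write(f"{chrom}\t{offset}\t{strand}\n")
    manifest["motif_sites"] = "motif_sites.tsv"
    return manifest
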