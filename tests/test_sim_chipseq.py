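"""Simulator: genome construction, fragment pools, PCR, sequencing."""

import collections

import numpy as np
import pytest

from lochip import (
    CapacityError,
    ConfigError,
    SimulationConfig,
    build_genome_model,
    expected_unique_fraction,
    parse_alignments,
    sequence_library,
    simulate_fragment_pool,
    simulate_library,
    write_reads,
)
from lochip.sim_chipseq import (
    NUCLEOSOME_HALF_WIDTH,
    NUCLEOSOME_OFFSETS,
    _k4_nucleosome_intervals,
)


class TestBuildGenomeModel:
    def test_no_repeat_case(self):
        genome, genes = build_genome_model(1, 10_000_000, 0.0, 100, seed=1)
        assert len(genes) == 100
        assert genome.repeat_length == 0
        assert genome.effective_genome_size == 10_000_000

    def test_repeat_coverage_near_target(self):
        genome, _ = build_genome_model(2, 5_000_000, 0.1, 200, seed=7)
        target = 0.1 * 10_000_000
        assert abs(genome.repeat_length - target) <= 0.02 * 10_000_000

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_exact_quartile_sizes(self, seed):
        _, genes = build_genome_model(1, 10_000_000, 0.0, 100, seed=seed)
        counts = collections.Counter(g.quartile for g in genes)
        assert counts == {"Q1": 25, "Q2": 25, "Q3": 25, "Q4": 25}

    def test_quartiles_consistent_with_expression_rank(self):
        _, genes = build_genome_model(1, 10_000_000, 0.0, 80, seed=5)
        ranked = sorted(genes, key=lambda g: g.expression)
        for i, g in enumerate(ranked):
            assert g.quartile == f"Q{i * 4 // 80 + 1}"

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            build_genome_model(1, 100_000, 0.0, 1000, seed=1)

    def test_tss_within_bounds(self, repeat_genome):
        genome, genes = repeat_genome
        for g in genes:
            assert 0 <= g.tss < genome.chrom_sizes[g.chrom]


class TestFragmentPool:
    def test_no_amplification_means_single_copies(self, small_genome):
        genome, genes = small_genome
        cfg = SimulationConfig(cells_per_ip=10_000, pcr_cycles=0, seed=1)
        pool = simulate_fragment_pool(cfg, genome, genes)
        assert (pool.copy_number == 1).all()

    def test_pool_size_is_cells_times_rate(self, small_genome):
        genome, genes = small_genome
        cfg = SimulationConfig(cells_per_ip=100_000, pool_per_cell=0.5, seed=1)
        pool = simulate_fragment_pool(cfg, genome, genes)
        assert pool.n_unique == 50_000

    def test_perfect_pcr_doubles_every_cycle(self, small_genome):
        genome, genes = small_genome
        cfg = SimulationConfig(
            cells_per_ip=5_000, pcr_cycles=3, pcr_efficiency_mean=1.0,
            pcr_efficiency_sd=0.0, seed=1,
        )
        pool = simulate_fragment_pool(cfg, genome, genes)
        assert (pool.copy_number == 8).all()

    def test_zero_pool_is_config_error(self, small_genome):
        genome, genes = small_genome
        cfg = SimulationConfig(cells_per_ip=1, pool_per_cell=0.1, seed=1)
        with pytest.raises(ConfigError):
            simulate_fragment_pool(cfg, genome, genes)

    def test_fragment_lengths_truncated(self, small_genome):
        genome, genes = small_genome
        cfg = SimulationConfig(cells_per_ip=20_000, seed=2)
        pool = simulate_fragment_pool(cfg, genome, genes)
        lengths = pool.end - pool.start
        assert lengths.min() >= 100 and lengths.max() <= 250

    def test_fragments_within_chromosome(self, small_genome):
        genome, genes = small_genome
        for mark in ("H3K4me3", "H3K27me3", "input"):
            cfg = SimulationConfig(cells_per_ip=20_000, mark=mark, seed=3)
            pool = simulate_fragment_pool(cfg, genome, genes)
            assert pool.start.min() >= 0
            assert pool.end.max() <= genome.chrom_sizes["chr1"]

    def test_mark_exclusivity(self, small_genome):
        """No enriched H3K27me3 fragment overlaps a top-quartile H3K4me3
        nucleosome footprint (exact interval check on the fragment list)."""
        genome, genes = small_genome
        cfg = SimulationConfig(cells_per_ip=100_000, mark="H3K27me3", seed=4)
        pool = simulate_fragment_pool(cfg, genome, genes)
        forbidden = _k4_nucleosome_intervals(genes, quartiles=("Q4",))
        sig = pool.is_signal
        for chrom, bounds in forbidden.items():
            ci = genome.chrom_names().index(chrom)
            sel = sig & (pool.chrom_idx == ci)
            s, e = pool.start[sel], pool.end[sel]
            i = np.searchsorted(bounds, s, side="right")
            j = np.searchsorted(bounds, e, side="left")
            assert ((i == j) & (i % 2 == 0)).all()


class TestExpectedUniqueFraction:
    def test_single_molecule(self):
        assert expected_unique_fraction(1, 5) == pytest.approx(0.2)

    def test_infinite_pool_limit(self):
        assert expected_unique_fraction(10**9, 10**3) == pytest.approx(1.0, abs=1e-6)

    def test_matches_monte_carlo(self):
        """Closed form agrees with direct simulation of the sampling process."""
        U = m = 1000
        rng = np.random.default_rng(12345)
        n_rep = 10_000
        distinct = np.empty(n_rep)
        for i in range(n_rep):
            distinct[i] = np.unique(rng.integers(0, U, size=m)).size
        mc = distinct.mean() / m
        se = distinct.std(ddof=1) / np.sqrt(n_rep) / m
        assert abs(expected_unique_fraction(U, m) - mc) < 3 * se


class TestSequenceLibrary:
    def test_all_artifacts_are_unmapped(self, small_genome):
        genome, genes = small_genome
        cfg = SimulationConfig(
            cells_per_ip=10_000, n_reads=500, artifact_fraction=1.0, seed=5
        )
        pool = simulate_fragment_pool(cfg, genome, genes)
        reads = sequence_library(pool, cfg, genome)
        assert all(r.mapping_class == "unmapped" for r in reads)
        assert all(r.molecule_id is None for r in reads)

    def test_clean_library_is_all_unique(self, small_genome):
        genome, genes = small_genome
        cfg = SimulationConfig(
            cells_per_ip=10_000, n_reads=2_000, artifact_fraction=0.0,
            error_unmapped_fraction=0.0, seed=5,
        )
        pool, reads = simulate_library(cfg, genome, genes)
        assert all(r.mapping_class == "unique" for r in reads)

    def test_repeat_fragments_become_multi(self, repeat_genome):
        genome, genes = repeat_genome
        cfg = SimulationConfig(
            cells_per_ip=20_000, n_reads=20_000, artifact_fraction=0.0,
            error_unmapped_fraction=0.0, mark="input", seed=6,
        )
        _, reads = simulate_library(cfg, genome, genes)
        classes = collections.Counter(r.mapping_class for r in reads)
        # ~10% of the genome is repeat territory
        assert 0.05 < classes["multi"] / len(reads) < 0.15

    def test_mean_distinct_molecules_matches_occupancy_formula(self, small_genome):
        genome, genes = small_genome
        U, m = 2_000, 4_000
        fracs = []
        for seed in range(20):
            cfg = SimulationConfig(
                cells_per_ip=U, pool_per_cell=1.0, pcr_cycles=8,
                pcr_efficiency_mean=1.0, pcr_efficiency_sd=0.0, n_reads=m,
                artifact_fraction=0.0, error_unmapped_fraction=0.0,
                mark="input", seed=seed,
            )
            _, reads = simulate_library(cfg, genome, genes)
            fracs.append(len({r.molecule_id for r in reads}) / m)
        fracs = np.asarray(fracs)
        expected = expected_unique_fraction(U, m)
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - expected) < 3 * se

    def test_amplification_bias_worsens_duplication(self, small_genome):
        """With per-molecule efficiency spread, the duplicate fraction is at
        least the unbiased closed-form prediction."""
        genome, genes = small_genome
        U, m = 5_000, 20_000
        means = []
        for seed in range(10):
            cfg = SimulationConfig(
                cells_per_ip=U, pool_per_cell=1.0, pcr_cycles=12,
                pcr_efficiency_mean=0.7, pcr_efficiency_sd=0.15, n_reads=m,
                artifact_fraction=0.0, error_unmapped_fraction=0.0,
                mark="input", seed=seed,
            )
            _, reads = simulate_library(cfg, genome, genes)
            means.append(1 - len({r.molecule_id for r in reads}) / m)
        unbiased = 1 - expected_unique_fraction(U, m)
        assert np.mean(means) >= unbiased

    def test_strand_balance_and_bounds(self, small_genome):
        genome, genes = small_genome
        cfg = SimulationConfig(
            cells_per_ip=50_000, n_reads=20_000, artifact_fraction=0.0,
            error_unmapped_fraction=0.0, mark="input", seed=8,
        )
        _, reads = simulate_library(cfg, genome, genes)
        plus = sum(1 for r in reads if r.strand == "+")
        n = len(reads)
        assert abs(plus - n / 2) < 4 * np.sqrt(n * 0.25)
        assert all(0 <= r.start < genome.chrom_sizes[r.chrom] for r in reads)


class TestSamRoundTrip:
    def test_empty_read_list(self, small_genome, tmp_path):
        genome, _ = small_genome
        path = tmp_path / "empty.sam"
        write_reads([], genome, str(path))
        assert parse_alignments(str(path)) == []

    def test_three_read_classes(self, small_genome, tmp_path):
        from lochip import ReadRecord

        genome, _ = small_genome
        reads = [
            ReadRecord("r1", "unmapped", None, None, None, None),
            ReadRecord("r2", "multi", "chr1", 5_000, "+", 3),
            ReadRecord("r3", "unique", "chr1", 9_000, "-", 4),
        ]
        path = tmp_path / "three.sam"
        write_reads(reads, genome, str(path))
        back = parse_alignments(str(path))
        assert [r.mapping_class for r in back] == [r.mapping_class for r in reads]
        mapped = [r for r in back if r.mapping_class != "unmapped"]
        orig = [r for r in reads if r.mapping_class != "unmapped"]
        assert [(r.chrom, r.start, r.strand) for r in mapped] == [
            (r.chrom, r.start, r.strand) for r in orig
        ]

    def test_simulated_library_round_trips_exactly(self, repeat_genome, tmp_path):
        genome, genes = repeat_genome
        cfg = SimulationConfig(
            cells_per_ip=20_000, n_reads=10_000, artifact_fraction=0.05,
            error_unmapped_fraction=0.02, seed=9,
        )
        _, reads = simulate_library(cfg, genome, genes)
        path = tmp_path / "sim.sam"
        write_reads(reads, genome, str(path))
        back = parse_alignments(str(path))
        assert len(back) == len(reads)
        by_id = {r.read_id: r for r in back}
        for r in reads:
            b = by_id[r.read_id]
            assert b.mapping_class == r.mapping_class
            assert b.chrom == r.chrom
            assert b.start == r.start
            assert b.strand == r.strand
            assert b.molecule_id == r.molecule_id
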