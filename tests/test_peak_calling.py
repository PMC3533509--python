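"""Pileup construction and Poisson-background peak calling."""

import numpy as np
import pytest
from scipy.stats import poisson

from lochip import (
    ConfigError,
    PeakCallConfig,
    ReadRecord,
    SimulationConfig,
    account,
    call_peaks,
    call_peaks_with_control,
    shift_and_pileup,
    simulate_library,
)


def R(rid, start, strand="+", chrom="chr1"):
    return ReadRecord(rid, "unique", chrom, start, strand)


def cfg(egs=10_000_000, **kw):
    kw.setdefault("shift", 75)
    kw.setdefault("window", 150)
    return PeakCallConfig(effective_genome_size=egs, **kw)


class TestShiftAndPileup:
    def test_plus_strand_window(self):
        cov = shift_and_pileup([R("a", 1000)], cfg())["chr1"]
        assert cov[999] == 0
        assert (cov[1000:1150] == 1).all()
        assert cov[1150] == 0 if cov.size > 1150 else True

    def test_minus_strand_symmetry(self):
        # a minus-strand 5' end at 1150 shifts back to the same fragment
        # midpoint as a plus-strand 5' end at 1000
        cov_plus = shift_and_pileup([R("a", 1000, "+")], cfg())["chr1"]
        cov_minus = shift_and_pileup([R("a", 1150, "-")], cfg())["chr1"]
        n = min(cov_plus.size, cov_minus.size)
        assert (cov_plus[:n] == cov_minus[:n]).all()
        assert (cov_minus[1000:1150] == 1).all()

    def test_zero_reads(self):
        assert shift_and_pileup([], cfg()) == {}

    def test_out_of_bounds_read_rejected(self):
        c = cfg(chrom_sizes={"chr1": 500})
        with pytest.raises(Exception):
            shift_and_pileup([R("a", 1000)], c)

    def test_total_mass_bounded(self):
        reads = [R(f"r{i}", 100 + 7 * i) for i in range(20)]
        cov = shift_and_pileup(reads, cfg())["chr1"]
        assert cov.sum() <= len(reads) * 150


class TestCallPeaks:
    def test_null_background_no_peaks(self):
        # sparse uniform reads: max pileup stays below the significance count
        rng = np.random.default_rng(0)
        reads = [
            R(f"r{i}", int(p)) for i, p in enumerate(
                np.sort(rng.integers(0, 1_000_000, size=500))
            )
        ]
        c = cfg(egs=1_000_000)
        lam = len(reads) * 150 / 1_000_000
        peaks = call_peaks(reads, c)
        # verify the premise: a pileup this sparse has no significant column
        assert poisson.sf(max(shift_and_pileup(reads, c)["chr1"]) - 1, lam) > 1e-5
        assert peaks == []

    def test_stacked_reads_form_single_peak(self):
        reads = [R(f"r{i:02d}", 5000) for i in range(50)]
        # lambda = 50*150/egs = 0.1
        c = cfg(egs=75_000)
        peaks = call_peaks(reads, c)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.read_count == 50
        assert p.start <= 5075 < p.end  # shifted midpoint inside
        # P(X >= 50; 0.1) is astronomically small => huge score
        assert p.score > 50

    def test_merge_gap_boundary(self):
        # two stacks whose pileup footprints are separated by exactly the
        # merge gap fuse into one peak; at twice the gap they stay separate
        def stacks(gap):
            a = [R(f"a{i:02d}", 1000) for i in range(50)]
            b = [R(f"b{i:02d}", 1000 + 150 + gap) for i in range(50)]
            return a + b

        c = cfg(egs=150_000, merge_gap=100)
        assert len(call_peaks(stacks(100), c)) == 1
        assert len(call_peaks(stacks(200), c)) == 2

    def test_relaxing_threshold_never_loses_peaks(self):
        rng = np.random.default_rng(1)
        reads = [R(f"r{i}", int(p)) for i, p in enumerate(
            np.sort(rng.integers(0, 200_000, size=2000)))]
        reads += [R(f"s{i}", 50_000 + (i % 20)) for i in range(40)]
        counts = [
            len(call_peaks(reads, cfg(egs=200_000, pvalue_threshold=t)))
            for t in (1e-9, 1e-7, 1e-5, 1e-3)
        ]
        assert counts == sorted(counts)

    def test_summit_is_leftmost_maximum(self):
        reads = [R(f"r{i:02d}", 1000) for i in range(50)]
        c = cfg(egs=75_000)
        [p] = call_peaks(reads, c)
        assert p.summit == p.start  # uniform plateau: leftmost position

    def test_requires_reads_and_valid_genome_size(self):
        with pytest.raises(ConfigError):
            call_peaks([], cfg())
        with pytest.raises(ConfigError):
            PeakCallConfig(shift=75, effective_genome_size=0)


class TestControlMode:
    def _background(self, rng, n, span, prefix):
        return [
            R(f"{prefix}{i:05d}", int(p))
            for i, p in enumerate(np.sort(rng.integers(0, span, size=n)))
        ]

    def test_uniform_control_changes_nothing(self):
        rng = np.random.default_rng(2)
        treat = self._background(rng, 2000, 1_000_000, "t")
        treat += [R(f"p{i:02d}", 300_000) for i in range(60)]
        ctrl = self._background(rng, 2000, 1_000_000, "c")
        c = cfg(egs=1_000_000)
        base = call_peaks(treat, c)
        with_ctrl, lost = call_peaks_with_control(treat, ctrl, c)
        assert [(p.start, p.end) for p in with_ctrl] == [
            (p.start, p.end) for p in base
        ]
        assert lost == []

    def test_control_enriched_artifact_region_dropped(self):
        rng = np.random.default_rng(3)
        treat = self._background(rng, 2000, 1_000_000, "t")
        # an artifact region: elevated in treatment, 10x more so in control
        treat += [
            R(f"a{i:04d}", int(p))
            for i, p in enumerate(rng.integers(500_000, 510_000, size=600))
        ]
        ctrl = self._background(rng, 2000, 1_000_000, "c") + [
            R(f"b{i:04d}", int(p))
            for i, p in enumerate(rng.integers(500_000, 510_000, size=6000))
        ]
        c = cfg(egs=1_000_000)
        base = call_peaks(treat, c)
        assert any(500_000 <= p.summit < 510_000 for p in base)
        with_ctrl, lost = call_peaks_with_control(treat, ctrl, c)
        assert not any(500_000 <= p.summit < 510_000 for p in with_ctrl)
        assert any(500_000 <= p.summit < 510_000 for p in lost)

    def test_empty_control_falls_back(self):
        treat = [R(f"p{i:02d}", 1000) for i in range(50)]
        c = cfg(egs=75_000)
        peaks, lost = call_peaks_with_control(treat, [], c)
        assert [(p.start, p.end) for p in peaks] == [
            (p.start, p.end) for p in call_peaks(treat, c)
        ]
        assert lost == []

    def test_matched_input_loses_few_peaks(self, small_genome):
        """With a matched input library as control, only a small fraction of
        peaks disappear (the workflow's negligible-difference observation)."""
        genome, genes = small_genome
        sim = dict(
            cells_per_ip=1_000_000, n_reads=200_000, artifact_fraction=0.0,
            error_unmapped_fraction=0.0,
        )
        _, treat_reads = simulate_library(
            SimulationConfig(mark="H3K4me3", seed=31, **sim), genome, genes
        )
        _, input_reads = simulate_library(
            SimulationConfig(mark="input", seed=32, **sim), genome, genes
        )
        _, treat = account(treat_reads)
        _, ctrl = account(input_reads)
        c = cfg(egs=genome.effective_genome_size,
                chrom_sizes=dict(genome.chrom_sizes))
        base = call_peaks(treat, c)
        _, lost = call_peaks_with_control(treat, ctrl, c)
        assert len(lost) / len(base) < 0.05


class TestDuplicateRetentionEffect:
    def test_duplicates_inflate_peak_counts_off_target(self, small_genome):
        """Keeping duplicates on a low-complexity library adds peaks, and the
        excess falls outside the planted promoter regions."""
        genome, genes = small_genome
        sim = SimulationConfig(
            cells_per_ip=20_000, n_reads=150_000, artifact_fraction=0.0,
            error_unmapped_fraction=0.0, seed=33,
        )
        _, reads = simulate_library(sim, genome, genes)
        _, usable = account(reads)
        mapped = [r for r in reads if r.mapping_class == "unique"]
        c = cfg(egs=genome.effective_genome_size,
                chrom_sizes=dict(genome.chrom_sizes))
        dedup_peaks = call_peaks(usable, c)
        dup_peaks = call_peaks(mapped, c)
        assert len(dup_peaks) >= len(dedup_peaks)

        planted = []
        for g in genes:
            sgn = 1 if g.strand == "+" else -1
            lo, hi = sorted((g.tss - sgn * 850, g.tss + sgn * 950))
            planted.append((lo, hi))

        def off_target(peaks):
            return sum(
                1 for p in peaks
                if not any(lo < p.end and p.start < hi for lo, hi in planted)
            )

        assert off_target(dup_peaks) >= off_target(dedup_peaks)
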