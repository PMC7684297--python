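"""Synthetic genome and read generation: determinism, conservation, SAM I/O."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxogprofiler import (
    FilterPolicy,
    SimulationConfig,
    bin_counts,
    build_intensity_map,
    filter_stream,
    make_genome,
    read_alignments,
    simulate_counts,
    simulate_reads,
    write_sam,
)
from oxogprofiler.profiling import BinGrid


class TestMakeGenome:
    def test_bin_layout(self):
        g = make_genome(2, 30_000, include_mito=False)
        assert g.analyzable_chromosomes == ("chr1", "chr2")
        assert all(g.n_bins(c, 10_000) == 3 for c in g.analyzable_chromosomes)

    def test_mito_appended_and_excluded(self):
        g = make_genome(23, 500_000, include_mito=True)
        assert len(g.analyzable_chromosomes) == 23
        assert g.mito_name == "chrM"
        assert g.names[-1] == "chrM"

    @pytest.mark.parametrize("n_chroms,length", [(0, 30_000), (-1, 30_000), (2, 0)])
    def test_bad_sizes_rejected(self, n_chroms, length):
        with pytest.raises(ValueError):
            make_genome(n_chroms, length)

    def test_duplicate_names_rejected(self):
        from oxogprofiler import GenomeModel

        with pytest.raises(ValueError):
            GenomeModel((("chr1", 100), ("chr1", 200)))


class TestIntensityMap:
    def test_zero_mass_gives_uniform_map(self, small_genome):
        cfg = SimulationConfig(hotspot_fraction=0.05, hotspot_mass=0.0)
        imap = build_intensity_map(small_genome, cfg, "wt", seed=1)
        assert np.allclose(imap.weights, 1.0 / imap.n_bins)
        assert not imap.hotspot.any()

    def test_hotspot_bins_carry_their_mass(self, small_genome):
        cfg = SimulationConfig(hotspot_fraction=0.05, hotspot_mass=0.5,
                               background_model="diffuse")
        imap = build_intensity_map(small_genome, cfg, "mut", seed=1)
        assert imap.weights[imap.hotspot].sum() == pytest.approx(0.5)
        assert imap.weights.sum() == pytest.approx(1.0)

    def test_deterministic_given_seed(self, small_genome, quiet_config):
        a = build_intensity_map(small_genome, quiet_config, "wt", seed=7)
        b = build_intensity_map(small_genome, quiet_config, "wt", seed=7)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.hotspot, b.hotspot)

    def test_hotspots_shared_between_conditions(self, small_genome):
        cfg = SimulationConfig(hotspot_fraction=0.1,
                               hotspot_mass={"wt": 0.1, "mut": 0.5})
        wt = build_intensity_map(small_genome, cfg, "wt", seed=3)
        mut = build_intensity_map(small_genome, cfg, "mut", seed=3)
        assert np.array_equal(wt.hotspot, mut.hotspot)

    def test_mass_without_hotspots_rejected(self, small_genome):
        cfg = SimulationConfig(hotspot_fraction=0.0, hotspot_mass=0.5)
        with pytest.raises(ValueError):
            build_intensity_map(small_genome, cfg, "wt", seed=1)


class TestSimulateCounts:
    @given(seed=st.integers(0, 2**31 - 1), n_reads=st.integers(1, 5000))
    @settings(max_examples=25, deadline=None)
    def test_counts_sum_to_n_reads(self, seed, n_reads):
        genome = make_genome(3, 100_000)
        cfg = SimulationConfig(hotspot_fraction=0.1, hotspot_mass=0.3)
        imap = build_intensity_map(genome, cfg, "mut", seed=0)
        counts = simulate_counts(imap, n_reads, seed=seed)
        assert counts.total() == n_reads
        assert counts.library_size == n_reads

    def test_single_bin_gets_everything(self):
        genome = make_genome(1, 10_000)
        cfg = SimulationConfig(hotspot_fraction=0.0, hotspot_mass=0.0)
        imap = build_intensity_map(genome, cfg, "wt", seed=0)
        counts = simulate_counts(imap, 777, seed=5)
        assert counts.counts["chr1"].tolist() == [777]

    def test_zero_reads_rejected(self, small_genome, quiet_config):
        imap = build_intensity_map(small_genome, quiet_config, "wt", seed=0)
        with pytest.raises(ValueError):
            simulate_counts(imap, 0, seed=1)

    def test_empirical_mean_matches_multinomial_expectation(self):
        """1000 draws of n=10000 on weights (0.25, 0.75): bin-1 mean within 3 SE of 2500."""
        genome = make_genome(1, 20_000)
        imap = build_intensity_map(
            genome, SimulationConfig(hotspot_fraction=0.0, hotspot_mass=0.0), "wt", seed=0
        )
        imap = type(imap)(genome=genome, bin_size=imap.bin_size, offsets=imap.offsets,
                          weights=np.array([0.25, 0.75]), hotspot=imap.hotspot)
        n, p, reps = 10_000, 0.25, 1000
        draws = np.array([
            simulate_counts(imap, n, seed=s).counts["chr1"][0] for s in range(reps)
        ])
        se_of_mean = np.sqrt(n * p * (1 - p) / reps)
        assert abs(draws.mean() - n * p) < 3 * se_of_mean


class TestSimulateReads:
    def test_deterministic_given_seed(self, small_genome, quiet_config):
        imap = build_intensity_map(small_genome, quiet_config, "wt", seed=4)
        r1 = simulate_reads(imap, small_genome, quiet_config, seed=11)
        r2 = simulate_reads(imap, small_genome, quiet_config, seed=11)
        assert r1 == r2

    def test_read_level_binning_matches_count_level(self, small_genome, quiet_config):
        """With zero noise, filter+bin over emitted reads equals the multinomial draw."""
        imap = build_intensity_map(small_genome, quiet_config, "wt", seed=4)
        reads = simulate_reads(imap, small_genome, quiet_config, seed=11)
        kept, library = filter_stream(reads, FilterPolicy.for_genome(small_genome))
        assert library == quiet_config.n_reads_per_sample
        binned = bin_counts(kept, small_genome, BinGrid(10_000), library_size=library)
        expected = simulate_counts(imap, quiet_config.n_reads_per_sample, seed=11)
        for chrom in expected.counts:
            assert np.array_equal(binned.counts[chrom], expected.counts[chrom])

    def test_mito_reads_generated_then_filtered_out(self, small_genome):
        cfg = SimulationConfig(n_reads_per_sample=10_000, mito_fraction=0.1,
                               mapq_low_fraction=0.0, duplicate_fraction=0.0)
        imap = build_intensity_map(small_genome, cfg, "wt", seed=4)
        reads = simulate_reads(imap, small_genome, cfg, seed=9)
        n_mito = sum(r.chromosome == "chrM" for r in reads)
        assert n_mito > 0
        kept, library = filter_stream(reads, FilterPolicy.for_genome(small_genome))
        assert library == len(reads) - n_mito
        assert all(r.chromosome != "chrM" for r in kept)

    def test_mito_fraction_without_mito_contig_rejected(self):
        genome = make_genome(2, 100_000, include_mito=False)
        cfg = SimulationConfig(mito_fraction=0.1)
        imap = build_intensity_map(genome, cfg, "wt", seed=0)
        with pytest.raises(ValueError):
            simulate_reads(imap, genome, cfg, seed=1)

    def test_reads_fit_their_chromosome(self, small_genome, rng):
        cfg = SimulationConfig(n_reads_per_sample=2_000, mito_fraction=0.05)
        imap = build_intensity_map(small_genome, cfg, "mut", seed=4)
        for read in simulate_reads(imap, small_genome, cfg, seed=13):
            assert 0 <= read.position
            assert read.position + cfg.read_length <= small_genome.length_of(read.chromosome)


class TestWriteSam:
    @staticmethod
    def _key(read):
        return (read.chromosome, read.position, read.mapq, read.strand,
                read.is_duplicate, read.is_secondary, read.is_supplementary)

    def test_round_trip_preserves_read_multiset(self, small_genome, tmp_path):
        cfg = SimulationConfig(n_reads_per_sample=3_000, mito_fraction=0.02,
                               mapq_low_fraction=0.1, duplicate_fraction=0.05)
        imap = build_intensity_map(small_genome, cfg, "mut", seed=2)
        reads = simulate_reads(imap, small_genome, cfg, seed=8)
        path = tmp_path / "sim.sam"
        write_sam(reads, small_genome, path, read_length=cfg.read_length)
        back = list(read_alignments(path, "sam"))
        assert Counter(map(self._key, reads)) == Counter(map(self._key, back))

    def test_pos_written_one_based(self, small_genome, tmp_path):
        from oxogprofiler import ReadRecord

        path = tmp_path / "one.sam"
        write_sam([ReadRecord("chr1", 0, mapq=60)], small_genome, path, read_length=50)
        body = [l for l in path.read_text().splitlines() if not l.startswith("@")]
        assert body[0].split("\t")[3] == "1"

    def test_empty_stream_gives_header_only_sam(self, small_genome, tmp_path):
        path = tmp_path / "empty.sam"
        write_sam([], small_genome, path)
        lines = path.read_text().splitlines()
        assert lines and all(l.startswith("@") for l in lines)
        # one @SQ per contig, mitochondrial included
        assert sum(l.startswith("@SQ") for l in lines) == len(small_genome.names)

    def test_read_past_chromosome_end_rejected(self, small_genome, tmp_path):
        from oxogprofiler import ReadRecord

        read = ReadRecord("chrM", small_genome.length_of("chrM") - 10, mapq=60)
        with pytest.raises(ValueError):
            write_sam([read], small_genome, tmp_path / "bad.sam", read_length=50)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_reads_per_sample=123, hotspot_mass={"wt": 0.2, "mut": 0.6})
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg

    @pytest.mark.parametrize("kwargs", [
        {"n_reads_per_sample": 0},
        {"hotspot_fraction": 1.5},
        {"mito_fraction": -0.1},
        {"background_model": "banana"},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
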