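"""Synthetic two-condition ChIP-style datasets for the damage-profiling pipeline.

The generator emulates the statistical structure the analysis consumes:
per-bin read intensities with damage hotspots shared between conditions,
a diffuse-versus-concentrated background difference between conditions,
a two-point mapping-quality mixture straddling the MAPQ 20 threshold,
mitochondrial-read contamination, and duplicate flags.

Two layers exist deliberately:

* a **count level** (`simulate_counts`) that draws one multinomial over bins —
  fast enough for Monte-Carlo calibration at hundreds to thousands of
  replicate pipelines; and
* a **read level** (`simulate_reads` / `write_sam`) that expands the same
  multinomial draw into individual aligned reads with positions, MAPQ, flags
  and strand, for end-to-end I/O and filter testing.  For a given seed the
  read level's bin draw is identical to the count level's, so with all noise
  fractions zero, filtering and binning the emitted reads reproduces
  `simulate_counts` exactly.

Everything is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam
import yaml

from .genome import GenomeModel
from .ingest import ReadRecord
from .profiling import BinGrid, BinnedCounts, counts_from_arrays

__all__ = [
    "SimulationConfig",
    "IntensityMap",
    "build_intensity_map",
    "simulate_counts",
    "simulate_reads",
    "write_sam",
    "simulate_dataset",
]

# rng stream labels: hotspot/background layout must not depend on the
# condition or on how many reads are drawn afterwards
_LAYOUT_STREAM = 0
_DRAW_STREAM = 1


def _per_condition(value, condition: str, name: str) -> object:
    """Resolve a scalar-or-mapping config field for one condition."""
    if isinstance(value, Mapping):
        try:
            return value[condition]
        except KeyError:
            raise KeyError(f"{name} has no entry for condition {condition!r}") from None
    return value


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    ``hotspot_mass`` and ``background_model`` may be scalars (same for every
    condition) or mappings keyed by condition label.  ``hotspot_mass`` is the
    fraction of a sample's reads drawn from hotspot bins; the remaining mass
    spreads over background bins either uniformly (``"diffuse"``) or over a
    random ``concentrated_fraction`` subset of them (``"concentrated"``).
    """

    n_reads_per_sample: int = 200_000
    read_length: int = 50
    hotspot_fraction: float = 0.05
    hotspot_mass: float | Mapping[str, float] = field(
        default_factory=lambda: {"wt": 0.1, "mut": 0.5}
    )
    background_model: str | Mapping[str, str] = field(
        default_factory=lambda: {"wt": "diffuse", "mut": "concentrated"}
    )
    concentrated_fraction: float = 0.1
    mapq_low_fraction: float = 0.05
    mito_fraction: float = 0.01
    duplicate_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads_per_sample <= 0:
            raise ValueError("n_reads_per_sample must be positive")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        scalars = {
            "hotspot_fraction": self.hotspot_fraction,
            "concentrated_fraction": self.concentrated_fraction,
            "mapq_low_fraction": self.mapq_low_fraction,
            "mito_fraction": self.mito_fraction,
            "duplicate_fraction": self.duplicate_fraction,
        }
        masses = (self.hotspot_mass.values()
                  if isinstance(self.hotspot_mass, Mapping) else [self.hotspot_mass])
        for j, mass in enumerate(masses):
            scalars[f"hotspot_mass[{j}]"] = mass
        for name, value in scalars.items():
            if not 0.0 <= float(value) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        models = (self.background_model.values()
                  if isinstance(self.background_model, Mapping) else [self.background_model])
        for model in models:
            if model not in ("diffuse", "concentrated"):
                raise ValueError(
                    f"background_model must be 'diffuse' or 'concentrated', got {model!r}"
                )

    def mass_for(self, condition: str) -> float:
        return float(_per_condition(self.hotspot_mass, condition, "hotspot_mass"))

    def background_for(self, condition: str) -> str:
        return str(_per_condition(self.background_model, condition, "background_model"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            name: getattr(self, name) for name in self.__dataclass_fields__
        }
        payload = {k: dict(v) if isinstance(v, Mapping) else v for k, v in payload.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass(frozen=True)
class IntensityMap:
    """Expected per-bin read weights over the analyzable genome, flat layout.

    ``weights`` sums to 1; ``offsets[chrom]`` is ``(start, n_bins)`` into the
    flat arrays; ``hotspot`` flags the hotspot bins.
    """

    genome: GenomeModel
    bin_size: int
    offsets: dict[str, tuple[int, int]]
    weights: np.ndarray
    hotspot: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.weights.size

    def per_chromosome(self, flat: np.ndarray) -> dict[str, np.ndarray]:
        """Split a flat per-bin vector back into per-chromosome arrays."""
        return {c: flat[s:s + n] for c, (s, n) in self.offsets.items()}


def _flat_layout(genome: GenomeModel, bin_size: int) -> tuple[dict[str, tuple[int, int]], int]:
    offsets: dict[str, tuple[int, int]] = {}
    start = 0
    for chrom in genome.analyzable_chromosomes:
        n = genome.n_bins(chrom, bin_size)
        offsets[chrom] = (start, n)
        start += n
    return offsets, start


def build_intensity_map(
    genome: GenomeModel,
    config: SimulationConfig,
    condition: str,
    seed: int,
    bin_size: int = 10_000,
) -> IntensityMap:
    """Expected read distribution over bins for one condition.

    Hotspot bins (and the concentrated-background subset) are drawn from the
    seed alone, so two conditions built with the same seed share them; the
    conditions differ only in how much mass the hotspots carry and in how the
    background spreads.  With ``hotspot_mass == 0`` the map is uniform over
    all bins.
    """
    offsets, total_bins = _flat_layout(genome, bin_size)
    if total_bins == 0:
        raise ValueError("genome has no analyzable bins")
    mass = config.mass_for(condition)
    if config.hotspot_fraction == 0.0 and mass > 0.0:
        raise ValueError("hotspot_mass > 0 requires hotspot_fraction > 0")

    layout_rng = np.random.default_rng(
        np.random.SeedSequence(seed).spawn(2)[_LAYOUT_STREAM]
    )
    n_hot = int(round(config.hotspot_fraction * total_bins))
    hot_idx = layout_rng.choice(total_bins, size=n_hot, replace=False)
    hotspot = np.zeros(total_bins, dtype=bool)
    hotspot[hot_idx] = True
    bg_idx = np.flatnonzero(~hotspot)
    # condition-independent draw so both conditions could share the subset
    n_conc = max(1, int(round(config.concentrated_fraction * bg_idx.size))) if bg_idx.size else 0
    conc_subset = layout_rng.choice(bg_idx, size=n_conc, replace=False) if n_conc else bg_idx

    weights = np.zeros(total_bins)
    if mass == 0.0:
        weights[:] = 1.0 / total_bins
        hotspot[:] = False  # zero-mass hotspots are not hotspots
    else:
        weights[hotspot] = mass / n_hot
        if bg_idx.size:
            if config.background_for(condition) == "diffuse":
                weights[bg_idx] = (1.0 - mass) / bg_idx.size
            else:
                weights[conc_subset] = (1.0 - mass) / conc_subset.size
        elif mass < 1.0:
            raise ValueError("no background bins available for background mass")
    weights = weights / weights.sum()
    return IntensityMap(genome=genome, bin_size=bin_size, offsets=offsets,
                        weights=weights, hotspot=hotspot)


def simulate_counts(imap: IntensityMap, n_reads: int, seed: int) -> BinnedCounts:
    """One multinomial draw of ``n_reads`` over the map's bins.

    The library size is recorded as ``n_reads`` (the count-level path has no
    contaminating reads to filter out).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    flat = rng.multinomial(n_reads, imap.weights)
    return counts_from_arrays(imap.per_chromosome(flat), library_size=n_reads,
                              grid=BinGrid(imap.bin_size))


def simulate_reads(
    imap: IntensityMap,
    genome: GenomeModel,
    config: SimulationConfig,
    seed: int,
) -> list[ReadRecord]:
    """Expand a count-level draw into individual aligned reads.

    The first random draw is the same multinomial as :func:`simulate_counts`
    with the same seed, so the two layers agree bin-for-bin.  Each read is
    placed uniformly within its bin (clipped so it fits the chromosome);
    ``mapq_low_fraction`` of reads get MAPQ 0, the rest MAPQ 60;
    ``mito_fraction`` are reassigned to the mitochondrial contig;
    ``duplicate_fraction`` are flagged duplicate; strand is fair-coin.
    """
    if config.mito_fraction > 0 and not genome.has_mito:
        raise ValueError("mito_fraction > 0 but the genome has no mitochondrial contig")
    n = config.n_reads_per_sample
    rng = np.random.default_rng(seed)
    flat_counts = rng.multinomial(n, imap.weights)  # same draw as simulate_counts

    # expand to per-read (chrom, bin) assignments in flat-bin order
    bin_ids = np.repeat(np.arange(imap.n_bins), flat_counts)
    offsets_within = rng.integers(0, imap.bin_size, size=n)
    low_mapq = rng.random(n) < config.mapq_low_fraction
    to_mito = rng.random(n) < config.mito_fraction
    duplicate = rng.random(n) < config.duplicate_fraction
    reverse = rng.random(n) < 0.5
    mito_len = genome.length_of(genome.mito_name) if genome.has_mito else 0
    n_mito = int(to_mito.sum())
    mito_pos = (
        rng.integers(0, max(mito_len - config.read_length, 1), size=n_mito)
        if n_mito else np.empty(0, dtype=np.int64)
    )

    chrom_of_bin: list[str] = []
    bin_start: np.ndarray = np.empty(imap.n_bins, dtype=np.int64)
    for chrom, (start, nb) in imap.offsets.items():
        chrom_of_bin.extend([chrom] * nb)
        bin_start[start:start + nb] = np.arange(nb) * imap.bin_size

    reads: list[ReadRecord] = []
    mito_cursor = 0
    for i in range(n):
        if to_mito[i]:
            chrom = genome.mito_name
            pos = int(mito_pos[mito_cursor])
            mito_cursor += 1
        else:
            b = bin_ids[i]
            chrom = chrom_of_bin[b]
            pos = int(bin_start[b] + offsets_within[i])
            pos = min(pos, genome.length_of(chrom) - config.read_length)
            pos = max(pos, 0)
        reads.append(
            ReadRecord(
                chromosome=chrom,
                position=pos,
                mapq=0 if low_mapq[i] else 60,
                strand="-" if reverse[i] else "+",
                is_duplicate=bool(duplicate[i]),
            )
        )
    return reads


def write_sam(
    reads: Sequence[ReadRecord],
    genome: GenomeModel,
    destination: str | Path,
    read_length: int = 50,
) -> None:
    """Write reads as a text SAM file with @HD/@SQ headers for every contig.

    Positions are converted to 1-based POS; strand/duplicate/secondary/
    supplementary/unmapped map onto the standard FLAG bits.  A read extending
    past its chromosome end is rejected.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome.chromosomes],
    }
    with pysam.AlignmentFile(str(destination), "w", header=header) as out:
        refs = {name: i for i, (name, _) in enumerate(genome.chromosomes)}
        for i, read in enumerate(reads):
            if read.chromosome not in refs:
                raise ValueError(f"read {i}: contig {read.chromosome!r} not in genome")
            if read.position + read_length > genome.length_of(read.chromosome):
                raise ValueError(
                    f"read {i}: extends past end of {read.chromosome} "
                    f"(pos {read.position} + {read_length} > "
                    f"{genome.length_of(read.chromosome)})"
                )
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = f"r{i:08d}"
            seg.flag = (
                (0x10 if read.strand == "-" else 0)
                | (0x4 if read.is_unmapped else 0)
                | (0x100 if read.is_secondary else 0)
                | (0x400 if read.is_duplicate else 0)
                | (0x800 if read.is_supplementary else 0)
            )
            seg.reference_id = refs[read.chromosome]
            seg.reference_start = read.position
            seg.mapping_quality = read.mapq if read.mapq is not None else 255
            if not read.is_unmapped:
                seg.cigar = [(0, read_length)]
            out.write(seg)


def simulate_dataset(
    genome: GenomeModel,
    config: SimulationConfig,
    conditions: Sequence[str],
    n_replicates: int,
    seed: int,
    out_dir: str | Path,
    bin_size: int = 10_000,
) -> dict[str, list[Path]]:
    """Write one SAM file per (condition, replicate); return paths per condition.

    Replicates share the condition's intensity map and differ only in the
    sampling seed, mirroring independent sequencing experiments of the same
    biological condition.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    draw_seeds = root.spawn(len(conditions) * n_replicates)
    paths: dict[str, list[Path]] = {}
    k = 0
    for condition in conditions:
        imap = build_intensity_map(genome, config, condition, seed=seed, bin_size=bin_size)
        paths[condition] = []
        for rep in range(1, n_replicates + 1):
            rep_seed = int(draw_seeds[k].generate_state(1)[0] % (2**31))
            k += 1
            reads = simulate_reads(imap, genome, config, seed=rep_seed)
            path = out_dir / f"{condition}_rep{rep}.sam"
            write_sam(reads, genome, path, read_length=config.read_length)
            paths[condition].append(path)
    return paths
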