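"""Binned damage profiles: bin, normalize, discard sparse bins, aggregate.

The core procedure: each filtered read is assigned to a fixed-width genomic
bin (10 kb by default) by its first-base (leftmost aligned) position; bin
counts are normalized by the library size (number of filtered reads) times a
reporting scale (reads per million by default); bins with fewer than
``min_hits`` raw reads (10 by default) are discarded; retained normalized
values are summed per chromosome, and per-chromosome totals are averaged
across a condition's replicate experiments.

Coordinates are 0-based, half-open throughout; bin ``k`` covers
``[k*bin_size, (k+1)*bin_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .ingest import ReadRecord

__all__ = [
    "BinGrid",
    "BinnedCounts",
    "NormalizedProfile",
    "ChromTotals",
    "ConditionSummary",
    "assign_bin",
    "bin_counts",
    "normalize_and_filter",
    "chrom_totals",
    "condition_mean",
    "write_profile",
    "read_bedgraph",
    "write_chrom_totals",
    "read_chrom_totals",
]

DEFAULT_BIN_SIZE = 10_000
DEFAULT_SCALE = 1e6
DEFAULT_MIN_HITS = 10


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width binning grid (half-open bins of ``bin_size`` bases)."""

    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")


@dataclass
class BinnedCounts:
    """Raw per-(chromosome, bin) hit counts plus the library size.

    ``counts`` maps each analyzable chromosome to a dense integer array, one
    entry per bin.  The sum over all bins is at most ``library_size`` (equal
    when every filtered read lies on an analyzable chromosome).
    """

    counts: dict[str, np.ndarray]
    library_size: int
    grid: BinGrid = field(default_factory=BinGrid)

    def total(self) -> int:
        return int(sum(int(arr.sum()) for arr in self.counts.values()))

    def __getitem__(self, key: tuple[str, int]) -> int:
        chrom, idx = key
        arr = self.counts[chrom]
        return int(arr[idx]) if 0 <= idx < arr.size else 0


@dataclass
class NormalizedProfile:
    """Library-normalized bin values with the sparse bins masked out.

    ``values[chrom][k]`` is ``raw * scale / library_size`` for retained bins
    and 0 for discarded ones; ``retained[chrom][k]`` flags which bins
    survived the ``min_hits`` cutoff.
    """

    values: dict[str, np.ndarray]
    retained: dict[str, np.ndarray]
    scale: float
    min_hits: int
    grid: BinGrid
    sample: str = "sample"

    def retained_items(self) -> Iterable[tuple[str, int, float]]:
        """Yield (chromosome, bin index, value) for retained bins, in order."""
        for chrom, mask in self.retained.items():
            vals = self.values[chrom]
            for k in np.flatnonzero(mask):
                yield chrom, int(k), float(vals[k])


@dataclass
class ChromTotals:
    """Per-chromosome sums of retained normalized bin values for one sample."""

    totals: dict[str, float]
    sample: str = "sample"

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.totals)


@dataclass
class ConditionSummary:
    """Per-chromosome means of :class:`ChromTotals` across replicates."""

    means: dict[str, float]
    n_replicates: int
    condition: str = "condition"

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.means)


def assign_bin(position: int, grid: BinGrid) -> int:
    """Bin index of a 0-based position: ``floor(position / bin_size)``."""
    if position < 0:
        raise ValueError(f"position must be >= 0, got {position}")
    return position // grid.bin_size


def bin_counts(
    reads: Iterable[ReadRecord],
    genome: GenomeModel,
    grid: BinGrid | None = None,
    library_size: int | None = None,
) -> BinnedCounts:
    """Count filtered reads per (chromosome, bin), keyed by first-base position.

    Every read must lie on an analyzable chromosome of ``genome`` (filtering,
    including the mitochondrial discard, happens upstream).  ``library_size``
    defaults to the number of reads supplied, which is correct only when the
    stream is exactly the filtered stream.
    """
    grid = grid or BinGrid()
    analyzable = set(genome.analyzable_chromosomes)
    counts = {
        chrom: np.zeros(genome.n_bins(chrom, grid.bin_size), dtype=np.int64)
        for chrom in genome.analyzable_chromosomes
    }
    n = 0
    for read in reads:
        n += 1
        if read.chromosome not in analyzable:
            raise ValueError(
                f"read on contig {read.chromosome!r} which is not an analyzable "
                "chromosome of the genome (unknown or excluded contig)"
            )
        counts[read.chromosome][assign_bin(read.position, grid)] += 1
    return BinnedCounts(counts=counts, library_size=n if library_size is None else library_size,
                        grid=grid)


def counts_from_arrays(
    arrays: dict[str, np.ndarray], library_size: int, grid: BinGrid | None = None
) -> BinnedCounts:
    """Wrap precomputed per-chromosome count arrays (the count-level fast path)."""
    return BinnedCounts(
        counts={c: np.asarray(a, dtype=np.int64) for c, a in arrays.items()},
        library_size=int(library_size),
        grid=grid or BinGrid(),
    )


def normalize_and_filter(
    counts: BinnedCounts,
    scale: float = DEFAULT_SCALE,
    min_hits: int = DEFAULT_MIN_HITS,
    *,
    threshold_on: Literal["raw", "normalized"] = "raw",
    sample: str = "sample",
) -> NormalizedProfile:
    """Normalize bin counts by library size and discard sparse bins.

    Retained bins get value ``raw * scale / library_size``.  The ``min_hits``
    cutoff is strict (``raw < min_hits`` discards, so 10 is retained and 9 is
    not with the default) and applies to raw counts by default;
    ``threshold_on="normalized"`` applies it to the normalized values instead.
    """
    if counts.library_size <= 0:
        raise ValueError("library_size must be positive to normalize")
    if min_hits < 0:
        raise ValueError("min_hits must be >= 0")
    factor = scale / counts.library_size
    values: dict[str, np.ndarray] = {}
    retained: dict[str, np.ndarray] = {}
    for chrom, raw in counts.counts.items():
        norm = raw * factor
        mask = (norm >= min_hits) if threshold_on == "normalized" else (raw >= min_hits)
        values[chrom] = np.where(mask, norm, 0.0)
        retained[chrom] = mask
    return NormalizedProfile(values=values, retained=retained, scale=scale,
                             min_hits=min_hits, grid=counts.grid, sample=sample)


def chrom_totals(profile: NormalizedProfile) -> ChromTotals:
    """Sum retained normalized values per chromosome (0 when none retained)."""
    totals = {
        chrom: float(profile.values[chrom][profile.retained[chrom]].sum())
        for chrom in profile.values
    }
    return ChromTotals(totals=totals, sample=profile.sample)


def condition_mean(replicates: Sequence[ChromTotals], condition: str = "condition") -> ConditionSummary:
    """Arithmetic mean of per-chromosome totals across replicate experiments."""
    if not replicates:
        raise ValueError("at least one replicate required")
    chroms = replicates[0].chromosomes
    for rep in replicates[1:]:
        if set(rep.chromosomes) != set(chroms):
            raise ValueError(
                f"replicate {rep.sample!r} has chromosome set {sorted(rep.chromosomes)} "
                f"!= {sorted(chroms)} of {replicates[0].sample!r}"
            )
    means = {
        chrom: float(np.mean([rep.totals[chrom] for rep in replicates]))
        for chrom in chroms
    }
    return ConditionSummary(means=means, n_replicates=len(replicates), condition=condition)


# ---------------------------------------------------------------------------
# text output: bedGraph for profiles, TSV for per-chromosome totals

def write_profile(
    profile: NormalizedProfile, genome: GenomeModel, destination: str | Path
) -> None:
    """Write retained bins as bedGraph (chrom, 0-based start, half-open end, value).

    Bin ends are clipped to the chromosome length.  Values are written with
    shortest round-trip float formatting so write -> parse -> write is
    byte-stable.
    """
    bs = profile.grid.bin_size
    with open(destination, "w") as fh:
        fh.write(f'track type=bedGraph name="{profile.sample}"\n')
        for chrom, k, value in profile.retained_items():
            start = k * bs
            end = min(start + bs, genome.length_of(chrom))
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


def read_bedgraph(path: str | Path) -> tuple[str, list[tuple[str, int, int, float]]]:
    """Parse a bedGraph file; return (track name, records)."""
    name = "sample"
    records: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "browser")):
                continue
            if line.startswith("track"):
                if 'name="' in line:
                    name = line.split('name="', 1)[1].split('"', 1)[0]
                continue
            chrom, start, end, value = line.split("\t")
            records.append((chrom, int(start), int(end), float(value)))
    return name, records


def write_bedgraph_records(
    name: str, records: Iterable[tuple[str, int, int, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


def write_chrom_totals(totals: ChromTotals, path: str | Path) -> None:
    """Write per-chromosome totals as TSV (sample, chromosome, total_normalized_hits)."""
    frame = pd.DataFrame(
        {
            "sample": totals.sample,
            "chromosome": list(totals.totals),
            "total_normalized_hits": [repr(v) for v in totals.totals.values()],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_chrom_totals(path: str | Path) -> ChromTotals:
    frame = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    samples = frame["sample"].unique()
    if len(samples) != 1:
        raise ValueError(f"{path}: expected one sample per totals file, found {list(samples)}")
    totals = dict(zip(frame["chromosome"], frame["total_normalized_hits"].astype(float)))
    return ChromTotals(totals=totals, sample=str(samples[0]))
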