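"""Genome models: the coordinate frame for binning.

A :class:`GenomeModel` is an ordered set of named contigs with lengths, one of
which may be flagged as the mitochondrial contig.  Mitochondrial reads are
discarded by the damage-profiling pipeline, so the mitochondrial contig is
never part of the *analyzable* chromosome set over which bins, per-chromosome
totals and the paired test are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["GenomeModel", "make_genome", "read_genome_table", "write_genome_table"]

#: Contig names commonly used for the mitochondrial genome.
MITO_ALIASES = ("chrM", "MT", "chrMT", "M")


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names/lengths plus the excluded mitochondrial contig.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs for every contig, including the
        mitochondrial one if present.
    mito_name
        Name of the contig treated as mitochondrial, or ``None``.  If given
        and present in ``chromosomes`` it is excluded from the analyzable set.
    """

    chromosomes: tuple[tuple[str, int], ...]
    mito_name: str | None = None

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if not self.analyzable_chromosomes:
            raise ValueError("genome has no analyzable (non-mitochondrial) chromosome")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def analyzable_chromosomes(self) -> tuple[str, ...]:
        """Contig names entering the analysis (mitochondrial contig excluded)."""
        return tuple(name for name, _ in self.chromosomes if name != self.mito_name)

    @property
    def has_mito(self) -> bool:
        return self.mito_name is not None and self.mito_name in self.names

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise KeyError(f"contig {name!r} not in genome") from None

    def n_bins(self, name: str, bin_size: int) -> int:
        """Number of fixed-width bins covering contig ``name`` (last bin may be short)."""
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        return -(-self.length_of(name) // bin_size)


def make_genome(
    n_chroms: int,
    chrom_length: int,
    include_mito: bool = False,
    *,
    mito_length: int = 16_569,
    prefix: str = "chr",
    mito_name: str = "chrM",
) -> GenomeModel:
    """Build a toy genome of ``n_chroms`` equal-length chromosomes.

    Chromosomes are named ``chr1..chrN``; when ``include_mito`` is true a
    mitochondrial contig (default length that of the human mitochondrial
    genome) is appended and flagged for exclusion.
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    chroms = [(f"{prefix}{i + 1}", int(chrom_length)) for i in range(n_chroms)]
    if include_mito:
        if mito_length <= 0:
            raise ValueError("mito_length must be positive")
        chroms.append((mito_name, int(mito_length)))
        return GenomeModel(tuple(chroms), mito_name=mito_name)
    return GenomeModel(tuple(chroms), mito_name=None)


def read_genome_table(path: str | Path, mito_name: str | None = "auto") -> GenomeModel:
    """Read a two-column TSV of (contig name, length).

    ``mito_name="auto"`` flags the first contig whose name is a common
    mitochondrial alias (chrM, MT, chrMT, M); pass an explicit name or
    ``None`` to override.
    """
    table = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["name", "length"], dtype={"name": str})
    chroms = tuple((str(n), int(l)) for n, l in table.itertuples(index=False, name=None))
    if mito_name == "auto":
        mito_name = next((n for n, _ in chroms if n in MITO_ALIASES), None)
    return GenomeModel(chroms, mito_name=mito_name)


def write_genome_table(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")
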