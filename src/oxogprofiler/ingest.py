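"""Alignment ingestion and read-level filtering.

Reads aligned short reads from SAM (via pysam) or BED interval files into
:class:`ReadRecord` objects, and applies the damage-profiling filters: a
mapping-quality threshold (MAPQ >= 20 by default, inclusive), discard of
mitochondrial reads, and discard of unmapped/secondary/supplementary/duplicate
alignments.  The number of reads surviving all filters is the *library size*
used downstream for normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pandas as pd
import pysam

from .genome import MITO_ALIASES, GenomeModel

__all__ = [
    "ReadRecord",
    "FilterPolicy",
    "read_alignments",
    "passes_filter",
    "filter_stream",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One aligned read, reduced to the fields the pipeline consumes.

    ``position`` is the 0-based leftmost aligned reference base.  ``mapq`` may
    be ``None`` for formats that carry no mapping quality (plain BED); such
    reads are treated as passing any MAPQ threshold.
    """

    chromosome: str
    position: int
    mapq: int | None = None
    strand: Literal["+", "-"] = "+"
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")
        if self.mapq is not None and not 0 <= self.mapq <= 255:
            raise ValueError(f"mapq must be in [0, 255], got {self.mapq}")


@dataclass(frozen=True)
class FilterPolicy:
    """Read-level filter: MAPQ threshold, excluded contigs, and flag drops.

    Defaults implement the standard treatment: keep primary mapped
    non-duplicate reads with MAPQ >= 20 that do not map to the mitochondrial
    contig.  Each drop is an independent flag so the literal minimal filter
    (MAPQ only) is also expressible.
    """

    min_mapq: int = 20
    excluded_chroms: frozenset[str] = frozenset(MITO_ALIASES)
    drop_unmapped: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_duplicates: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")

    @classmethod
    def for_genome(cls, genome: GenomeModel, **kwargs) -> "FilterPolicy":
        """Policy excluding exactly the genome's mitochondrial contig."""
        excl = frozenset({genome.mito_name}) if genome.mito_name else frozenset()
        return cls(excluded_chroms=excl, **kwargs)


def _records_from_sam(source: str | Path) -> Iterator[ReadRecord]:
    with pysam.AlignmentFile(str(source), "r", check_sq=False) as fh:
        for i, rec in enumerate(fh.fetch(until_eof=True), start=1):
            try:
                yield ReadRecord(
                    chromosome=rec.reference_name if rec.reference_name else "*",
                    position=max(rec.reference_start, 0),
                    mapq=rec.mapping_quality,
                    strand="-" if rec.is_reverse else "+",
                    is_unmapped=rec.is_unmapped,
                    is_secondary=rec.is_secondary,
                    is_supplementary=rec.is_supplementary,
                    is_duplicate=rec.is_duplicate,
                )
            except ValueError as exc:  # pragma: no cover - defensive
                raise ValueError(f"{source}: malformed record {i}: {exc}") from exc


def _records_from_bed(source: str | Path) -> Iterator[ReadRecord]:
    import io

    with open(source) as fh:  # strip track/browser header lines before parsing
        body = "".join(
            line for line in fh
            if line.strip() and not line.startswith(("track", "browser", "#"))
        )
    if not body:
        raise ValueError(f"{source}: BED file contains no interval records")
    rows = pd.read_csv(io.StringIO(body), sep="\t", header=None, dtype=str)
    ncol = rows.shape[1]
    if ncol < 3:
        raise ValueError(f"{source}: BED requires >= 3 columns, found {ncol}")
    if ncol < 5:
        log.warning(
            "%s: BED file has no score column; reads are treated as passing "
            "the MAPQ filter", source,
        )
    for i, row in enumerate(rows.itertuples(index=False, name=None), start=1):
        chrom, start = row[0], row[1]
        try:
            pos = int(start)
        except (TypeError, ValueError):
            raise ValueError(f"{source}: malformed record at data line {i}: "
                             f"chromStart {start!r} is not an integer") from None
        mapq: int | None = None
        if ncol >= 5 and row[4] not in (None, ".", ""):
            try:
                mapq = min(int(float(row[4])), 255)
            except ValueError:
                raise ValueError(f"{source}: malformed record at data line {i}: "
                                 f"score {row[4]!r} is not numeric") from None
        strand = "+"
        if ncol >= 6 and row[5] in ("+", "-"):
            strand = row[5]
        yield ReadRecord(chromosome=str(chrom), position=pos, mapq=mapq, strand=strand)


def read_alignments(source: str | Path, format: str = "sam") -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` objects from a SAM or BED file.

    SAM POS (1-based) is converted to a 0-based ``position``; FLAG bits are
    decoded into the boolean fields.  For BED, ``chromStart`` is already
    0-based; the score column, when present, is interpreted as MAPQ.
    """
    fmt = format.lower()
    if fmt == "sam":
        return _records_from_sam(source)
    if fmt == "bed":
        return _records_from_bed(source)
    raise ValueError(f"unknown alignment format {format!r} (expected 'sam' or 'bed')")


def passes_filter(read: ReadRecord, policy: FilterPolicy) -> bool:
    """True iff ``read`` survives every filter in ``policy``.

    The MAPQ threshold is inclusive: a read with MAPQ exactly equal to
    ``min_mapq`` passes.  Reads with unknown MAPQ (``None``) pass the
    threshold.
    """
    if policy.drop_unmapped and read.is_unmapped:
        return False
    if policy.drop_secondary and read.is_secondary:
        return False
    if policy.drop_supplementary and read.is_supplementary:
        return False
    if policy.drop_duplicates and read.is_duplicate:
        return False
    if read.chromosome in policy.excluded_chroms:
        return False
    if read.mapq is not None and read.mapq < policy.min_mapq:
        return False
    return True


def filter_stream(
    reads: Iterable[ReadRecord], policy: FilterPolicy
) -> tuple[list[ReadRecord], int]:
    """Apply ``policy`` to a read stream; return survivors and the library size.

    The library size — the denominator of the downstream normalization — is
    the number of reads surviving *all* filters.  An empty filtered stream is
    an error because that normalization would be undefined.
    """
    n_in = 0
    kept: list[ReadRecord] = []
    for read in reads:
        n_in += 1
        if passes_filter(read, policy):
            kept.append(read)
    if not kept:
        raise ValueError(
            f"no reads survive filtering ({n_in} read in); "
            "library-size normalization is undefined"
        )
    log.info("filter: %d reads in, %d retained (library size)", n_in, len(kept))
    return kept, len(kept)
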