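"""Genomic coordinate primitives: bin grids, gene models, per-bin tracks.

Conventions used throughout the package:

* genomic intervals (exons, promoters, peaks, bins) are 0-based half-open
  ``[start, end)`` — the BED convention;
* variant positions are 1-based — the variant-table convention;
* conversions between the two live here and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .errors import ParameterError

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 1000


def pos_1based_to_0based(pos: int) -> int:
    """Convert a 1-based variant position to a 0-based offset."""
    if pos < 1:
        raise ParameterError(f"1-based position must be >= 1, got {pos}")
    return pos - 1


def interval_0based_to_1based_inclusive(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive bounds."""
    if end <= start:
        raise ParameterError(f"empty interval [{start}, {end})")
    return start + 1, end


def interval_1based_inclusive_to_0based(start: int, stop: int) -> tuple[int, int]:
    """Inverse of :func:`interval_0based_to_1based_inclusive`."""
    if stop < start or start < 1:
        raise ParameterError(f"invalid 1-based inclusive interval {start}:{stop}")
    return start - 1, stop


@dataclass(frozen=True)
class BinGrid:
    """Fixed-resolution binning of a genome.

    Bin ``i`` of a chromosome covers ``[i * resolution, (i + 1) * resolution)``;
    the last bin may extend past the chromosome end (``n_bins = ceil(L / res)``).
    """

    chrom_sizes: Mapping[str, int]
    resolution: int

    def __post_init__(self):
        if self.resolution <= 0:
            raise ParameterError(f"resolution must be positive, got {self.resolution}")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ParameterError(f"chromosome {chrom} has non-positive length {size}")
        object.__setattr__(self, "chrom_sizes", dict(self.chrom_sizes))

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.resolution)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Bin containing 0-based position ``pos``."""
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ParameterError(f"position {pos} outside {chrom} (length {self.chrom_sizes[chrom]})")
        return pos // self.resolution

    def bin_interval(self, chrom: str, i: int) -> tuple[int, int]:
        """0-based half-open genomic interval of bin ``i`` (clipped to the chromosome)."""
        n = self.n_bins(chrom)
        if not 0 <= i < n:
            raise ParameterError(f"bin {i} outside {chrom} (n_bins {n})")
        start = i * self.resolution
        return start, min(start + self.resolution, self.chrom_sizes[chrom])

    def bins_overlapping(self, chrom: str, start: int, end: int) -> range:
        """Bins overlapping the 0-based half-open interval ``[start, end)``."""
        if end <= start:
            return range(0, 0)
        lo = max(start, 0) // self.resolution
        hi = min(-(-end // self.resolution), self.n_bins(chrom))
        return range(lo, hi)


@dataclass(frozen=True)
class GeneModel:
    """A gene: TSS, strand, and sorted non-overlapping exons (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ParameterError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a, b) in exons:
            if b <= a:
                raise ParameterError(f"{self.gene_id}: empty exon [{a}, {b})")
        for (_, b0), (a1, _) in zip(exons, exons[1:]):
            if a1 < b0:
                raise ParameterError(f"{self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def promoter(self) -> tuple[int, int]:
        """Strand-aware promoter: 2 kb upstream to 1 kb downstream of the TSS."""
        if self.strand == "+":
            return self.tss - PROMOTER_UPSTREAM, self.tss + PROMOTER_DOWNSTREAM
        return self.tss - PROMOTER_DOWNSTREAM, self.tss + PROMOTER_UPSTREAM

    @property
    def span(self) -> tuple[int, int]:
        """Convex hull of promoter and exons (0-based half-open)."""
        starts = [self.promoter[0]] + [a for a, _ in self.exons]
        ends = [self.promoter[1]] + [b for _, b in self.exons]
        return min(starts), max(ends)


@dataclass
class BinTrack:
    """A per-bin scalar signal on one chromosome of a grid.

    ``mask`` marks bins that carry a valid value; masked bins (``mask == False``)
    are excluded from downstream statistics.
    """

    chrom: str
    grid: BinGrid
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.grid.n_bins(self.chrom)
        if self.values.shape != (n,):
            raise ParameterError(
                f"track length {self.values.shape} does not match {n} bins on {self.chrom}"
            )
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ParameterError("mask length does not match bin count")

    def same_grid(self, other: "BinTrack") -> bool:
        return (
            self.chrom == other.chrom
            and self.grid.resolution == other.grid.resolution
            and self.grid.chrom_sizes == other.grid.chrom_sizes
        )


def write_bedgraph(track: BinTrack, path, header: str | None = None) -> None:
    """Write a BinTrack as bedGraph; masked bins are omitted."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        for i, (v, ok) in enumerate(zip(track.values, track.mask)):
            if not ok:
                continue
            s, e = track.grid.bin_interval(track.chrom, i)
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.6g}\n")


def iter_gene_table(genes: list[GeneModel]) -> Iterator[str]:
    """Serialize genes as tab-delimited rows (exons semicolon-joined start-end)."""
    for g in genes:
        exons = ";".join(f"{a}-{b}" for a, b in g.exons)
        yield f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{exons}"


def write_gene_table(genes: list[GeneModel], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        for row in iter_gene_table(genes):
            fh.write(row + "\n")


def read_gene_table(path) -> list[GeneModel]:
    from .errors import FormatError

    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"expected 5 tab-separated fields, got {len(parts)}", line=ln)
            gene_id, chrom, strand, tss, exons_s = parts
            try:
                exons = tuple(
                    (int(p.split("-")[0]), int(p.split("-")[1]))
                    for p in exons_s.split(";")
                    if p
                )
                genes.append(GeneModel(gene_id, chrom, strand, int(tss), exons))
            except (ValueError, ParameterError) as exc:
                raise FormatError(str(exc), line=ln) from exc
    return genes
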