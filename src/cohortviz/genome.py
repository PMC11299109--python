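"""Genome assembly model and linearized genome coordinates.

A :class:`GenomeAssembly` is an ordered list of named chromosomes with
lengths.  Genome-wide tracks are drawn on a single linear axis obtained by
concatenating the chromosomes in assembly order with no gaps; the
:func:`linearize` / :func:`delinearize` pair is the bijection between
``(chromosome, position)`` and that axis.

Coordinates are 0-based and intervals half-open, matching BED.  Chromosome
order is taken verbatim from the ``chrom.sizes`` file — no natural sort — so
the axis is reproducible from the input file alone.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

__all__ = [
    "GenomeAssembly",
    "Locus",
    "GenomicInterval",
    "read_chrom_sizes",
    "cumulative_offsets",
    "linearize",
    "delinearize",
]


@dataclass(frozen=True)
class Locus:
    """A single 0-based position on a named chromosome."""

    chrom: str
    pos: int


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on one chromosome, 0-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


class GenomeAssembly:
    """Ordered, immutable set of chromosomes with lengths.

    Parameters
    ----------
    name:
        Assembly identifier (e.g. ``"hg38"`` or a toy name).
    chromosomes:
        Iterable of ``(name, length)``; order is significant and preserved.
    """

    def __init__(self, name: str, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(c), int(n)) for c, n in chromosomes)
        if not chroms:
            raise ValueError("assembly must contain at least one chromosome")
        seen: set[str] = set()
        for cname, length in chroms:
            if length <= 0:
                raise ValueError(f"chromosome {cname!r} has non-positive length {length}")
            if cname in seen:
                raise ValueError(f"duplicate chromosome name {cname!r}")
            seen.add(cname)
        self.name = name
        self.chromosomes = chroms
        # prefix sums over lengths give each chromosome's linear offset
        offsets: dict[str, int] = {}
        acc = 0
        starts: list[int] = []
        names: list[str] = []
        for cname, length in chroms:
            offsets[cname] = acc
            starts.append(acc)
            names.append(cname)
            acc += length
        self._offsets = offsets
        self._starts = starts
        self._names = names
        self._lengths = {c: n for c, n in chroms}
        self.total_length = acc

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenomeAssembly({self.name!r}, {len(self.chromosomes)} chromosomes)"

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenomeAssembly)
            and self.name == other.name
            and self.chromosomes == other.chromosomes
        )

    def __hash__(self) -> int:
        return hash((self.name, self.chromosomes))

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r} in assembly {self.name!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths


def read_chrom_sizes(path: Union[str, Path], name: str | None = None) -> GenomeAssembly:
    """Read a two-column ``chrom.sizes`` TSV (name, length; no header)."""
    path = Path(path)
    chroms: list[tuple[str, int]] = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{i}: expected two tab-separated columns")
        chroms.append((parts[0], int(parts[1])))
    return GenomeAssembly(name or path.stem, chroms)


def write_chrom_sizes(assembly: GenomeAssembly, path: Union[str, Path]) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{n}\n" for c, n in assembly.chromosomes)
    )


def cumulative_offsets(assembly: GenomeAssembly) -> Mapping[str, int]:
    """Linear offset (bp) of each chromosome's first base; prefix sums."""
    return dict(assembly._offsets)


def linearize(assembly: GenomeAssembly, locus: Union[Locus, tuple[str, int]]) -> int:
    """Map ``(chrom, pos)`` to the gapless linear genome coordinate."""
    if isinstance(locus, tuple):
        locus = Locus(*locus)
    length = assembly.length_of(locus.chrom)
    if not 0 <= locus.pos < length:
        raise ValueError(
            f"position {locus.pos} out of range for {locus.chrom} (length {length})"
        )
    return assembly._offsets[locus.chrom] + locus.pos


def linearize_interval(assembly: GenomeAssembly, interval: GenomicInterval) -> tuple[int, int]:
    """Linear ``(start, end)`` of an intra-chromosome half-open interval."""
    length = assembly.length_of(interval.chrom)
    if interval.end > length:
        raise ValueError(
            f"interval end {interval.end} beyond {interval.chrom} length {length}"
        )
    off = assembly._offsets[interval.chrom]
    return off + interval.start, off + interval.end


def delinearize(assembly: GenomeAssembly, coord: int) -> Locus:
    """Inverse of :func:`linearize`."""
    coord = int(coord)
    if not 0 <= coord < assembly.total_length:
        raise ValueError(
            f"linear coordinate {coord} out of range [0, {assembly.total_length})"
        )
    i = bisect.bisect_right(assembly._starts, coord) - 1
    return Locus(assembly._names[i], coord - assembly._starts[i])
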