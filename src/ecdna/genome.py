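"""Genomic data model and readers for chrom.sizes, BED and fragment files.

All coordinates are 0-based half-open (the BED / fragments.tsv convention).
Strand is ignored throughout: ATAC coverage is strand-agnostic.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import FormatError


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-overlap (>= 1 bp) under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class Genome(Mapping[str, int]):
    """Ordered mapping of chromosome name to length in bp."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        self._sizes: dict[str, int] = {}
        for name, length in items:
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if int(length) <= 0:
                raise ValueError(f"non-positive length for {name!r}: {length}")
            self._sizes[str(name)] = int(length)

    def __getitem__(self, key: str) -> int:
        return self._sizes[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def contains(self, interval: GenomicInterval) -> bool:
        size = self._sizes.get(interval.chrom)
        return size is not None and interval.end <= size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Genome({self._sizes!r})"


@dataclass(frozen=True)
class RegionSet:
    """A named collection of intervals (amplicon, exclusion list, null draw)."""

    name: str
    intervals: tuple[GenomicInterval, ...]

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class FragmentRecord:
    """One deduplicated ATAC fragment attributed to a cell barcode."""

    interval: GenomicInterval
    barcode: str
    support: int = 1

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError(f"support must be >= 1, got {self.support}")


def read_chrom_sizes(path: str | Path) -> Genome:
    """Parse a two-column (name, length) tab-separated chrom.sizes file."""
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            name, length_s = fields
            try:
                length = int(length_s)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer length {length_s!r}"
                ) from None
            if name in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate name {name!r}")
            seen.add(name)
            entries.append((name, length))
    if not entries:
        raise FormatError(f"{path}: empty chrom.sizes file")
    return Genome(entries)


_BED_SKIP_PREFIXES = ("track", "browser", "#")


def _iter_bed_lines(path: str | Path):
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if end <= start or start < 0:
                raise FormatError(
                    f"{path}: line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            yield lineno, chrom, start, end, fields


def read_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Read BED3+ into a single RegionSet; extra columns are ignored."""
    intervals = [
        GenomicInterval(chrom, start, end)
        for _, chrom, start, end, _ in _iter_bed_lines(path)
    ]
    return RegionSet(name=name or Path(path).stem, intervals=tuple(intervals))


def read_bed_grouped(path: str | Path) -> dict[str, RegionSet]:
    """Read BED4+ grouping records by the name column (column 4).

    Multi-segment amplicons are expressed as several BED lines sharing a name.
    Records without a name column each become their own singleton set.
    """
    groups: dict[str, list[GenomicInterval]] = {}
    for lineno, chrom, start, end, fields in _iter_bed_lines(path):
        label = fields[3] if len(fields) >= 4 and fields[3] else f"region_{lineno}"
        groups.setdefault(label, []).append(GenomicInterval(chrom, start, end))
    return {k: RegionSet(name=k, intervals=tuple(v)) for k, v in groups.items()}


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for iv in regions.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{regions.name}\n")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fragments(path: str | Path) -> Iterator[FragmentRecord]:
    """Stream 5-column fragment records (chrom, start, end, barcode, count).

    Plain or gzip text; header lines beginning ``#`` are skipped.
    """
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(
                    f"{path}: line {lineno}: expected 5 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, barcode, count_s = fields
            try:
                start, end, count = int(start_s), int(end_s), int(count_s)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinate or count"
                ) from None
            yield FragmentRecord(GenomicInterval(chrom, start, end), barcode, count)


def write_fragments(records: Iterable[FragmentRecord], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rec in records:
            iv = rec.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.barcode}\t{rec.support}\n")


def overlap_count(
    fragments: Iterable[FragmentRecord], region: GenomicInterval
) -> int:
    """Number of fragments intersecting ``region`` (each fragment counts once).

    The duplicate-support column is deliberately ignored: fragments are
    already deduplicated and support would re-count PCR copies.
    """
    return sum(1 for frag in fragments if frag.interval.overlaps(region))


class FragmentIndex:
    """Column-oriented fragment store for fast per-barcode overlap counting.

    Fragments are grouped per chromosome and sorted by start so that counting
    overlaps with a query interval is two binary searches plus a bincount.
    """

    def __init__(
        self,
        barcodes: Sequence[str],
        per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ):
        self.barcodes = list(barcodes)
        self._index = {b: i for i, b in enumerate(self.barcodes)}
        self._per_chrom = per_chrom
        self._max_len = {
            c: int((ends - starts).max()) if len(starts) else 0
            for c, (starts, ends, _) in per_chrom.items()
        }

    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    @property
    def n_fragments(self) -> int:
        return sum(len(starts) for starts, _, _ in self._per_chrom.values())

    @classmethod
    def from_arrays(
        cls,
        chroms: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        barcodes: np.ndarray,
        barcode_universe: Sequence[str] | None = None,
    ) -> "FragmentIndex":
        chroms = np.asarray(chroms)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        barcodes = np.asarray(barcodes)
        if barcode_universe is None:
            barcode_universe = sorted(np.unique(barcodes).tolist())
        lookup = {b: i for i, b in enumerate(barcode_universe)}
        codes = np.array([lookup.get(b, -1) for b in barcodes], dtype=np.int64)
        keep = codes >= 0
        chroms, starts, ends, codes = chroms[keep], starts[keep], ends[keep], codes[keep]
        per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            cs, ce, cc = starts[sel], ends[sel], codes[sel]
            order = np.argsort(cs, kind="stable")
            per_chrom[str(chrom)] = (cs[order], ce[order], cc[order])
        return cls(list(barcode_universe), per_chrom)

    @classmethod
    def from_records(
        cls,
        records: Iterable[FragmentRecord],
        barcode_universe: Sequence[str] | None = None,
    ) -> "FragmentIndex":
        chroms, starts, ends, bcs = [], [], [], []
        for rec in records:
            chroms.append(rec.interval.chrom)
            starts.append(rec.interval.start)
            ends.append(rec.interval.end)
            bcs.append(rec.barcode)
        return cls.from_arrays(
            np.array(chroms), np.array(starts), np.array(ends), np.array(bcs),
            barcode_universe,
        )

    @classmethod
    def from_file(
        cls, path: str | Path, barcode_universe: Sequence[str] | None = None
    ) -> "FragmentIndex":
        return cls.from_records(read_fragments(path), barcode_universe)

    def count_overlaps(
        self, intervals: GenomicInterval | Sequence[GenomicInterval]
    ) -> np.ndarray:
        """Per-barcode count of fragments overlapping any of the intervals."""
        if isinstance(intervals, GenomicInterval):
            intervals = [intervals]
        out = np.zeros(self.n_barcodes, dtype=np.int64)
        for iv in intervals:
            entry = self._per_chrom.get(iv.chrom)
            if entry is None:
                continue
            starts, ends, codes = entry
            hi = np.searchsorted(starts, iv.end, side="left")
            lo = np.searchsorted(starts, iv.start - self._max_len[iv.chrom], side="left")
            mask = ends[lo:hi] > iv.start
            out += np.bincount(codes[lo:hi][mask], minlength=self.n_barcodes)
        return out

    def total_per_barcode(self) -> np.ndarray:
        out = np.zeros(self.n_barcodes, dtype=np.int64)
        for _, (_, _, codes) in self._per_chrom.items():
            out += np.bincount(codes, minlength=self.n_barcodes)
        return out

    def chrom_counts(self, chrom: str) -> np.ndarray:
        """Per-barcode fragment count on one chromosome (e.g. the mito contig)."""
        out = np.zeros(self.n_barcodes, dtype=np.int64)
        entry = self._per_chrom.get(chrom)
        if entry is not None:
            out += np.bincount(entry[2], minlength=self.n_barcodes)
        return out
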