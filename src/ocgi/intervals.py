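"""Genomic interval model, BED I/O, and interval algebra.

All coordinates are 0-based half-open ([start, end)), the BED convention,
both in memory and on disk. Every operation in the package goes through
these primitives so there is a single place where coordinate semantics
live.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "FeatureCategory",
    "FeatureSet",
    "IntervalIndex",
    "read_bed",
    "write_bed",
    "overlap_length",
    "overlaps",
    "merge_intervals",
    "subtract",
    "derive_promoters",
    "total_length",
]

_VALID_STRANDS = {"+", "-", ".", None}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``.

    ``name``, ``score`` and ``strand`` are optional BED-style annotations.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}"


class FeatureCategory(str, Enum):
    exon = "exon"
    tss = "tss"
    blacklist = "blacklist"
    fantom_promoter = "fantom_promoter"
    repeat_mask = "repeat_mask"
    other = "other"


@dataclass
class FeatureSet:
    """A named category of annotation intervals (exons, TSSs, blacklist...).

    TSS feature sets carry strands so promoter windows can be derived;
    everything else is excluded as plain intervals.
    """

    category: FeatureCategory
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.category = FeatureCategory(self.category)
        self.intervals = sorted(self.intervals, key=GenomicInterval.sort_key)
        if self.category is FeatureCategory.tss:
            for iv in self.intervals:
                if iv.strand not in ("+", "-"):
                    raise ValueError(
                        f"TSS interval {iv} lacks a +/- strand, required for "
                        "promoter derivation"
                    )


# ---------------------------------------------------------------------------
# BED I/O

_DIALECT_COLS = {"bed3": 3, "bed4": 4, "bed6": 6}


def read_bed(path: str | Path, dialect: str = "bed3") -> list[GenomicInterval]:
    """Read a tab-separated BED3/BED4/BED6 file (no header).

    Coordinates are taken verbatim: BED is already 0-based half-open.
    Malformed lines raise ``ValueError`` naming the line number.
    """
    ncols = _DIALECT_COLS.get(dialect)
    if ncols is None:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncols:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {ncols} columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if ncols >= 4 else None
            score: float | None = None
            strand: str | None = None
            if ncols >= 6:
                score = float(fields[4]) if fields[4] not in (".", "") else None
                strand = fields[5] if fields[5] != "" else None
            try:
                out.append(
                    GenomicInterval(fields[0], start, end, name=name, score=score, strand=strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(
    intervals: Iterable[GenomicInterval], path: str | Path, dialect: str = "bed3"
) -> None:
    """Write intervals as sorted tab-separated BED (no header)."""
    ncols = _DIALECT_COLS.get(dialect)
    if ncols is None:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    with open(path, "w") as fh:
        for iv in ivs:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if ncols >= 4:
                fields.append(iv.name if iv.name is not None else ".")
            if ncols >= 6:
                fields.append(f"{iv.score:g}" if iv.score is not None else "0")
                fields.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Algebra


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by ``a`` and ``b`` (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_bp`` bases."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return overlap_length(a, b) >= min_bp


def merge_intervals(
    intervals: Sequence[GenomicInterval], track_sources: bool = False
) -> list[GenomicInterval]:
    """Fuse overlapping or book-ended (distance 0) intervals.

    Output is sorted and non-overlapping. With ``track_sources`` the merged
    interval's name is the comma-joined names of its inputs in positional
    order — the behaviour of ``bedtools merge -c 4 -o collapse``, used to
    preserve the species of origin when pooling interval sets.
    """
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    out: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    cur_names: list[str] = []
    for iv in ivs:
        if cur is not None and iv.chrom == cur.chrom and iv.start <= cur.end:
            cur = replace(cur, end=max(cur.end, iv.end))
            if iv.name is not None:
                cur_names.append(iv.name)
        else:
            if cur is not None:
                out.append(_finish_merged(cur, cur_names, track_sources))
            cur = iv
            cur_names = [iv.name] if iv.name is not None else []
    if cur is not None:
        out.append(_finish_merged(cur, cur_names, track_sources))
    return out


def _finish_merged(
    iv: GenomicInterval, names: list[str], track_sources: bool
) -> GenomicInterval:
    if track_sources:
        return replace(iv, name=",".join(names) if names else None, score=None, strand=None)
    return GenomicInterval(iv.chrom, iv.start, iv.end)


def subtract(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Portions of ``a`` intervals not covered by any ``b`` interval.

    Annotations of each ``a`` interval are kept on its surviving pieces.
    """
    b_merged = merge_intervals(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b_merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in a:
        cursor = iv.start
        for block in by_chrom.get(iv.chrom, []):
            if block.end <= cursor:
                continue
            if block.start >= iv.end:
                break
            if block.start > cursor:
                out.append(replace(iv, start=cursor, end=block.start))
            cursor = max(cursor, block.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(replace(iv, start=cursor, end=iv.end))
    return out


def derive_promoters(
    tss: FeatureSet,
    window_bp: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Promoter windows upstream of each TSS (2 kb by default).

    For a + strand TSS at position p the window is ``[p - window_bp, p)``;
    for a − strand TSS it is ``[p, p + window_bp)``. Windows are clipped at
    position 0 and, when ``chrom_sizes`` is given, at chromosome ends.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if tss.category is not FeatureCategory.tss:
        raise ValueError("derive_promoters requires a tss FeatureSet")
    out: list[GenomicInterval] = []
    for iv in tss.intervals:
        p = iv.start
        if iv.strand == "+":
            start, end = max(0, p - window_bp), p
        else:
            start, end = p, p + window_bp
        if chrom_sizes is not None and iv.chrom in chrom_sizes:
            end = min(end, chrom_sizes[iv.chrom])
        if start < end:
            out.append(GenomicInterval(iv.chrom, start, end, name=iv.name, strand=iv.strand))
    return sorted(out, key=GenomicInterval.sort_key)


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered, counting each base once."""
    return sum(len(iv) for iv in merge_intervals(intervals))


class IntervalIndex:
    """Per-chromosome sorted index answering overlap queries.

    Built once over a static interval set; used on the hot paths
    (feature exclusion, peak overlap, site labelling).
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[GenomicInterval]]] = {}
        grouped: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            grouped.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in grouped.items():
            ivs.sort(key=GenomicInterval.sort_key)
            starts = [iv.start for iv in ivs]
            maxend: list[int] = []
            running = 0
            for iv in ivs:
                running = max(running, iv.end)
                maxend.append(running)
            self._by_chrom[chrom] = (starts, maxend, ivs)

    def overlapping(
        self, query: GenomicInterval, min_bp: int = 1
    ) -> list[GenomicInterval]:
        """All indexed intervals sharing >= min_bp bases with ``query``."""
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return []
        starts, maxend, ivs = entry
        hi = bisect.bisect_left(starts, query.end)
        out = []
        for i in range(hi - 1, -1, -1):
            if maxend[i] <= query.start:
                break
            iv = ivs[i]
            if min(iv.end, query.end) - max(iv.start, query.start) >= min_bp:
                out.append(iv)
        out.reverse()
        return out

    def any_overlap(self, query: GenomicInterval, min_bp: int = 1) -> bool:
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return False
        starts, maxend, ivs = entry
        hi = bisect.bisect_left(starts, query.end)
        for i in range(hi - 1, -1, -1):
            if maxend[i] <= query.start:
                return False
            iv = ivs[i]
            if min(iv.end, query.end) - max(iv.start, query.start) >= min_bp:
                return True
        return False
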