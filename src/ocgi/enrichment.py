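"""oCGI x peak overlap quantification and the genomic shuffle null.

The headline question — do oCGIs sit in enhancer-associated histone
modification peaks more often than chance — is answered by a
length- and chromosome-preserving reshuffle of the oCGI set: each round
redistributes every oCGI uniformly on its own chromosome, avoiding
annotated/excluded regions and other placed intervals, re-applies the
cross-species (human-intermediate) filter, and records the fraction of
the surviving shuffled set that overlaps a peak. The observed fraction
is compared with the distribution over rounds.

Also here: RPKM signal normalization, conservation summaries against
constrained-element (phastCons-style) intervals with LOD scores, and
sequence-age assignment from an age segmentation map.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np

from .caller import CgiCall
from .filtering import cross_species_filter
from .intervals import GenomicInterval, IntervalIndex, merge_intervals
from .orthology import CoordinateMap

__all__ = [
    "Peak",
    "ConservationSummary",
    "AgeCategory",
    "ShuffleResult",
    "overlap_fraction",
    "shuffle_intervals",
    "shuffle_test",
    "quantify_rpkm",
    "conservation_summary",
    "assign_age",
]


@dataclass(frozen=True)
class Peak:
    """A reproducible ChIP-seq peak with an RPKM-like signal level."""

    interval: GenomicInterval
    signal: float = 0.0
    mark: str = ""
    tissue: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("peak signal must be >= 0")


def _iv(x) -> GenomicInterval:
    """Accept CgiCall, Peak or bare GenomicInterval."""
    return x.interval if hasattr(x, "interval") else x


def overlap_fraction(ocgis: Sequence, peaks: Sequence) -> float:
    """Percent of oCGIs overlapping (>= 1 bp) at least one peak."""
    if len(ocgis) == 0:
        raise ValueError("overlap_fraction of an empty oCGI set is undefined")
    index = IntervalIndex(_iv(p) for p in peaks)
    hits = sum(1 for o in ocgis if index.any_overlap(_iv(o)))
    return 100.0 * hits / len(ocgis)


class _Placement:
    """Sorted blocked-region bookkeeping for one chromosome."""

    def __init__(self, excluded: Sequence[GenomicInterval]):
        self.starts = [iv.start for iv in excluded]
        self.ends = [iv.end for iv in excluded]

    def conflicts(self, start: int, end: int) -> bool:
        i = bisect.bisect_right(self.starts, start)
        if i > 0 and self.ends[i - 1] > start:
            return True
        return i < len(self.starts) and self.starts[i] < end

    def add(self, start: int, end: int) -> None:
        i = bisect.bisect_right(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)


def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    chrom_sizes: dict[str, int],
    excluded: Sequence[GenomicInterval],
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> list[GenomicInterval]:
    """One shuffle round: place each interval uniformly on its own
    chromosome, length-preserving, avoiding excluded regions and other
    placed intervals (bedtools shuffle -chrom -noOverlapping semantics).

    Raises RuntimeError naming the chromosome if an interval cannot be
    placed within ``max_attempts`` rejection-sampling draws.
    """
    excl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(excluded):
        excl_by_chrom.setdefault(iv.chrom, []).append(iv)
    placements = {
        chrom: _Placement(excl_by_chrom.get(chrom, [])) for chrom in chrom_sizes
    }
    out: list[GenomicInterval] = []
    for iv in intervals:
        size = chrom_sizes.get(iv.chrom)
        if size is None:
            raise ValueError(f"no chromosome size for {iv.chrom}")
        length = len(iv)
        if length > size:
            raise RuntimeError(f"interval longer than chromosome {iv.chrom}")
        placer = placements[iv.chrom]
        for _ in range(max_attempts):
            start = int(rng.integers(0, size - length + 1))
            if not placer.conflicts(start, start + length):
                placer.add(start, start + length)
                out.append(GenomicInterval(iv.chrom, start, start + length, name=iv.name))
                break
        else:
            raise RuntimeError(
                f"could not place a {length}-bp interval on {iv.chrom} after "
                f"{max_attempts} attempts"
            )
    return out


@dataclass
class ShuffleResult:
    """Observed vs shuffled overlap fractions (percent) and the p-value."""

    observed: float
    expected: float
    p_value: float
    rounds: int
    shuffled_fractions: np.ndarray

    def as_dict(self) -> dict:
        return {
            "observed": self.observed,
            "expected": self.expected,
            "p_value": self.p_value,
            "rounds": self.rounds,
        }


def shuffle_test(
    ocgis: Sequence,
    peaks: Sequence,
    chrom_sizes: dict[str, int],
    excluded: Sequence[GenomicInterval],
    map_to_human: CoordinateMap | None = None,
    human_exclude: Sequence | None = None,
    rounds: int = 20_000,
    seed: int | np.random.Generator | None = None,
    max_attempts: int = 10_000,
) -> ShuffleResult:
    """Genomic reshuffling test of oCGI/peak overlap.

    When ``map_to_human`` is given, every shuffled set is passed through
    the cross-species filter (lift to human, drop human-feature
    overlaps) before its overlap fraction is recorded, mirroring how the
    observed oCGI set was produced. The p-value is two-sided with an
    add-one pseudo-count, so it is never 0 and lies in (0, 1].
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = overlap_fraction(ocgis, peaks)
    peak_index = IntervalIndex(_iv(p) for p in peaks)
    intervals = [_iv(o) for o in ocgis]
    fractions = np.empty(rounds, dtype=float)
    for r in range(rounds):
        placed = shuffle_intervals(
            intervals, chrom_sizes, excluded, rng, max_attempts=max_attempts
        )
        if map_to_human is not None:
            calls = [
                CgiCall(iv, len(iv), 0.0, 0, 0.0) for iv in placed
            ]
            kept = cross_species_filter(calls, map_to_human, human_exclude or [])
            placed = [c.interval for c in kept]
        if placed:
            hits = sum(1 for iv in placed if peak_index.any_overlap(iv))
            fractions[r] = 100.0 * hits / len(placed)
        else:
            fractions[r] = 0.0
    expected = float(fractions.mean())
    dev = abs(observed - expected)
    p = (1 + int(np.sum(np.abs(fractions - expected) >= dev))) / (1 + rounds)
    return ShuffleResult(observed, expected, float(p), rounds, fractions)


def quantify_rpkm(peak: Peak, read_count_in_peak: int, library_size: int) -> float:
    """Reads per kilobase per million mapped reads for one peak."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if read_count_in_peak < 0:
        raise ValueError("read count must be >= 0")
    length_kb = len(peak.interval) / 1000.0
    return read_count_in_peak / (length_kb * library_size / 1e6)


@dataclass(frozen=True)
class ConservationSummary:
    """Constraint evidence overlapping one interval."""

    max_lod: float
    aggregate_lod: float
    covered_fraction: float

    def __post_init__(self) -> None:
        if not (0 <= self.covered_fraction <= 1):
            raise ValueError("covered_fraction must be in [0, 1]")


def conservation_summary(
    iv: GenomicInterval,
    elements: Sequence[tuple[GenomicInterval, float]],
) -> ConservationSummary:
    """Max LOD, summed LOD, and base coverage of constrained elements
    overlapping ``iv`` by >= 1 bp; (0, 0, 0) when nothing overlaps."""
    hits = []
    for el, lod in elements:
        if lod < 0:
            raise ValueError("LOD scores must be >= 0")
        if el.chrom == iv.chrom and min(el.end, iv.end) > max(el.start, iv.start):
            hits.append((el, lod))
    if not hits:
        return ConservationSummary(0.0, 0.0, 0.0)
    lods = [lod for _, lod in hits]
    clipped = [
        GenomicInterval(iv.chrom, max(el.start, iv.start), min(el.end, iv.end))
        for el, _ in hits
    ]
    covered = sum(len(x) for x in merge_intervals(clipped))
    return ConservationSummary(
        max(lods), float(sum(lods)), covered / len(iv)
    )


class AgeCategory(IntEnum):
    """Sequence-age categories, youngest to oldest; the three most
    ancient raw labels are collapsed into OlderThanAmniota. Unknown is
    incomparable (kept last for convenience only)."""

    Human = 0
    Ape = 1
    Primate = 2
    Eutheria = 3
    Theria = 4
    Mammalia = 5
    Amniota = 6
    OlderThanAmniota = 7
    Unknown = 8


_RAW_AGE_ORDER = [
    "Human",
    "Ape",
    "Primate",
    "Eutheria",
    "Theria",
    "Mammalia",
    "Amniota",
    "Tetrapoda",
    "Gnathostomata",
    "Vertebrata",
]
_ANCIENT = {"Tetrapoda", "Gnathostomata", "Vertebrata"}


def assign_age(
    iv: GenomicInterval,
    age_map: Sequence[tuple[GenomicInterval, str]],
    species_clade_members: set[str] | None = None,
) -> AgeCategory:
    """Date an interval (human coordinates) with an age segmentation map.

    The age is the most ancient raw label among overlapping segments;
    Tetrapoda/Gnathostomata/Vertebrata collapse to OlderThanAmniota.
    Because the map is human-based, an age naming a clade that does not
    contain the analysed species is meaningless for it and becomes
    Unknown (e.g. a pig interval dated "Human"); pass the set of raw
    ages valid for the species as ``species_clade_members``. No overlap
    also gives Unknown.
    """
    oldest: str | None = None
    for seg, raw in age_map:
        if raw not in _RAW_AGE_ORDER and raw != "Unknown":
            raise ValueError(f"unknown raw age label {raw!r}")
        if seg.chrom == iv.chrom and min(seg.end, iv.end) > max(seg.start, iv.start):
            if raw == "Unknown":
                continue
            if oldest is None or _RAW_AGE_ORDER.index(raw) > _RAW_AGE_ORDER.index(oldest):
                oldest = raw
    if oldest is None:
        return AgeCategory.Unknown
    if oldest in _ANCIENT:
        return AgeCategory.OlderThanAmniota
    if species_clade_members is not None and oldest not in species_clade_members:
        return AgeCategory.Unknown
    return AgeCategory[oldest]
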