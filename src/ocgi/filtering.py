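"""Reduction of raw CGI calls to orphan CGIs (oCGIs).

An orphan CGI is a CGI away from annotated gene-associated features:
anything overlapping an exon, a promoter window (2 kb upstream of a
TSS), a blacklist region, or an annotated CAGE promoter is removed, by
a single base of overlap. A second, cross-species filter then requires
the surviving oCGIs to have orthologous sequence in the human genome
that is itself free of the human versions of those features, so that
every species' oCGI set has been vetted against the best-annotated
genome.

Which categories are excluded is data-driven: every FeatureSet supplied
is applied, so species-asymmetric schemes (e.g. blacklist and CAGE
promoters available only for human and mouse) are configuration, not
code.
"""

from __future__ import annotations

from typing import Sequence

from .caller import CgiCall
from .intervals import (
    FeatureCategory,
    FeatureSet,
    GenomicInterval,
    IntervalIndex,
    derive_promoters,
)
from .orthology import CoordinateMap, map_interval

__all__ = ["exclusion_intervals", "filter_orphan", "cross_species_filter"]


def exclusion_intervals(
    features: Sequence[FeatureSet],
    promoter_window_bp: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Expand feature sets into the flat list of excluded intervals.

    TSS sets become strand-aware promoter windows; every other category
    is excluded as-is.
    """
    out: list[GenomicInterval] = []
    for fs in features:
        if fs.category is FeatureCategory.tss:
            out.extend(
                derive_promoters(fs, window_bp=promoter_window_bp, chrom_sizes=chrom_sizes)
            )
        else:
            out.extend(fs.intervals)
    return out


def filter_orphan(
    cgis: Sequence[CgiCall],
    features: Sequence[FeatureSet],
    promoter_window_bp: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[CgiCall]:
    """Keep CGIs with no overlap (>= 1 bp) with any excluded feature.

    Survivors keep their order and statistics unchanged.
    """
    index = IntervalIndex(
        exclusion_intervals(features, promoter_window_bp, chrom_sizes)
    )
    return [c for c in cgis if not index.any_overlap(c.interval)]


def cross_species_filter(
    ocgis: Sequence[CgiCall],
    map_to_human: CoordinateMap,
    human_features: Sequence[FeatureSet],
    promoter_window_bp: int = 2000,
) -> list[CgiCall]:
    """Apply the human-intermediate filter to a species' oCGI set.

    Removes oCGIs without orthologous human sequence (the lift must
    satisfy the map's min_match fraction) and oCGIs whose human
    ortholog overlaps any human exclusion feature. Survivors keep their
    source-genome coordinates.
    """
    index = IntervalIndex(
        exclusion_intervals(human_features, promoter_window_bp)
    )
    out: list[CgiCall] = []
    for call in ocgis:
        lifted = map_interval(call.interval, map_to_human)
        if lifted is None:
            continue
        if index.any_overlap(lifted):
            continue
        out.append(call)
    return out
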