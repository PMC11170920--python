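"""Cross-species orthology of oCGI sites via a liftover surrogate.

A :class:`CoordinateMap` is a monotone piecewise mapping between two
genomes given as paired aligned blocks of equal length — the same
information a liftOver chain provides, in a plain-text form. Orthologous
oCGI sites for a species pair are built through a human intermediate:
both species' oCGIs are projected to human coordinates, overlapping
projections are merged into anchors, and a site is kept only when the
anchor has orthologous sequence in *both* species, regardless of whether
the oCGI was called in both. Sites are then labelled A-only, B-only or
shared, and three-species presence/absence patterns can be polarized
into gains and losses on the focal branch using an outgroup.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .caller import CgiCall, cgi_stats
from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "CoordinateMap",
    "OrthologousSite",
    "PresencePattern",
    "map_interval",
    "build_orthologous_sites",
    "apply_min_oe_delta",
    "polarize_gain_loss",
    "presence_patterns",
]


@dataclass
class CoordinateMap:
    """Monotone piecewise mapping between two genomes.

    ``blocks`` are (source interval, target interval) pairs of equal
    length; within a chromosome they must be non-overlapping and
    order-preserving on both genomes. Anything between blocks is an
    explicit unmapped gap. ``min_match`` is the fraction of a query's
    bases that must fall in aligned blocks for it to lift (the liftOver
    minMatch parameter; 0.8 by default).
    """

    blocks: list[tuple[GenomicInterval, GenomicInterval]]
    min_match: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.min_match <= 1):
            raise ValueError("min_match must be in (0, 1]")
        for src, tgt in self.blocks:
            if len(src) != len(tgt):
                raise ValueError(f"block length mismatch: {src} vs {tgt}")
        self.blocks = sorted(self.blocks, key=lambda p: p[0].sort_key())
        self._by_chrom: dict[str, tuple[list[int], list[tuple[GenomicInterval, GenomicInterval]]]] = {}
        for pair in self.blocks:
            self._by_chrom.setdefault(pair[0].chrom, ([], []))
        for pair in self.blocks:
            starts, pairs = self._by_chrom[pair[0].chrom]
            if pairs and pair[0].start < pairs[-1][0].end:
                raise ValueError(f"overlapping source blocks near {pair[0]}")
            starts.append(pair[0].start)
            pairs.append(pair)

    def invert(self) -> "CoordinateMap":
        """The reverse mapping (blocks are symmetric)."""
        return CoordinateMap(
            [(tgt, src) for src, tgt in self.blocks], min_match=self.min_match
        )

    @classmethod
    def identity(cls, chrom_sizes: dict[str, int], min_match: float = 0.8) -> "CoordinateMap":
        blocks = [
            (GenomicInterval(c, 0, n), GenomicInterval(c, 0, n))
            for c, n in chrom_sizes.items()
        ]
        return cls(blocks, min_match=min_match)

    @classmethod
    def read_tsv(cls, path: str | Path, min_match: float = 0.8) -> "CoordinateMap":
        """Read paired blocks from a 6-column TSV
        (srcChrom srcStart srcEnd tgtChrom tgtStart tgtEnd)."""
        blocks = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 6:
                    raise ValueError(f"{path}:{lineno}: expected 6 columns")
                blocks.append(
                    (
                        GenomicInterval(f[0], int(f[1]), int(f[2])),
                        GenomicInterval(f[3], int(f[4]), int(f[5])),
                    )
                )
        return cls(blocks, min_match=min_match)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for src, tgt in self.blocks:
                fh.write(
                    f"{src.chrom}\t{src.start}\t{src.end}\t"
                    f"{tgt.chrom}\t{tgt.start}\t{tgt.end}\n"
                )

    def _overlapping_blocks(
        self, iv: GenomicInterval
    ) -> list[tuple[GenomicInterval, GenomicInterval]]:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return []
        starts, pairs = entry
        idx = bisect.bisect_left(starts, iv.end)
        out = []
        # blocks are non-overlapping, so scan left until one ends before iv
        for k in range(idx - 1, -1, -1):
            src = pairs[k][0]
            if src.end <= iv.start:
                break
            out.append(pairs[k])
        out.reverse()
        return out


def map_interval(
    iv: GenomicInterval, cmap: CoordinateMap
) -> GenomicInterval | None:
    """Lift an interval through a coordinate map.

    Returns the target-genome span from the mapped position of the
    query's first mappable base to that of its last, provided at least
    ``min_match`` of its bases lie in aligned blocks and all mapped
    blocks land co-linearly on one target chromosome. Otherwise returns
    None (unmapped is a value, not an error).
    """
    hits = cmap._overlapping_blocks(iv)
    if not hits:
        return None
    mapped = 0
    tgt_chrom = hits[0][1].chrom
    prev_tgt_end: int | None = None
    first_tgt: int | None = None
    last_tgt: int | None = None
    for src, tgt in hits:
        lo, hi = max(src.start, iv.start), min(src.end, iv.end)
        mapped += hi - lo
        if tgt.chrom != tgt_chrom:
            return None
        t_lo = tgt.start + (lo - src.start)
        t_hi = tgt.start + (hi - src.start)
        if prev_tgt_end is not None and t_lo < prev_tgt_end:
            return None  # not co-linear
        prev_tgt_end = t_hi
        if first_tgt is None:
            first_tgt = t_lo
        last_tgt = t_hi
    if mapped < cmap.min_match * len(iv):
        return None
    assert first_tgt is not None and last_tgt is not None
    return GenomicInterval(tgt_chrom, first_tgt, last_tgt, name=iv.name)


@dataclass
class OrthologousSite:
    """One orthologous locus of a species pair, anchored in human.

    ``present_X`` records whether an oCGI was called there in species X;
    ``oe_X`` is that oCGI's observed/expected CpG ratio when present,
    else the ratio recomputed on the orthologous species-X sequence when
    sequence was supplied (0.0 otherwise).
    """

    human_anchor: GenomicInterval
    interval_A: GenomicInterval | None
    interval_B: GenomicInterval | None
    present_A: bool
    present_B: bool
    oe_A: float = 0.0
    oe_B: float = 0.0

    def __post_init__(self) -> None:
        if not (self.present_A or self.present_B):
            raise ValueError("a site requires an oCGI in at least one species")

    @property
    def label(self) -> str:
        if self.present_A and self.present_B:
            return "shared"
        return "A_only" if self.present_A else "B_only"


def build_orthologous_sites(
    ocgis_A: Sequence[CgiCall],
    ocgis_B: Sequence[CgiCall],
    map_A_to_human: CoordinateMap,
    map_B_to_human: CoordinateMap,
    map_human_to_A: CoordinateMap | None = None,
    map_human_to_B: CoordinateMap | None = None,
    seqs_A: dict[str, str] | None = None,
    seqs_B: dict[str, str] | None = None,
) -> list[OrthologousSite]:
    """Pairwise orthologous oCGI sites through the human intermediate.

    Both species' oCGIs are lifted to human; overlapping or book-ended
    projections merge into one anchor; a site is emitted only when the
    anchor lifts back to both species (the underlying sequence must be
    present in both even if the oCGI was called in only one).
    """
    if map_human_to_A is None:
        map_human_to_A = map_A_to_human.invert()
    if map_human_to_B is None:
        map_human_to_B = map_B_to_human.invert()

    projections: list[GenomicInterval] = []
    for tag, ocgis, cmap in (("A", ocgis_A, map_A_to_human), ("B", ocgis_B, map_B_to_human)):
        for idx, call in enumerate(ocgis):
            lifted = map_interval(call.interval, cmap)
            if lifted is not None:
                projections.append(replace(lifted, name=f"{tag}:{idx}"))
    anchors = merge_intervals(projections, track_sources=True)

    sites: list[OrthologousSite] = []
    for anchor in anchors:
        back_A = map_interval(anchor, map_human_to_A)
        back_B = map_interval(anchor, map_human_to_B)
        if back_A is None or back_B is None:
            continue  # sequence must exist in both species
        src_A = [int(s.split(":")[1]) for s in (anchor.name or "").split(",") if s.startswith("A:")]
        src_B = [int(s.split(":")[1]) for s in (anchor.name or "").split(",") if s.startswith("B:")]
        present_A, present_B = bool(src_A), bool(src_B)
        if present_A:
            call = max((ocgis_A[k] for k in src_A), key=lambda c: c.obs_exp_ratio)
            interval_A, oe_A = call.interval, call.obs_exp_ratio
        else:
            interval_A, oe_A = replace(back_A, name=None), _seq_oe(back_A, seqs_A)
        if present_B:
            call = max((ocgis_B[k] for k in src_B), key=lambda c: c.obs_exp_ratio)
            interval_B, oe_B = call.interval, call.obs_exp_ratio
        else:
            interval_B, oe_B = replace(back_B, name=None), _seq_oe(back_B, seqs_B)
        sites.append(
            OrthologousSite(
                human_anchor=replace(anchor, name=None),
                interval_A=interval_A,
                interval_B=interval_B,
                present_A=present_A,
                present_B=present_B,
                oe_A=oe_A,
                oe_B=oe_B,
            )
        )
    return sites


def _seq_oe(iv: GenomicInterval, seqs: dict[str, str] | None) -> float:
    """O/E recomputed on orthologous sequence; 0.0 when no sequence given."""
    if seqs is None or iv.chrom not in seqs:
        return 0.0
    seq = seqs[iv.chrom]
    if iv.end > len(seq):
        return 0.0
    _, _, oe = cgi_stats(seq, iv)
    return oe


def apply_min_oe_delta(
    sites: Sequence[OrthologousSite], delta: float
) -> list[OrthologousSite]:
    """Drop species-specific sites whose O/E difference is below ``delta``.

    A minimal difference requirement on |oe_A - oe_B| guards the
    species-specific calls against threshold-straddling artifacts
    (an island at O/E 0.61 in one species and 0.59 in the other is not
    convincing turnover). Shared sites are unaffected; delta = 0 is the
    identity.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    out = []
    for s in sites:
        if s.label != "shared" and abs(s.oe_A - s.oe_B) < delta:
            continue
        out.append(s)
    return out


@dataclass(frozen=True)
class PresencePattern:
    """oCGI presence/absence across an ordered list of species."""

    species: tuple[str, ...]
    present: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.species) != len(self.present):
            raise ValueError("species and present must align")
        if not any(self.present):
            raise ValueError("a pattern requires presence in >= 1 species")

    def is_present(self, sp: str) -> bool:
        try:
            return self.present[self.species.index(sp)]
        except ValueError as exc:
            raise ValueError(f"species {sp!r} not in pattern") from exc


def polarize_gain_loss(
    patterns: Iterable[PresencePattern],
    focal: str,
    sister: str,
    outgroup: str,
) -> dict[str, int]:
    """Count gains and losses on the focal branch.

    A gain requires presence in the focal species and absence in both
    the sister species and the outgroup; a loss is the mirror image.
    All other patterns are unpolarized.
    """
    counts = {"gain": 0, "loss": 0, "unpolarized": 0}
    for pat in patterns:
        f, s, o = (pat.is_present(x) for x in (focal, sister, outgroup))
        if f and not s and not o:
            counts["gain"] += 1
        elif not f and s and o:
            counts["loss"] += 1
        else:
            counts["unpolarized"] += 1
    return counts


def presence_patterns(
    ocgis_by_species: dict[str, Sequence[CgiCall]],
    maps_to_human: dict[str, CoordinateMap],
) -> list[PresencePattern]:
    """Merge all species' oCGIs in human coordinates into presence patterns.

    Each species' oCGIs are lifted to human (name = species of origin)
    and pooled with a source-tracking merge; each merged site yields one
    presence/absence pattern over the species list.
    """
    species = tuple(ocgis_by_species.keys())
    pooled: list[GenomicInterval] = []
    for sp in species:
        cmap = maps_to_human[sp]
        for call in ocgis_by_species[sp]:
            lifted = map_interval(call.interval, cmap)
            if lifted is not None:
                pooled.append(replace(lifted, name=sp))
    merged = merge_intervals(pooled, track_sources=True)
    out = []
    for site in merged:
        sources = set((site.name or "").split(","))
        out.append(
            PresencePattern(species, tuple(sp in sources for sp in species))
        )
    return out


def sites_to_table(sites: Sequence[OrthologousSite]):
    """Orthologous sites as a pandas DataFrame (one row per site)."""
    import pandas as pd

    def _cols(iv: GenomicInterval | None):
        return (iv.chrom, iv.start, iv.end) if iv is not None else (".", -1, -1)

    rows = []
    for s in sites:
        rows.append(
            (*_cols(s.human_anchor), *_cols(s.interval_A), *_cols(s.interval_B),
             int(s.present_A), int(s.present_B), s.oe_A, s.oe_B, s.label)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "anchor_chrom", "anchor_start", "anchor_end",
            "chrom_A", "start_A", "end_A",
            "chrom_B", "start_B", "end_B",
            "present_A", "present_B", "oe_A", "oe_B", "label",
        ],
    )


def sites_from_table(df) -> list[OrthologousSite]:
    out = []
    for r in df.itertuples():
        iv_A = (
            GenomicInterval(r.chrom_A, int(r.start_A), int(r.end_A))
            if r.chrom_A != "." else None
        )
        iv_B = (
            GenomicInterval(r.chrom_B, int(r.start_B), int(r.end_B))
            if r.chrom_B != "." else None
        )
        out.append(
            OrthologousSite(
                human_anchor=GenomicInterval(r.anchor_chrom, int(r.anchor_start), int(r.anchor_end)),
                interval_A=iv_A,
                interval_B=iv_B,
                present_A=bool(r.present_A),
                present_B=bool(r.present_B),
                oe_A=float(r.oe_A),
                oe_B=float(r.oe_B),
            )
        )
    return out
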