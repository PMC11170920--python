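"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be simulated here: two- or
three-species genomes with planted CpG islands of controlled GC and
observed/expected CpG ratio on a CpG-depleted background, indel-bearing
coordinate maps between species, ChIP-seq-like peaks whose species
specificity is coupled to oCGI specificity at a chosen enrichment,
signal levels boosted at oCGI-containing peaks, enhancer sets with a
planted excess of a presence pattern, and negative-binomial expression
counts with a planted log2 fold effect. All planted truth is returned
(and written as sidecar files by the pipeline) so statistical stages
have parameter-recovery tests that never re-derive truth from the data.

Generators are pure functions of their spec: the same
:class:`SyntheticSpec` always produces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .expression import Gene
from .hge import TRIPLE_PATTERNS, Enhancer
from .intervals import GenomicInterval
from .orthology import CoordinateMap
from .enrichment import Peak

__all__ = [
    "SyntheticSpec",
    "make_genome",
    "make_species_pair",
    "make_peaks_and_signal",
    "make_expression",
    "make_enhancers",
    "make_gene_layout",
    "SpeciesPairData",
    "PeakData",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(c) for c in "ACGT")


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of the synthetic study, with the study's conditions as
    defaults. Fractions are (shared, A_only, B_only) and must sum to 1."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length_bp: int = 500_000
    background_gc: float = 0.40
    cpg_depletion: float = 0.25  # background CpG frequency vs. independence
    n_islands: int = 100
    island_length_bp: int = 400
    island_gc: float = 0.60
    island_oe_target: float = 1.0
    masked_block_bp: int = 2_000
    n_masked_blocks_per_chrom: int = 2
    # species pair
    turnover_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    indel_rate_per_kb: float = 0.05
    indel_max_bp: int = 50
    # peaks
    peak_coupling_odds: float = 1.0
    peak_base_probs: tuple[float, float, float, float] = (0.1, 0.1, 0.3, 0.5)
    peak_extension_bp: int = 200
    n_background_peaks: int = 100
    signal_boost_at_ocgi: float = 1.0
    library_size: int = 20_000_000
    # expression
    n_genes: int = 200
    n_set_genes: int = 30
    expression_log2_effect: float = 0.0
    nb_dispersion: float = 0.05
    n_expression_replicates: int = 4
    # enhancers / HGEs
    n_hges: int = 300
    n_background_enhancers: int = 3_000
    hge_pattern_multiplier: float = 1.0
    hge_signal_shift: float = 0.5

    def __post_init__(self) -> None:
        if abs(sum(self.turnover_fractions) - 1.0) > 1e-9:
            raise ValueError("turnover_fractions must sum to 1")
        if any(f < 0 for f in self.turnover_fractions):
            raise ValueError("turnover_fractions must be non-negative")
        if abs(sum(self.peak_base_probs) - 1.0) > 1e-9:
            raise ValueError("peak_base_probs must sum to 1")
        if self.peak_coupling_odds < 1:
            raise ValueError("peak_coupling_odds must be >= 1")
        if not (0 < self.background_gc < 1 and 0 < self.island_gc < 1):
            raise ValueError("GC fractions must be in (0, 1)")
        if self.island_oe_target > 2.0 / self.island_gc**2:
            raise ValueError(
                "island_oe_target exceeds what the island GC content permits"
            )
        for name in ("cpg_depletion", "indel_rate_per_kb", "signal_boost_at_ocgi",
                     "nb_dispersion", "hge_pattern_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# sequence synthesis helpers


def _iid_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _cpg_positions(arr: np.ndarray) -> np.ndarray:
    return np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))


def _thin_cpgs(arr: np.ndarray, keep_prob: float, rng: np.random.Generator) -> None:
    """Destroy CpGs in place (G -> A/T) until only ~keep_prob remain,
    emulating the genome-wide CpG depletion caused by deamination."""
    pos = _cpg_positions(arr)
    kill = pos[rng.random(pos.size) > keep_prob]
    arr[kill + 1] = np.where(rng.random(kill.size) < 0.5, _A, _T)


def _tune_island_oe(
    arr: np.ndarray, oe_target: float, rng: np.random.Generator, iters: int = 4
) -> None:
    """Adjust an island's CpG count in place toward the target O/E.

    Surplus CpGs are destroyed by swapping CG -> GC (composition
    preserved); deficits are filled by overwriting dinucleotides with
    CG at positions that create exactly one new CpG.
    """
    for _ in range(iters):
        n_c = int((arr == _C).sum())
        n_g = int((arr == _G).sum())
        if n_c * n_g == 0:
            return
        desired = int(round(oe_target * n_c * n_g / arr.size))
        pos = _cpg_positions(arr)
        diff = pos.size - desired
        if diff == 0:
            return
        if diff > 0:
            # swap CG->GC where no new CpG appears (left neighbour not C,
            # right neighbour not G)
            ok = pos[
                ((pos == 0) | (arr[np.maximum(pos - 1, 0)] != _C))
                & ((pos + 2 >= arr.size) | (arr[np.minimum(pos + 2, arr.size - 1)] != _G))
            ]
            take = ok[rng.permutation(ok.size)[: min(diff, ok.size)]]
            arr[take], arr[take + 1] = _G, _C
        else:
            cand = rng.permutation(arr.size - 2)
            planted = 0
            is_cpg = np.zeros(arr.size, dtype=bool)
            p = _cpg_positions(arr)
            is_cpg[p] = True
            for i in cand:
                if planted >= -diff:
                    break
                # avoid touching an existing CpG or creating a second one
                if is_cpg[i] or (i > 0 and is_cpg[i - 1]) or is_cpg[i + 1]:
                    continue
                if i > 0 and arr[i - 1] == _C:
                    continue
                if i + 2 < arr.size and arr[i + 2] == _G:
                    continue
                arr[i], arr[i + 1] = _C, _G
                is_cpg[i] = True
                planted += 1


def _degrade_island(arr: np.ndarray, rng: np.random.Generator) -> None:
    """CpG -> TpG transitions in place: the deamination path that erodes
    islands while keeping the sequence alignable."""
    pos = _cpg_positions(arr)
    arr[pos] = _T


# ---------------------------------------------------------------------------
# genome


def make_genome(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GenomicInterval], list[GenomicInterval]]:
    """Synthesize a genome with planted islands.

    Returns (sequences, planted island intervals, masked intervals).
    Background sequence has the spec's GC with CpGs depleted to
    ``cpg_depletion`` of the independence expectation; islands are tuned
    to the target GC/O/E within +-0.05; masked blocks are lowercased.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n_per_chrom = _split_count(spec.n_islands, spec.n_chroms)
    sequences: dict[str, str] = {}
    islands: list[GenomicInterval] = []
    masked: list[GenomicInterval] = []
    margin = 500
    for ci in range(spec.n_chroms):
        chrom = f"chr{ci + 1}"
        arr = _iid_sequence(spec.chrom_length_bp, spec.background_gc, rng)
        _thin_cpgs(arr, spec.cpg_depletion, rng)
        starts = _place_nonoverlapping(
            n_per_chrom[ci], spec.island_length_bp, spec.chrom_length_bp, margin, rng
        )
        for k, s in enumerate(starts):
            isl = _iid_sequence(spec.island_length_bp, spec.island_gc, rng)
            _tune_island_oe(isl, spec.island_oe_target, rng)
            arr[s : s + spec.island_length_bp] = isl
            islands.append(
                GenomicInterval(
                    chrom, s, s + spec.island_length_bp, name=f"island_{chrom}_{k}"
                )
            )
        seq = arr.tobytes().decode("ascii")
        # lowercase masked blocks in island-free background
        taken = [(iv.start - margin, iv.end + margin) for iv in islands if iv.chrom == chrom]
        placed_masks = 0
        attempts = 0
        while placed_masks < spec.n_masked_blocks_per_chrom and attempts < 1000:
            attempts += 1
            s = int(rng.integers(0, spec.chrom_length_bp - spec.masked_block_bp))
            e = s + spec.masked_block_bp
            if any(s < hi and e > lo for lo, hi in taken):
                continue
            seq = seq[:s] + seq[s:e].lower() + seq[e:]
            masked.append(GenomicInterval(chrom, s, e, name="mask"))
            taken.append((s, e))
            placed_masks += 1
        sequences[chrom] = seq
    return sequences, islands, masked


def _split_count(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def _place_nonoverlapping(
    n: int, length: int, chrom_len: int, margin: int, rng: np.random.Generator
) -> list[int]:
    """Random non-overlapping placements with a margin between them."""
    starts: list[int] = []
    attempts = 0
    while len(starts) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise RuntimeError("could not place islands; chromosome too crowded")
        s = int(rng.integers(margin, chrom_len - length - margin))
        if all(abs(s - t) >= length + margin for t in starts):
            starts.append(s)
    starts.sort()
    return starts


# ---------------------------------------------------------------------------
# species pair


@dataclass
class SpeciesPairData:
    """A simulated species pair with its human-anchor coordinate system."""

    human: dict[str, str]
    seq_A: dict[str, str]
    seq_B: dict[str, str]
    map_A_to_human: CoordinateMap
    map_B_to_human: CoordinateMap
    islands_human: list[GenomicInterval]
    labels: list[str]  # per island: shared / A_only / B_only
    islands_A: list[GenomicInterval | None]
    islands_B: list[GenomicInterval | None]
    masked_human: list[GenomicInterval]

    @property
    def chrom_sizes_human(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.human.items()}

    @property
    def chrom_sizes_A(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seq_A.items()}

    @property
    def chrom_sizes_B(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seq_B.items()}


def make_species_pair(spec: SyntheticSpec) -> SpeciesPairData:
    """Derive species A and B from a human anchor genome.

    Islands planted absent in a species are degraded there by CpG->TpG
    transitions (keeping the sequence alignable); indels applied in the
    background break the coordinate maps into aligned blocks.
    """
    rng = np.random.default_rng(spec.seed)
    human, islands, masked = make_genome(spec, rng)
    labels = [
        ("shared", "A_only", "B_only")[k]
        for k in rng.choice(3, size=len(islands), p=list(spec.turnover_fractions))
    ]
    seq_A, map_A = _derive_species(spec, human, islands, labels, absent_label="B_only", rng=rng)
    seq_B, map_B = _derive_species(spec, human, islands, labels, absent_label="A_only", rng=rng)
    from .orthology import map_interval

    inv_A, inv_B = map_A.invert(), map_B.invert()
    islands_A = [map_interval(iv, inv_A) for iv in islands]
    islands_B = [map_interval(iv, inv_B) for iv in islands]
    return SpeciesPairData(
        human=human,
        seq_A=seq_A,
        seq_B=seq_B,
        map_A_to_human=map_A,
        map_B_to_human=map_B,
        islands_human=islands,
        labels=labels,
        islands_A=islands_A,
        islands_B=islands_B,
        masked_human=masked,
    )


def _derive_species(
    spec: SyntheticSpec,
    human: dict[str, str],
    islands: Sequence[GenomicInterval],
    labels: Sequence[str],
    absent_label: str,
    rng: np.random.Generator,
) -> tuple[dict[str, str], CoordinateMap]:
    """One species genome + its map to human.

    ``absent_label`` names the island class degraded in this species.
    """
    seqs: dict[str, str] = {}
    blocks: list[tuple[GenomicInterval, GenomicInterval]] = []
    for chrom, seq in human.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        upper = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        for iv, lab in zip(islands, labels):
            if iv.chrom == chrom and lab == absent_label:
                sub = upper[iv.start : iv.end].copy()
                _degrade_island(sub, rng)
                arr[iv.start : iv.end] = sub
        # indel positions in island-free background, away from island edges
        n_indels = rng.poisson(spec.indel_rate_per_kb * len(seq) / 1000.0)
        forbidden = [
            (iv.start - 200, iv.end + 200) for iv in islands if iv.chrom == chrom
        ]
        positions: list[int] = []
        attempts = 0
        while len(positions) < n_indels and attempts < 50 * (n_indels + 1):
            attempts += 1
            p = int(rng.integers(1000, len(seq) - 1000))
            if any(lo <= p < hi for lo, hi in forbidden):
                continue
            if any(abs(p - q) < 2 * spec.indel_max_bp for q in positions):
                continue
            positions.append(p)
        positions.sort()
        out_parts: list[np.ndarray] = []
        sp_cursor = 0
        h_cursor = 0
        for p in positions:
            size = int(rng.integers(1, spec.indel_max_bp + 1))
            is_insertion = bool(rng.random() < 0.5)
            # aligned block up to the event
            seg = arr[h_cursor:p]
            if seg.size:
                blocks.append(
                    (
                        GenomicInterval(chrom, h_cursor, p),
                        GenomicInterval(chrom, sp_cursor, sp_cursor + seg.size),
                    )
                )
                out_parts.append(seg)
                sp_cursor += seg.size
            if is_insertion:
                ins = _iid_sequence(size, spec.background_gc, rng)
                out_parts.append(ins)
                sp_cursor += size
                h_cursor = p
            else:
                h_cursor = min(p + size, len(seq))
        seg = arr[h_cursor:]
        if seg.size:
            blocks.append(
                (
                    GenomicInterval(chrom, h_cursor, len(seq)),
                    GenomicInterval(chrom, sp_cursor, sp_cursor + seg.size),
                )
            )
            out_parts.append(seg)
        seqs[chrom] = np.concatenate(out_parts).tobytes().decode("ascii")
    species_to_human = CoordinateMap([(tgt, src) for src, tgt in blocks])
    return seqs, species_to_human


# ---------------------------------------------------------------------------
# peaks and signal


@dataclass
class PeakData:
    peaks_A: list[Peak]
    peaks_B: list[Peak]
    counts_A: list[int]
    counts_B: list[int]
    library_size: int
    site_peak_labels: list[str]  # per input site: A_only/B_only/shared/none


def _coupled_joint(spec: SyntheticSpec) -> np.ndarray:
    """Joint distribution over (oCGI label x peak label) with the planted
    coupling: conditional on a peak being present, the matching
    species-specific diagonal cells are enriched exactly
    ``peak_coupling_odds``-fold over the product of marginals, and the
    no-peak column is independent of the oCGI label.

    Rows: (A_only, B_only, shared); columns: (A_only, B_only, shared, none).
    """
    qA, qB, qS, qN = spec.peak_base_probs
    pS, pA, pB = spec.turnover_fractions
    w = spec.peak_coupling_odds
    rows = np.array([pA, pB, pS])
    if qN >= 1.0:  # no peaks at all: everything lands in the none column
        J = np.zeros((3, 4))
        J[:, 3] = rows
        return J
    kA, kB, kS = (q / (1 - qN) for q in (qA, qB, qS))
    K = np.zeros((3, 3))
    K[0, 0] = w * kA * pA
    K[1, 1] = w * kB * pB
    leftA = kA - K[0, 0]
    leftB = kB - K[1, 1]
    if leftA < 0 or leftB < 0 or K[0, 0] > pA or K[1, 1] > pB:
        raise ValueError("peak_coupling_odds too large for these probabilities")
    K[1, 0] = leftA * pB / (pB + pS)
    K[2, 0] = leftA * pS / (pB + pS)
    K[0, 1] = leftB * pA / (pA + pS)
    K[2, 1] = leftB * pS / (pA + pS)
    K[:, 2] = rows - K[:, 0] - K[:, 1]
    if (K < -1e-12).any():
        raise ValueError("peak_coupling_odds too large for these probabilities")
    K = np.clip(K, 0, None)
    J = np.zeros((3, 4))
    J[:, :3] = K * (1 - qN)
    J[:, 3] = qN * rows
    return J


def make_peaks_and_signal(
    spec: SyntheticSpec,
    sites: Sequence,
    chrom_sizes_A: Mapping[str, int],
    chrom_sizes_B: Mapping[str, int],
    rng: np.random.Generator | None = None,
    avoid_sites: bool = True,
) -> PeakData:
    """Place peaks at oCGI sites with the planted specificity coupling.

    ``sites`` need ``interval_A``, ``interval_B`` and ``label``
    attributes (planted truth or recovered OrthologousSites). Peaks at
    oCGI-containing locations get their signal multiplied by
    ``signal_boost_at_ocgi``; per-peak read counts are Poisson draws
    consistent with the signal as RPKM at the given library size.

    With ``avoid_sites`` (the default) background peaks stay clear of
    the oCGI sites so they cannot contaminate the planted specificity
    labels; pass False for overlap-null studies, where background peaks
    must be placed fully independently of the oCGIs.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    J = _coupled_joint(spec)
    row_mass = J.sum(axis=1, keepdims=True)
    cond = np.divide(J, row_mass, out=np.full_like(J, 0.25), where=row_mass > 0)
    row_of = {"A_only": 0, "B_only": 1, "shared": 2}
    col_names = ("A_only", "B_only", "shared", "none")

    peaks_A: list[Peak] = []
    peaks_B: list[Peak] = []
    counts_A: list[int] = []
    counts_B: list[int] = []
    site_labels: list[str] = []
    occupied_A: list[GenomicInterval] = []
    occupied_B: list[GenomicInterval] = []

    def _add_peak(iv: GenomicInterval, species: str, has_ocgi: bool) -> None:
        ext = int(rng.integers(50, spec.peak_extension_bp + 1))
        start = max(0, iv.start - ext)
        sizes = chrom_sizes_A if species == "A" else chrom_sizes_B
        end = min(sizes[iv.chrom], iv.end + ext)
        signal = float(rng.lognormal(np.log(3.0), 0.5))
        if has_ocgi:
            signal *= spec.signal_boost_at_ocgi
        peak = Peak(GenomicInterval(iv.chrom, start, end), signal=signal,
                    mark="H3K27ac", tissue="synthetic", species=species)
        lam = signal * ((end - start) / 1000.0) * (spec.library_size / 1e6)
        count = int(rng.poisson(lam))
        if species == "A":
            peaks_A.append(peak)
            counts_A.append(count)
            occupied_A.append(peak.interval)
        else:
            peaks_B.append(peak)
            counts_B.append(count)
            occupied_B.append(peak.interval)

    for site in sites:
        col = int(rng.choice(4, p=cond[row_of[site.label]]))
        name = col_names[col]
        site_labels.append(name)
        if name in ("A_only", "shared") and site.interval_A is not None:
            _add_peak(site.interval_A, "A", has_ocgi=site.label in ("A_only", "shared"))
        if name in ("B_only", "shared") and site.interval_B is not None:
            _add_peak(site.interval_B, "B", has_ocgi=site.label in ("B_only", "shared"))

    for species, sizes, occupied in (
        ("A", chrom_sizes_A, occupied_A),
        ("B", chrom_sizes_B, occupied_B),
    ):
        site_zones = [
            (getattr(s, "interval_A" if species == "A" else "interval_B"))
            for s in sites
        ]
        zones = [
            (iv.chrom, iv.start - spec.peak_extension_bp, iv.end + spec.peak_extension_bp)
            for iv in site_zones
            if iv is not None
        ]
        chroms = list(sizes)
        placed = 0
        attempts = 0
        length = spec.island_length_bp
        while placed < spec.n_background_peaks and attempts < 100 * spec.n_background_peaks:
            attempts += 1
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            s = int(rng.integers(0, sizes[chrom] - length))
            iv = GenomicInterval(chrom, s, s + length)
            if avoid_sites and any(
                c == iv.chrom and s < hi and iv.end > lo for c, lo, hi in zones
            ):
                continue
            if any(o.chrom == iv.chrom and iv.start < o.end and iv.end > o.start for o in occupied):
                continue
            _add_peak(GenomicInterval(chrom, s + 100, s + length - 100), species, has_ocgi=False)
            placed += 1
    return PeakData(peaks_A, peaks_B, counts_A, counts_B, spec.library_size, site_labels)


def make_labeled_sites(
    spec: SyntheticSpec, n_sites: int, rng: np.random.Generator | None = None
):
    """Draw (oCGI label, peak label) pairs directly from the coupled joint.

    The label-level shortcut for calibration studies that need many
    replicate datasets: the grid test consumes only labels, and this
    samples them from exactly the joint distribution the full genome
    simulation plants.
    """
    from .turnover import LabeledSite, OCGI_LABELS, PEAK_LABELS

    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    J = _coupled_joint(spec)
    flat = J.ravel()
    draws = rng.choice(flat.size, size=n_sites, p=flat / flat.sum())
    return [
        LabeledSite(OCGI_LABELS[d // 4], PEAK_LABELS[d % 4]) for d in draws
    ]


# ---------------------------------------------------------------------------
# expression


def make_gene_layout(
    spec: SyntheticSpec,
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, int, str]], dict[str, str], list[tuple[GenomicInterval, str]]]:
    """Lay genes out on the genome and plant qualifying turnover sites.

    Returns (gene placements as (id, chrom, tss, strand), the planted
    set assignment per gene, and the planted qualifying sites). Sites
    are planted inside the basal domain of their gene, so with spaced
    TSSs the GREAT assignment recovers the planted sets exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 2)
    chroms = list(chrom_sizes)
    per_chrom = _split_count(spec.n_genes, len(chroms))
    placements: list[tuple[str, str, int, str]] = []
    gi = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        spacing = (chrom_sizes[chrom] - 40_000) // n
        if spacing < 12_000:
            raise ValueError("chromosomes too short for this many genes")
        for k in range(n):
            tss = 20_000 + k * spacing + int(rng.integers(0, min(2000, spacing // 4)))
            strand = "+" if rng.random() < 0.5 else "-"
            placements.append((f"gene_{gi}", chrom, tss, strand))
            gi += 1
    ids = [p[0] for p in placements]
    chosen = rng.permutation(len(ids))[: 2 * spec.n_set_genes]
    truth = {g: "background_set" for g in ids}
    sites: list[tuple[GenomicInterval, str]] = []
    for j, idx in enumerate(chosen):
        gid, chrom, tss, strand = placements[idx]
        label = "A_only" if j < spec.n_set_genes else "B_only"
        truth[gid] = "A_only_set" if label == "A_only" else "B_only_set"
        lo = tss - 4_000 if strand == "+" else tss + 2_000
        sites.append((GenomicInterval(chrom, lo, lo + 300, name=f"site_{gid}"), label))
    return placements, truth, sites


def make_expression(
    spec: SyntheticSpec,
    gene_sets_truth: Mapping[str, str],
    placements: Sequence[tuple[str, str, int, str]] | None = None,
    rng: np.random.Generator | None = None,
) -> list[Gene]:
    """Negative-binomial expression counts with the planted log2 effect.

    Genes planted in the A-only set get a ``2**expression_log2_effect``
    mean boost in species A (mirrored for the B-only set). Per species,
    each gene's count is the sum over ``n_expression_replicates``
    negative-binomial draws (dispersion ``nb_dispersion``), emulating a
    replicated RNA-seq experiment pooled for TPM computation.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 3)
    ids = list(gene_sets_truth)
    if placements is None:
        placements = [
            (g, "chr1", 20_000 + 20_000 * i, "+") for i, g in enumerate(ids)
        ]
    place_by_id = {p[0]: p for p in placements}
    n_nb = 1.0 / spec.nb_dispersion
    effect = 2.0**spec.expression_log2_effect
    genes: list[Gene] = []
    for gid in ids:
        _, chrom, tss, strand = place_by_id[gid]
        base = float(rng.lognormal(np.log(200.0), 1.0))
        mean_A = base * (effect if gene_sets_truth[gid] == "A_only_set" else 1.0)
        mean_B = base * (effect if gene_sets_truth[gid] == "B_only_set" else 1.0)
        reps = spec.n_expression_replicates
        cA = int(rng.negative_binomial(n_nb, n_nb / (n_nb + mean_A), size=reps).sum())
        cB = int(rng.negative_binomial(n_nb, n_nb / (n_nb + mean_B), size=reps).sum())
        genes.append(
            Gene(
                id=gid,
                chrom=chrom,
                tss=tss,
                strand=strand,
                exon_length_bp=int(rng.integers(500, 5001)),
                counts_A=cA,
                counts_B=cB,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# enhancers / HGEs

_BASE_PATTERN_PROBS = np.array(
    [0.05, 0.03, 0.03, 0.04, 0.04, 0.03, 0.08, 0.70]
)  # order = TRIPLE_PATTERNS; none-heavy, as most enhancers lack an oCGI


def make_enhancers(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[list[Enhancer], list[Enhancer]]:
    """Synthetic HGE and non-HGE enhancer sets.

    HGEs draw their oCGI triple pattern with the human-only probability
    multiplied by ``hge_pattern_multiplier`` (renormalized) and their
    signal from a log-shifted distribution, so the signal-matched
    resampling is actually exercised.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 4)
    probs_bg = _BASE_PATTERN_PROBS
    probs_hge = probs_bg.copy()
    probs_hge[0] *= spec.hge_pattern_multiplier
    probs_hge = probs_hge / probs_hge.sum()

    def _draw(n: int, probs: np.ndarray, is_hge: bool, shift: float) -> list[Enhancer]:
        pats = rng.choice(8, size=n, p=probs)
        signals = rng.lognormal(np.log(5.0) + shift, 0.6, size=n)
        out = []
        for i in range(n):
            start = 1_000 + 2_000 * i
            out.append(
                Enhancer(
                    interval=GenomicInterval("chr1", start, start + 1_000),
                    signal=float(signals[i]),
                    is_hge=is_hge,
                    pattern=TRIPLE_PATTERNS[int(pats[i])],
                )
            )
        return out

    hges = _draw(spec.n_hges, probs_hge, True, spec.hge_signal_shift)
    background = _draw(spec.n_background_enhancers, probs_bg, False, 0.0)
    return hges, background
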