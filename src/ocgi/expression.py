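"""Linking species-specific oCGI/peak turnover to gene expression.

Genes are given regulatory domains by the GREAT rules: a strand-aware
basal domain (5 kb upstream, 1 kb downstream of the TSS) extended on
each side to the nearest neighbouring basal domain, up to 1 Mb from the
basal edge. Genes are then sorted by the qualifying turnover sites
(species-specific oCGIs inside same-species-specific peaks) falling in
their domains: the A-only set, the B-only set, the mixed set (excluded
from testing) and the background set. Expression change is measured as
the per-gene log2 TPM ratio between species, and each test set's median
ratio is compared against expression-matched resamples of the
background set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalIndex
from .turnover import bh_correct

__all__ = [
    "Gene",
    "RegulatoryDomain",
    "GENE_SETS",
    "compute_tpm",
    "great_domains",
    "assign_gene_sets",
    "ExpressionSetResult",
    "expression_ratio_test",
    "read_gene_table",
    "genes_to_table",
]

GENE_SETS = ("A_only_set", "B_only_set", "mixed_set", "background_set")

BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_EXTENSION = 1_000_000


@dataclass(frozen=True)
class Gene:
    """A 1:1-ortholog gene with per-species read counts."""

    id: str
    chrom: str
    tss: int
    strand: str
    exon_length_bp: int
    counts_A: int
    counts_B: int
    is_one_to_one_ortholog: bool = True

    def __post_init__(self) -> None:
        if self.exon_length_bp <= 0:
            raise ValueError(f"gene {self.id}: exon length must be positive")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -")
        if self.counts_A < 0 or self.counts_B < 0:
            raise ValueError(f"gene {self.id}: negative counts")


@dataclass(frozen=True)
class RegulatoryDomain:
    """Basal and extended regulatory domain of one gene."""

    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval

    def __post_init__(self) -> None:
        if not (
            self.extended.start <= self.basal.start
            and self.basal.end <= self.extended.end
        ):
            raise ValueError(f"{self.gene_id}: basal not inside extended domain")


def compute_tpm(genes: Sequence[Gene], species: str) -> dict[str, float]:
    """Transcripts per million from counts and exonic lengths.

    rate_g = counts_g / exon_length_kb_g; TPM_g = 1e6 * rate_g / sum(rates).
    """
    if species not in ("A", "B"):
        raise ValueError("species must be 'A' or 'B'")
    counts = np.array(
        [g.counts_A if species == "A" else g.counts_B for g in genes], dtype=float
    )
    lengths_kb = np.array([g.exon_length_bp for g in genes], dtype=float) / 1000.0
    rates = counts / lengths_kb
    total = rates.sum()
    if total == 0:
        raise ValueError("all counts are zero; TPM undefined")
    tpm = 1e6 * rates / total
    return {g.id: float(t) for g, t in zip(genes, tpm)}


def _basal(gene: Gene, chrom_size: int | None) -> GenomicInterval:
    if gene.strand == "+":
        start, end = gene.tss - BASAL_UPSTREAM, gene.tss + BASAL_DOWNSTREAM
    else:
        start, end = gene.tss - BASAL_DOWNSTREAM, gene.tss + BASAL_UPSTREAM
    start = max(0, start)
    if chrom_size is not None:
        end = min(end, chrom_size)
    return GenomicInterval(gene.chrom, start, end, name=gene.id)


def great_domains(
    genes: Sequence[Gene], chrom_sizes: Mapping[str, int] | None = None
) -> list[RegulatoryDomain]:
    """GREAT-rule regulatory domains.

    The basal domain is 5 kb upstream / 1 kb downstream of the TSS,
    strand-aware. Extension on each side runs to the boundary of the
    nearest other basal domain lying outside our own, capped at 1 Mb
    from the basal edge and clipped to the chromosome; a neighbouring
    basal domain overlapping ours blocks extension on that side
    entirely, but basal domains are never truncated.
    """
    sizes = dict(chrom_sizes) if chrom_sizes else {}
    basals = [_basal(g, sizes.get(g.chrom)) for g in genes]
    by_chrom: dict[str, list[int]] = {}
    for i, b in enumerate(basals):
        by_chrom.setdefault(b.chrom, []).append(i)

    out: list[RegulatoryDomain] = []
    for chrom, idxs in by_chrom.items():
        chrom_len = sizes.get(chrom)
        for i in idxs:
            b = basals[i]
            left_limit = max(0, b.start - MAX_EXTENSION)
            right_limit = b.end + MAX_EXTENSION
            if chrom_len is not None:
                right_limit = min(right_limit, chrom_len)
            for j in idxs:
                if j == i:
                    continue
                o = basals[j]
                if o.end <= b.start:
                    left_limit = max(left_limit, o.end)
                elif o.start >= b.end:
                    right_limit = min(right_limit, o.start)
                else:
                    # overlapping basal blocks extension on the sides it reaches
                    if o.start < b.start:
                        left_limit = b.start
                    if o.end > b.end:
                        right_limit = b.end
            extended = GenomicInterval(
                chrom, min(left_limit, b.start), max(right_limit, b.end), name=b.name
            )
            out.append(RegulatoryDomain(gene_id=b.name, basal=b, extended=extended))
    return out


def assign_gene_sets(
    domains: Sequence[RegulatoryDomain],
    qualifying_sites: Sequence[tuple[GenomicInterval, str]],
) -> dict[str, str]:
    """Sort genes into A-only / B-only / mixed / background sets.

    ``qualifying_sites`` must already be restricted to species-specific
    oCGIs inside same-species-specific peaks, as (interval, label) pairs
    with label "A_only" or "B_only"; all other oCGIs and peaks are
    ignored by construction. A gene joins the A-only set iff >= 1
    A-qualifying site falls in its extended domain and no B-qualifying
    site does (symmetrically for B); both kinds make it mixed (excluded
    from testing); neither, background.
    """
    for _, label in qualifying_sites:
        if label not in ("A_only", "B_only"):
            raise ValueError(f"qualifying site label must be A_only/B_only, got {label!r}")
    index_A = IntervalIndex(iv for iv, lab in qualifying_sites if lab == "A_only")
    index_B = IntervalIndex(iv for iv, lab in qualifying_sites if lab == "B_only")
    out: dict[str, str] = {}
    for dom in domains:
        has_A = index_A.any_overlap(dom.extended)
        has_B = index_B.any_overlap(dom.extended)
        if has_A and has_B:
            out[dom.gene_id] = "mixed_set"
        elif has_A:
            out[dom.gene_id] = "A_only_set"
        elif has_B:
            out[dom.gene_id] = "B_only_set"
        else:
            out[dom.gene_id] = "background_set"
    return out


@dataclass
class ExpressionSetResult:
    """Resampling comparison of one gene set against background."""

    set_label: str
    n_genes: int
    median_log2_ratio: float
    normalized_median: float
    p: float
    q: float | None
    underpowered: bool
    n_zero_dropped: int

    def as_dict(self) -> dict:
        return {
            "set": self.set_label,
            "n_genes": self.n_genes,
            "median_log2_ratio": self.median_log2_ratio,
            "normalized_median": self.normalized_median,
            "p": self.p,
            "q": self.q,
            "underpowered": self.underpowered,
            "n_zero_dropped": self.n_zero_dropped,
        }


def expression_ratio_test(
    assignments: Mapping[str, str],
    tpm_A: Mapping[str, float],
    tpm_B: Mapping[str, float],
    rounds: int = 10_000,
    n_bins: int = 10,
    seed: int | np.random.Generator | None = None,
    min_set_size: int = 5,
) -> dict[str, ExpressionSetResult]:
    """Expression-matched resampling test of log2 TPM ratios.

    For each gene r_g = log2(TPM_A / TPM_B); genes with zero TPM in
    either species are dropped (their count is reported). Each round
    draws from the background set, with replacement, a pseudo-set
    matching the test set's size and its composition over bins of mean
    log2 TPM, and records the median r. The observed test-set median is
    normalized by subtracting the median of the resampled medians; the
    p-value is a two-sided add-one tail probability; q is BH across the
    tested sets.
    """
    # Each test set gets its own generator seeded identically, so the
    # draws for a given set of genes depend only on that set's bin
    # composition; swapping species A<->B then negates every resampled
    # median exactly, making the sign symmetry of the test exact.
    if isinstance(seed, np.random.Generator):
        _set_rng = lambda: seed
    else:
        _base = 0 if seed is None else int(seed)
        _set_rng = lambda: np.random.default_rng(_base)
    gene_ids = [g for g in assignments if g in tpm_A and g in tpm_B]
    kept, dropped = [], 0
    for g in gene_ids:
        if tpm_A[g] <= 0 or tpm_B[g] <= 0:
            dropped += 1
        else:
            kept.append(g)
    if not kept:
        raise ValueError("no genes with nonzero TPM in both species")
    r = np.array([np.log2(tpm_A[g] / tpm_B[g]) for g in kept])
    mean_log = np.array(
        [0.5 * (np.log2(tpm_A[g]) + np.log2(tpm_B[g])) for g in kept]
    )
    labels = np.array([assignments[g] for g in kept])

    bg_mask = labels == "background_set"
    if bg_mask.sum() < n_bins:
        raise ValueError("background set too small for the requested bins")
    edges = np.quantile(mean_log[bg_mask], np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, mean_log, side="right")

    bg_r_by_bin = [r[bg_mask & (bins == b)] for b in range(n_bins)]

    results: dict[str, ExpressionSetResult] = {}
    p_list: list[tuple[str, float]] = []
    for set_label in ("A_only_set", "B_only_set"):
        mask = labels == set_label
        n = int(mask.sum())
        if n == 0:
            continue
        obs_median = float(np.median(r[mask]))
        bin_counts = np.bincount(bins[mask], minlength=n_bins)
        rng = _set_rng()
        cols = []
        for b in range(n_bins):
            k = int(bin_counts[b])
            if k == 0:
                continue
            pool = bg_r_by_bin[b]
            if pool.size == 0:
                raise ValueError(
                    f"expression bin {b} has no background genes; use fewer bins"
                )
            cols.append(pool[rng.integers(0, pool.size, size=(rounds, k))])
        samples = np.concatenate(cols, axis=1)
        res_medians = np.median(samples, axis=1)
        normalized = obs_median - float(np.median(res_medians))
        lo = (1 + np.sum(res_medians <= obs_median)) / (1 + rounds)
        hi = (1 + np.sum(res_medians >= obs_median)) / (1 + rounds)
        p = min(1.0, 2 * min(lo, hi))
        results[set_label] = ExpressionSetResult(
            set_label=set_label,
            n_genes=n,
            median_log2_ratio=obs_median,
            normalized_median=normalized,
            p=float(p),
            q=None,
            underpowered=n < min_set_size,
            n_zero_dropped=dropped,
        )
        p_list.append((set_label, float(p)))

    if p_list:
        qs = bh_correct([p for _, p in p_list])
        for (set_label, _), q in zip(p_list, qs):
            results[set_label].q = float(q)
    return results


# ---------------------------------------------------------------------------
# Gene table I/O (minimal TSV; full GTF parsing is out of scope)

_GENE_COLS = [
    "id",
    "chrom",
    "tss",
    "strand",
    "exon_length_bp",
    "counts_A",
    "counts_B",
    "ortholog_flag",
]


def read_gene_table(path) -> list[Gene]:
    """Read the minimal tab-separated gene table."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_GENE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return [
        Gene(
            id=str(row.id),
            chrom=str(row.chrom),
            tss=int(row.tss),
            strand=str(row.strand),
            exon_length_bp=int(row.exon_length_bp),
            counts_A=int(row.counts_A),
            counts_B=int(row.counts_B),
            is_one_to_one_ortholog=bool(row.ortholog_flag),
        )
        for row in df.itertuples()
    ]


def genes_to_table(genes: Sequence[Gene], path) -> None:
    pd.DataFrame(
        {
            "id": [g.id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
            "exon_length_bp": [g.exon_length_bp for g in genes],
            "counts_A": [g.counts_A for g in genes],
            "counts_B": [g.counts_B for g in genes],
            "ortholog_flag": [int(g.is_one_to_one_ortholog) for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)
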