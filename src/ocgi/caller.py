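"""CpG island segmentation from repeat-masked genome sequence.

The caller scans each chromosome for CpG dinucleotides and grows
candidate islands CpG by CpG. A candidate anchored at one CpG is
extended downstream until its span first reaches the minimum length
(200 bp by default), at which point it is tested against the canonical
thresholds: GC content >= 50% and observed/expected CpG ratio >= 0.6.
A passing candidate keeps growing until the first failing extension,
then the last passing interval is emitted; a failing candidate drops
its anchor CpG and keeps extending. This produces a permissive CGI
track (no post-hoc density pruning), with island boundaries delimited
by CpGs: start at the first CpG's C, end just past the last CpG's G.

Repeat masking is respected by treating soft-masked (lowercase) bases
as N before any computation, so masked bases neither form CpGs nor
count toward GC content.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .intervals import GenomicInterval

__all__ = [
    "CgiParams",
    "CgiCall",
    "normalize_sequence",
    "find_cpgs",
    "cgi_stats",
    "segment_cgis",
    "call_genome",
]


@dataclass(frozen=True)
class CgiParams:
    """The three canonical CpG-island thresholds."""

    min_length: int = 200
    min_gc: float = 0.5
    min_oe: float = 0.6

    def __post_init__(self) -> None:
        if self.min_length <= 0 or self.min_gc <= 0 or self.min_oe <= 0:
            raise ValueError("CgiParams must all be strictly positive")


@dataclass(frozen=True)
class CgiCall:
    """An emitted CpG island with its sequence statistics."""

    interval: GenomicInterval
    length_bp: int
    gc_fraction: float
    cpg_count: int
    obs_exp_ratio: float


_TO_N = str.maketrans(
    "".join(chr(c) for c in range(256) if chr(c) not in "ACGTN"),
    "N" * sum(1 for c in range(256) if chr(c) not in "ACGTN"),
)


def normalize_sequence(seq: str) -> str:
    """Convert soft-masked (lowercase) and non-ACGT characters to N."""
    return seq.translate(_TO_N)


def find_cpgs(seq: str) -> list[int]:
    """0-based positions i with seq[i:i+2] == 'CG', both uppercase.

    Lowercase (masked) or N bases never form a CpG.
    """
    seq = normalize_sequence(seq)
    out = []
    pos = seq.find("CG")
    while pos != -1:
        out.append(pos)
        pos = seq.find("CG", pos + 1)
    return out


class _SeqProfile:
    """Prefix-sum profile of a normalized sequence for O(1) window stats."""

    def __init__(self, seq: str):
        self.seq = normalize_sequence(seq)
        arr = np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        is_acgt = is_c | is_g | (arr == ord("A")) | (arr == ord("T"))
        is_cpg = np.zeros(len(arr), dtype=bool)
        if len(arr) > 1:
            is_cpg[:-1] = is_c[:-1] & is_g[1:]
        z = np.zeros(1, dtype=np.int64)
        self._cum_c = np.concatenate([z, np.cumsum(is_c)])
        self._cum_g = np.concatenate([z, np.cumsum(is_g)])
        self._cum_acgt = np.concatenate([z, np.cumsum(is_acgt)])
        self._cum_cpg = np.concatenate([z, np.cumsum(is_cpg)])

    def stats(self, start: int, end: int) -> tuple[float, int, float]:
        """(gc_fraction, cpg_count, obs_exp_ratio) over [start, end)."""
        n_c = int(self._cum_c[end] - self._cum_c[start])
        n_g = int(self._cum_g[end] - self._cum_g[start])
        n_acgt = int(self._cum_acgt[end] - self._cum_acgt[start])
        # CpGs fully inside the window: the C must sit at <= end-2
        n_cpg = int(self._cum_cpg[max(start, end - 1)] - self._cum_cpg[start])
        gc = (n_c + n_g) / n_acgt if n_acgt else 0.0
        length = end - start
        oe = n_cpg * length / (n_c * n_g) if n_c * n_g else 0.0
        return gc, n_cpg, oe


def cgi_stats(
    seq: str, interval: GenomicInterval
) -> tuple[float, int, float]:
    """GC fraction, CpG count and observed/expected CpG ratio for a window.

    Computed on the uppercase-normalized subsequence with N excluded from
    base counts. The expected CpG count is the Gardiner-Garden–Frommer
    form #C x #G / L, so obs/exp = cpg_count x L / (#C x #G), defined as
    0 when the denominator vanishes.
    """
    if interval.start < 0 or interval.end > len(seq):
        raise IndexError(
            f"interval {interval} outside sequence of length {len(seq)}"
        )
    return _SeqProfile(seq[interval.start : interval.end]).stats(
        0, interval.end - interval.start
    )


def segment_cgis(
    seq: str, chrom: str, params: CgiParams = CgiParams(), max_n_run: int = 20
) -> list[CgiCall]:
    """Run the CpG-windowing segmentation over one chromosome.

    Returns sorted, non-overlapping calls, each of which passes all
    three thresholds when its statistics are recomputed independently.
    Runs of ``max_n_run`` or more masked/ambiguous (N) bases act as
    barriers: a candidate island never bridges them, because masked
    bases carry no CpG information and a bridge would inflate the
    observed/expected ratio over an uninformative gap.
    """
    profile = _SeqProfile(seq)
    segments = _unmasked_segments(profile.seq, max_n_run)
    calls: list[CgiCall] = []
    for seg_start, seg_end in segments:
        calls.extend(
            _segment_core(profile, seg_start, seg_end, chrom, params)
        )
    return calls


def _unmasked_segments(seq: str, max_n_run: int) -> list[tuple[int, int]]:
    """Maximal intervals not interrupted by an N run of >= max_n_run."""
    segments: list[tuple[int, int]] = []
    start = 0
    pos = 0
    n = len(seq)
    while pos < n:
        nxt = seq.find("N", pos)
        if nxt == -1:
            break
        run_end = nxt
        while run_end < n and seq[run_end] == "N":
            run_end += 1
        if run_end - nxt >= max_n_run:
            if nxt > start:
                segments.append((start, nxt))
            start = run_end
        pos = run_end
    if start < n:
        segments.append((start, n))
    return segments


def _segment_core(
    profile: "_SeqProfile",
    seg_start: int,
    seg_end: int,
    chrom: str,
    params: CgiParams,
) -> list[CgiCall]:
    cpg_positions = [
        p for p in find_cpgs(profile.seq[seg_start:seg_end])
    ]
    cpg_positions = [p + seg_start for p in cpg_positions]
    calls: list[CgiCall] = []
    n = len(cpg_positions)
    i = 0
    j = 0
    last_pass: tuple[int, int] | None = None  # (anchor idx, last CpG idx)

    def span(ii: int, jj: int) -> tuple[int, int]:
        return cpg_positions[ii], cpg_positions[jj] + 2

    def passes(ii: int, jj: int) -> bool:
        s, e = span(ii, jj)
        gc, _, oe = profile.stats(s, e)
        return gc >= params.min_gc and oe >= params.min_oe

    def emit(ii: int, jj: int) -> int:
        s, e = span(ii, jj)
        gc, cpg, oe = profile.stats(s, e)
        calls.append(
            CgiCall(
                interval=GenomicInterval(chrom, s, e),
                length_bp=e - s,
                gc_fraction=gc,
                cpg_count=cpg,
                obs_exp_ratio=oe,
            )
        )
        # resume scanning at the first CpG past the emitted interval
        k = jj + 1
        while k < n and cpg_positions[k] < e:
            k += 1
        return k

    while i < n:
        if j < i:
            j = i
        s, e = span(i, j)
        if e - s < params.min_length:
            if j + 1 < n:
                j += 1
                continue
            # sequence end reached before min length; nothing more to emit
            break
        if passes(i, j):
            last_pass = (i, j)
            if j + 1 < n:
                j += 1
                continue
            # sequence end: emit the passing candidate
            i = emit(i, j)
            j = i
            last_pass = None
        elif last_pass is not None:
            # first failing extension of a previously passing candidate
            i = emit(last_pass[0], last_pass[1])
            j = i
            last_pass = None
        else:
            # initial test failed: drop the anchor CpG, keep extending
            i += 1
    return calls


def call_genome(
    sequences: dict[str, str] | str | Path,
    params: CgiParams = CgiParams(),
) -> list[CgiCall]:
    """Segment CGIs over a whole genome.

    ``sequences`` is either a mapping chrom -> sequence or a FASTA path
    (read with pyfaidx).
    """
    if not isinstance(sequences, dict):
        from pyfaidx import Fasta

        fa = Fasta(str(sequences))
        sequences = {name: str(fa[name][:]) for name in fa.keys()}
    calls: list[CgiCall] = []
    for chrom in sequences:
        calls.extend(segment_cgis(sequences[chrom], chrom, params))
    return calls


def calls_to_table(calls):
    """Per-call statistics as a pandas DataFrame (the sidecar TSV)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in calls],
            "start": [c.interval.start for c in calls],
            "end": [c.interval.end for c in calls],
            "name": [c.interval.name or f"CGI_{i + 1}" for i, c in enumerate(calls)],
            "length_bp": [c.length_bp for c in calls],
            "gc_fraction": [c.gc_fraction for c in calls],
            "cpg_count": [c.cpg_count for c in calls],
            "obs_exp_ratio": [c.obs_exp_ratio for c in calls],
        }
    )


def calls_from_table(df) -> list[CgiCall]:
    """Rebuild CgiCall objects from a statistics table."""
    return [
        CgiCall(
            interval=GenomicInterval(r.chrom, int(r.start), int(r.end), name=str(r.name)),
            length_bp=int(r.length_bp),
            gc_fraction=float(r.gc_fraction),
            cpg_count=int(r.cpg_count),
            obs_exp_ratio=float(r.obs_exp_ratio),
        )
        for r in df.itertuples()
    ]
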