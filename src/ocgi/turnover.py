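"""Species-specificity enrichment: the 3x3 oCGI x peak grid test.

For a species pair, each orthologous oCGI site is labelled by its own
species specificity (A-only / B-only / shared) and by the specificity
of the ChIP-seq peaks it overlaps (A-only / B-only / shared / none;
no-peak sites are excluded from the grid). Enrichment of each of the
nine (oCGI label, peak label) combinations over the independence
expectation is assessed with a label-permutation test: one set of
labels is held fixed and the other permuted across the included sites,
which preserves both marginals of the grid in every round. The same
operation run with roles swapped is the peak-centric analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalIndex
from .orthology import OrthologousSite

__all__ = [
    "OCGI_LABELS",
    "PEAK_LABELS",
    "LabeledSite",
    "GridResult",
    "label_sites",
    "build_grid",
    "permutation_grid_test",
    "bh_correct",
]

OCGI_LABELS = ("A_only", "B_only", "shared")
PEAK_LABELS = ("A_only", "B_only", "shared", "none")


@dataclass(frozen=True)
class LabeledSite:
    """One orthologous site with its oCGI and peak specificity labels."""

    ocgi_label: str
    peak_label: str

    def __post_init__(self) -> None:
        if self.ocgi_label not in OCGI_LABELS:
            raise ValueError(f"bad ocgi_label {self.ocgi_label!r}")
        if self.peak_label not in PEAK_LABELS:
            raise ValueError(f"bad peak_label {self.peak_label!r}")

    @property
    def excluded(self) -> bool:
        return self.peak_label == "none"


def label_sites(
    sites: Sequence[OrthologousSite],
    peaks_A: Sequence,
    peaks_B: Sequence,
) -> list[LabeledSite]:
    """Attach peak-specificity labels to orthologous oCGI sites.

    ``peaks_A``/``peaks_B`` are each species' reproducible peaks (the
    same orthology logic applied upstream decides which peaks exist per
    species, so species specificity of the peak is encoded by where it
    is present). A site overlapping (>= 1 bp) a peak in both species is
    "shared"; in exactly one, that species' label; in neither, "none"
    (retained but flagged excluded).
    """
    from .enrichment import _iv

    index_A = IntervalIndex(_iv(p) for p in peaks_A)
    index_B = IntervalIndex(_iv(p) for p in peaks_B)
    out = []
    for site in sites:
        hit_A = site.interval_A is not None and index_A.any_overlap(site.interval_A)
        hit_B = site.interval_B is not None and index_B.any_overlap(site.interval_B)
        if hit_A and hit_B:
            peak_label = "shared"
        elif hit_A:
            peak_label = "A_only"
        elif hit_B:
            peak_label = "B_only"
        else:
            peak_label = "none"
        out.append(LabeledSite(site.label, peak_label))
    return out


def build_grid(sites: Sequence[LabeledSite]) -> np.ndarray:
    """3x3 counts over (oCGI label x peak label), excluding no-peak sites.

    Rows follow OCGI_LABELS, columns the first three PEAK_LABELS.
    """
    grid = np.zeros((3, 3), dtype=np.int64)
    for s in sites:
        if s.excluded:
            continue
        grid[OCGI_LABELS.index(s.ocgi_label), PEAK_LABELS.index(s.peak_label)] += 1
    return grid


@dataclass
class GridResult:
    """Observed / expected counts, enrichment ratios and per-cell
    permutation p- and BH q-values for the 3x3 grid."""

    observed: np.ndarray
    expected: np.ndarray
    enrichment: np.ndarray
    p: np.ndarray
    q: np.ndarray
    rounds: int
    permuted: str  # which labels were permuted: "peak" or "ocgi"

    def as_dict(self) -> dict:
        return {
            "ocgi_labels": list(OCGI_LABELS),
            "peak_labels": list(PEAK_LABELS[:3]),
            "observed": self.observed.tolist(),
            "expected": self.expected.tolist(),
            "enrichment": [
                [None if not np.isfinite(v) else v for v in row]
                for row in self.enrichment.tolist()
            ],
            "p": self.p.tolist(),
            "q": self.q.tolist(),
            "rounds": self.rounds,
            "permuted": self.permuted,
        }


def permutation_grid_test(
    sites: Sequence[LabeledSite],
    rounds: int = 20_000,
    seed: int | np.random.Generator | None = None,
    permute: str = "peak",
    _check_marginals: bool = False,
) -> GridResult:
    """Label-permutation test of the 3x3 specificity grid.

    Sites with no peak are excluded; among the rest, the chosen label
    vector ("peak" for the oCGI-centric analysis, "ocgi" for the
    peak-centric mirror) is permuted uniformly each round and the grid
    re-tallied. Expected counts are per-cell means over rounds;
    enrichment is observed/expected (NaN where expected is 0); p-values
    are two-sided with an add-one pseudo-count; q-values are BH across
    the nine cells.
    """
    if rounds < 100:
        raise ValueError("rounds must be >= 100")
    if permute not in ("peak", "ocgi"):
        raise ValueError("permute must be 'peak' or 'ocgi'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    included = [s for s in sites if not s.excluded]
    observed = build_grid(included)
    n = len(included)
    if n == 0:
        nan = np.full((3, 3), np.nan)
        return GridResult(observed, np.zeros((3, 3)), nan, np.ones((3, 3)), np.ones((3, 3)), rounds, permute)

    rows = np.array([OCGI_LABELS.index(s.ocgi_label) for s in included])
    cols = np.array([PEAK_LABELS.index(s.peak_label) for s in included])
    fixed, moving = (rows, cols) if permute == "peak" else (cols, rows)

    # permute the moving labels across sites, all rounds at once
    perm = np.tile(moving, (rounds, 1))
    perm = rng.permuted(perm, axis=1)
    # per-round 3x3 tallies via one flat bincount
    if permute == "peak":
        cell = fixed[None, :] * 3 + perm
    else:
        cell = perm * 3 + fixed[None, :]
    offsets = (np.arange(rounds) * 9)[:, None]
    counts = np.bincount((cell + offsets).ravel(), minlength=rounds * 9).reshape(
        rounds, 3, 3
    )
    if _check_marginals:
        assert (counts.sum(axis=2) == observed.sum(axis=1)).all()
        assert (counts.sum(axis=1) == observed.sum(axis=0)).all()

    expected = counts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        enrichment = np.where(expected > 0, observed / expected, np.nan)
    dev = np.abs(observed[None, :, :] - expected[None, :, :])
    p = (1 + (np.abs(counts - expected[None, :, :]) >= dev).sum(axis=0)) / (1 + rounds)
    q = bh_correct(p.ravel()).reshape(3, 3)
    return GridResult(observed, expected, enrichment, p.astype(float), q, rounds, permute)


def bh_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
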