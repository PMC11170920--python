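"""Overlap fractions, the genomic shuffle null, RPKM, conservation, ages."""

import numpy as np
import pytest

from ocgi.enrichment import (
    AgeCategory,
    Peak,
    assign_age,
    conservation_summary,
    overlap_fraction,
    quantify_rpkm,
    shuffle_intervals,
    shuffle_test,
)
from ocgi.intervals import GenomicInterval, merge_intervals


def _iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestOverlapFraction:
    def test_simple_percentage(self):
        ocgis = [_iv(i * 100, i * 100 + 50) for i in range(10)]
        peaks = [Peak(_iv(i * 100, i * 100 + 10)) for i in range(4)]
        assert overlap_fraction(ocgis, peaks) == 40.0

    def test_no_peaks_gives_zero(self):
        assert overlap_fraction([_iv(0, 10)], []) == 0.0

    def test_empty_ocgis_is_error(self):
        with pytest.raises(ValueError):
            overlap_fraction([], [Peak(_iv(0, 10))])

    def test_matches_quadratic_oracle(self, rng):
        ocgis = [
            _iv(int(s), int(s + l))
            for s, l in zip(rng.integers(0, 20_000, 200), rng.integers(50, 400, 200))
        ]
        peaks = [
            Peak(_iv(int(s), int(s + l)))
            for s, l in zip(rng.integers(0, 20_000, 100), rng.integers(50, 400, 100))
        ]
        brute = (
            100.0
            * sum(
                1
                for o in ocgis
                if any(
                    min(o.end, p.interval.end) - max(o.start, p.interval.start) >= 1
                    for p in peaks
                )
            )
            / len(ocgis)
        )
        assert overlap_fraction(ocgis, peaks) == pytest.approx(brute)


class TestRpkm:
    @pytest.mark.parametrize(
        "length, reads, lib, expected",
        [(500, 10, 10_000_000, 2.0), (500, 0, 10_000_000, 0.0), (1000, 1000, 1_000_000, 1000.0)],
    )
    def test_closed_form(self, length, reads, lib, expected):
        peak = Peak(_iv(0, length))
        assert quantify_rpkm(peak, reads, lib) == pytest.approx(expected)

    def test_zero_library_is_error(self):
        with pytest.raises(ValueError):
            quantify_rpkm(Peak(_iv(0, 100)), 5, 0)


class TestConservationSummary:
    def test_no_overlap_gives_zeros(self):
        s = conservation_summary(_iv(0, 100), [(_iv(500, 600), 9.0)])
        assert (s.max_lod, s.aggregate_lod, s.covered_fraction) == (0.0, 0.0, 0.0)

    def test_hand_counted_example(self):
        s = conservation_summary(
            _iv(0, 100), [(_iv(10, 20), 5.0), (_iv(50, 90), 7.0)]
        )
        assert (s.max_lod, s.aggregate_lod, s.covered_fraction) == (7.0, 12.0, 0.5)

    def test_full_coverage(self):
        s = conservation_summary(_iv(10, 60), [(_iv(0, 100), 3.0)])
        assert s.covered_fraction == 1.0

    def test_matches_per_base_oracle(self, rng):
        iv = _iv(0, 2_000)
        elements = [
            (_iv(int(s), int(s + l)), float(lod))
            for s, l, lod in zip(
                rng.integers(0, 2_500, 30), rng.integers(10, 300, 30), rng.random(30) * 10
            )
        ]
        s = conservation_summary(iv, elements)
        mask = np.zeros(2_000, dtype=bool)
        lods = []
        for el, lod in elements:
            lo, hi = max(0, el.start), min(2_000, el.end)
            if hi > lo:
                mask[lo:hi] = True
                lods.append(lod)
        assert s.covered_fraction == pytest.approx(mask.sum() / 2_000)
        assert s.max_lod == pytest.approx(max(lods) if lods else 0.0)
        assert s.aggregate_lod == pytest.approx(sum(lods))
        if lods:
            assert s.aggregate_lod >= s.max_lod


class TestAssignAge:
    AGEMAP = [
        (_iv(0, 100, "chrH"), "Primate"),
        (_iv(100, 200, "chrH"), "Amniota"),
        (_iv(300, 400, "chrH"), "Tetrapoda"),
        (_iv(500, 600, "chrH"), "Human"),
    ]

    def test_oldest_overlapping_age_wins(self):
        assert assign_age(_iv(50, 150, "chrH"), self.AGEMAP) == AgeCategory.Amniota

    def test_ancient_categories_collapse(self):
        assert (
            assign_age(_iv(310, 320, "chrH"), self.AGEMAP)
            == AgeCategory.OlderThanAmniota
        )

    def test_age_outside_species_clade_becomes_unknown(self):
        # a pig interval dated "Human" is meaningless for pig
        pig_clades = {"Eutheria", "Theria", "Mammalia", "Amniota"}
        assert (
            assign_age(_iv(510, 520, "chrH"), self.AGEMAP, pig_clades)
            == AgeCategory.Unknown
        )

    def test_no_overlap_is_unknown(self):
        assert assign_age(_iv(900, 950, "chrH"), self.AGEMAP) == AgeCategory.Unknown


class TestShuffle:
    def test_placements_preserve_length_and_chrom_avoid_exclusions(self, rng):
        sizes = {"chr1": 50_000, "chr2": 30_000}
        excluded = [_iv(10_000, 20_000), _iv(5_000, 8_000, "chr2")]
        intervals = [_iv(0, 400), _iv(100, 600), _iv(0, 300, "chr2")] * 10
        for _ in range(50):
            placed = shuffle_intervals(intervals, sizes, excluded, rng)
            assert [len(p) for p in placed] == [len(i) for i in intervals]
            assert [p.chrom for p in placed] == [i.chrom for i in intervals]
            merged = merge_intervals(placed)
            assert sum(len(m) for m in merged) == sum(len(p) for p in placed)  # disjoint
            for p in placed:
                for e in excluded:
                    assert (
                        p.chrom != e.chrom
                        or min(p.end, e.end) <= max(p.start, e.start)
                    )

    def test_unplaceable_interval_names_chromosome(self, rng):
        sizes = {"chr1": 1_000}
        excluded = [_iv(0, 990)]
        with pytest.raises(RuntimeError, match="chr1"):
            shuffle_intervals([_iv(0, 500)], sizes, excluded, rng, max_attempts=50)

    def test_saturating_peaks_give_p_one(self):
        sizes = {"chr1": 10_000}
        peaks = [Peak(_iv(0, 10_000))]
        ocgis = [_iv(100, 300), _iv(5_000, 5_400)]
        res = shuffle_test(ocgis, peaks, sizes, [], rounds=100, seed=0)
        assert res.observed == 100.0
        assert res.expected == 100.0
        assert res.p_value == 1.0

    def test_planted_overlap_enrichment_detected(self):
        rng = np.random.default_rng(3)
        sizes = {"chr1": 200_000}
        # peaks over 10% of the chromosome; 80% of oCGIs planted inside them
        peaks = [Peak(_iv(i * 10_000, i * 10_000 + 1_000)) for i in range(20)]
        ocgis = []
        for k in range(50):
            if k < 40:
                base = (k % 20) * 10_000 + int(rng.integers(0, 800))
            else:
                base = int(rng.integers(0, 199_000))
                base = base - base % 10_000 + 2_000 + int(rng.integers(0, 6_000))
            ocgis.append(_iv(base, base + 200))
        res = shuffle_test(ocgis, peaks, sizes, [], rounds=1_000, seed=3)
        assert res.observed > res.expected
        assert res.p_value < 0.005

    def test_two_seeds_agree_on_expected_value(self):
        rng = np.random.default_rng(8)
        sizes = {"chr1": 100_000}
        peaks = [Peak(_iv(int(s), int(s) + 500)) for s in rng.integers(0, 99_000, 30)]
        ocgis = [_iv(int(s), int(s) + 300) for s in rng.integers(0, 99_000, 40)]
        r1 = shuffle_test(ocgis, peaks, sizes, [], rounds=400, seed=1)
        r2 = shuffle_test(ocgis, peaks, sizes, [], rounds=400, seed=2)
        se = np.std(r1.shuffled_fractions) / np.sqrt(400)
        assert abs(r1.expected - r2.expected) < 3 * se * np.sqrt(2) + 1e-9
        for r in (r1, r2):
            assert 0 < r.p_value <= 1
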