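"""Synthetic-data generators: determinism, planted-truth fidelity."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from ocgi.caller import call_genome, cgi_stats
from ocgi.orthology import map_interval
from ocgi.simulate import (
    SyntheticSpec,
    _coupled_joint,
    make_enhancers,
    make_expression,
    make_genome,
    make_peaks_and_signal,
    make_species_pair,
)


class TestSpecValidation:
    def test_turnover_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SyntheticSpec(turnover_fractions=(0.5, 0.4, 0.3))

    def test_infeasible_island_oe_rejected(self):
        with pytest.raises(ValueError, match="island_oe_target"):
            SyntheticSpec(island_gc=0.5, island_oe_target=9.0)

    def test_coupling_below_one_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(peak_coupling_odds=0.5)


class TestMakeGenome:
    def test_same_seed_identical_output(self):
        spec = SyntheticSpec(seed=3, n_chroms=1, chrom_length_bp=50_000, n_islands=5)
        s1, i1, m1 = make_genome(spec)
        s2, i2, m2 = make_genome(spec)
        assert s1 == s2 and i1 == i2 and m1 == m2

    def test_zero_islands_negative_control(self):
        spec = SyntheticSpec(seed=5, n_chroms=1, chrom_length_bp=1_000_000, n_islands=0)
        seqs, islands, _ = make_genome(spec)
        assert islands == []
        assert len(call_genome(seqs)) < 1_000_000 / 1e6 + 1  # < 1 per Mb

    def test_planted_islands_hit_target_oe_and_gc(self):
        spec = SyntheticSpec(seed=7, n_chroms=1, chrom_length_bp=200_000, n_islands=20)
        seqs, islands, _ = make_genome(spec)
        for iv in islands:
            gc, _, oe = cgi_stats(seqs[iv.chrom], iv)
            assert oe == pytest.approx(spec.island_oe_target, abs=0.05)
            assert gc == pytest.approx(spec.island_gc, abs=0.05)


class TestMakeSpeciesPair:
    def test_zero_indel_rate_gives_identity_maps(self):
        spec = SyntheticSpec(
            seed=2, n_chroms=1, chrom_length_bp=100_000, n_islands=10,
            indel_rate_per_kb=0.0,
        )
        pair = make_species_pair(spec)
        for cmap in (pair.map_A_to_human, pair.map_B_to_human):
            assert len(cmap.blocks) == 1
            src, tgt = cmap.blocks[0]
            assert (src.start, src.end) == (tgt.start, tgt.end) == (0, 100_000)

    def test_round_trip_through_indel_maps_is_identity_on_islands(self):
        spec = SyntheticSpec(seed=4, n_chroms=1, chrom_length_bp=300_000, n_islands=20)
        pair = make_species_pair(spec)
        inv = pair.map_A_to_human.invert()
        for iv in pair.islands_human:
            down = map_interval(iv, inv)
            assert down is not None
            back = map_interval(down, pair.map_A_to_human)
            assert (back.chrom, back.start, back.end) == (iv.chrom, iv.start, iv.end)

    def test_all_shared_turnover_recovers_all_shared(self):
        spec = SyntheticSpec(
            seed=8, n_chroms=1, chrom_length_bp=400_000, n_islands=40,
            turnover_fractions=(1.0, 0.0, 0.0),
        )
        pair = make_species_pair(spec)
        assert set(pair.labels) == {"shared"}
        # degraded nowhere: both species carry every island
        calls_A = call_genome(pair.seq_A)
        calls_B = call_genome(pair.seq_B)
        assert len(calls_A) >= 38 and len(calls_B) >= 38

    def test_absent_islands_fall_below_oe_threshold(self):
        spec = SyntheticSpec(seed=12, n_chroms=1, chrom_length_bp=400_000, n_islands=40)
        pair = make_species_pair(spec)
        for iv_h, iv_a, label in zip(pair.islands_human, pair.islands_A, pair.labels):
            if label == "B_only" and iv_a is not None:
                _, _, oe = cgi_stats(pair.seq_A[iv_a.chrom], iv_a)
                assert oe < 0.6


class TestCoupledJoint:
    def test_sums_to_one_and_marginals_match(self):
        spec = SyntheticSpec(peak_coupling_odds=2.5)
        J = _coupled_joint(spec)
        assert J.sum() == pytest.approx(1.0)
        pS, pA, pB = spec.turnover_fractions
        assert J.sum(axis=1) == pytest.approx([pA, pB, pS])

    def test_unit_odds_gives_independence(self):
        spec = SyntheticSpec(peak_coupling_odds=1.0)
        J = _coupled_joint(spec)
        rows, cols = J.sum(axis=1), J.sum(axis=0)
        assert J == pytest.approx(np.outer(rows, cols))

    def test_included_diagonal_enrichment_equals_odds(self):
        spec = SyntheticSpec(peak_coupling_odds=3.0)
        J = _coupled_joint(spec)
        K = J[:, :3] / J[:, :3].sum()
        rows, cols = K.sum(axis=1), K.sum(axis=0)
        assert K[0, 0] / (rows[0] * cols[0]) == pytest.approx(3.0)
        assert K[1, 1] / (rows[1] * cols[1]) == pytest.approx(3.0)

    def test_excessive_odds_rejected(self):
        spec = SyntheticSpec(peak_coupling_odds=3.0)
        object.__setattr__(spec, "peak_coupling_odds", 50.0)
        with pytest.raises(ValueError):
            _coupled_joint(spec)


class TestPeaksAndExpression:
    def test_signal_boost_raises_ocgi_peak_signal(self, turnover_study):
        spec0 = turnover_study["spec"]
        pair = turnover_study["pair"]
        sites = turnover_study["sites"]
        boosted = SyntheticSpec(
            seed=spec0.seed, peak_base_probs=(0.1, 0.1, 0.4, 0.4),
            signal_boost_at_ocgi=3.0,
        )
        pk = make_peaks_and_signal(
            boosted, sites, pair.chrom_sizes_A, pair.chrom_sizes_B,
            rng=np.random.default_rng(1),
        )
        from ocgi.intervals import IntervalIndex

        ocgi_idx = IntervalIndex(
            s.interval_A for s in sites if s.present_A and s.interval_A is not None
        )
        with_ocgi = [p.signal for p in pk.peaks_A if ocgi_idx.any_overlap(p.interval)]
        without = [p.signal for p in pk.peaks_A if not ocgi_idx.any_overlap(p.interval)]
        assert np.mean(with_ocgi) > 2.0 * np.mean(without)
        u = stats.mannwhitneyu(with_ocgi, without)
        assert u.pvalue < 1e-6

    def test_read_counts_consistent_with_signal_as_rpkm(self, turnover_study):
        pair = turnover_study["pair"]
        sites = turnover_study["sites"]
        spec = turnover_study["spec"]
        pk = make_peaks_and_signal(
            spec, sites, pair.chrom_sizes_A, pair.chrom_sizes_B,
            rng=np.random.default_rng(2),
        )
        from ocgi.enrichment import quantify_rpkm

        rpkms = [
            quantify_rpkm(p, c, pk.library_size)
            for p, c in zip(pk.peaks_A, pk.counts_A)
        ]
        signals = [p.signal for p in pk.peaks_A]
        assert np.corrcoef(rpkms, signals)[0, 1] > 0.9

    def test_expression_counts_deterministic(self):
        spec = SyntheticSpec(seed=6)
        truth = {f"g{i}": "background_set" for i in range(50)}
        g1 = make_expression(spec, truth)
        g2 = make_expression(spec, truth)
        assert g1 == g2

    def test_enhancer_pattern_multiplier_shifts_human_only_rate(self):
        base = Counter(
            e.pattern for e in make_enhancers(SyntheticSpec(seed=3))[1]
        )
        hges, _ = make_enhancers(SyntheticSpec(seed=3, hge_pattern_multiplier=3.0))
        boosted = Counter(e.pattern for e in hges)
        assert boosted["human_only"] / len(hges) > 1.8 * base["human_only"] / 3_000
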