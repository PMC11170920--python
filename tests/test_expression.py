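"""TPM, GREAT regulatory domains, gene sets, expression-ratio resampling."""

import pytest

from ocgi.expression import (
    Gene,
    assign_gene_sets,
    compute_tpm,
    expression_ratio_test,
    great_domains,
)
from ocgi.intervals import GenomicInterval
from ocgi.simulate import SyntheticSpec, make_expression, make_gene_layout


def _gene(gid, tss, counts_A=100, counts_B=100, length=1_000, strand="+", chrom="chr1"):
    return Gene(
        id=gid, chrom=chrom, tss=tss, strand=strand,
        exon_length_bp=length, counts_A=counts_A, counts_B=counts_B,
    )


class TestTpm:
    def test_equal_rates_split_evenly(self):
        genes = [_gene("a", 0, 100, 0, length=1_000), _gene("b", 0, 300, 0, length=3_000)]
        tpm = compute_tpm(genes, "A")
        assert tpm == {"a": pytest.approx(500_000.0), "b": pytest.approx(500_000.0)}

    def test_single_gene_gets_everything(self):
        assert compute_tpm([_gene("a", 0)], "A")["a"] == pytest.approx(1e6)

    def test_sum_is_one_million_and_matches_recomputation(self, rng):
        genes = [
            _gene(f"g{i}", 0, int(c), 0, length=int(l))
            for i, (c, l) in enumerate(
                zip(rng.integers(1, 5_000, 20), rng.integers(200, 8_000, 20))
            )
        ]
        tpm = compute_tpm(genes, "A")
        assert sum(tpm.values()) == pytest.approx(1e6)
        rates = {g.id: g.counts_A / (g.exon_length_bp / 1_000) for g in genes}
        total = sum(rates.values())
        for g in genes:
            assert tpm[g.id] == pytest.approx(1e6 * rates[g.id] / total)

    def test_all_zero_counts_is_error(self):
        with pytest.raises(ValueError):
            compute_tpm([_gene("a", 0, 0, 0)], "A")


class TestGreatDomains:
    def test_isolated_gene_arithmetic_with_cap(self):
        doms = great_domains([_gene("a", 2_000_000)], {"chr1": 10_000_000})
        d = doms[0]
        assert (d.basal.start, d.basal.end) == (1_995_000, 2_001_000)
        assert (d.extended.start, d.extended.end) == (995_000, 3_001_000)

    def test_basal_window_is_6kb_and_strand_aware(self):
        plus, minus = great_domains(
            [_gene("p", 100_000, strand="+"), _gene("m", 500_000, strand="-")],
            {"chr1": 1_000_000},
        )
        assert len(plus.basal) == 6_000 and len(minus.basal) == 6_000
        assert (plus.basal.start, plus.basal.end) == (95_000, 101_000)
        assert (minus.basal.start, minus.basal.end) == (499_000, 505_000)

    def test_extension_stops_at_neighbouring_basal_domain(self):
        g1, g2 = _gene("up", 100_000), _gene("down", 110_000)
        doms = {d.gene_id: d for d in great_domains([g1, g2], {"chr1": 1_000_000})}
        # downstream gene's basal starts at 105,000: upstream gene stops there
        assert doms["up"].extended.end == doms["down"].basal.start
        assert doms["down"].extended.start == doms["up"].basal.end

    def test_matches_brute_force_nearest_basal_scan(self, rng):
        chrom_len = 30_000_000
        genes = [
            _gene(f"g{i}", int(t), strand="+" if rng.random() < 0.5 else "-")
            for i, t in enumerate(sorted(rng.integers(10_000, chrom_len - 10_000, 50)))
        ]
        doms = {d.gene_id: d for d in great_domains(genes, {"chr1": chrom_len})}
        # quadratic re-derivation straight from the rules
        basals = {}
        for g in genes:
            if g.strand == "+":
                basals[g.id] = (g.tss - 5_000, g.tss + 1_000)
            else:
                basals[g.id] = (g.tss - 1_000, g.tss + 5_000)
        for g in genes:
            b_lo, b_hi = basals[g.id]
            left, right = max(0, b_lo - 1_000_000), min(chrom_len, b_hi + 1_000_000)
            for o in genes:
                if o.id == g.id:
                    continue
                o_lo, o_hi = basals[o.id]
                if o_hi <= b_lo:
                    left = max(left, o_hi)
                elif o_lo >= b_hi:
                    right = min(right, o_lo)
                else:
                    if o_lo < b_lo:
                        left = b_lo
                    if o_hi > b_hi:
                        right = b_hi
            d = doms[g.id]
            assert (d.extended.start, d.extended.end) == (min(left, b_lo), max(right, b_hi))


class TestAssignGeneSets:
    def _domains(self):
        genes = [_gene("a", 100_000), _gene("b", 400_000), _gene("c", 800_000)]
        return great_domains(genes, {"chr1": 2_000_000})

    def test_single_a_site_gives_a_only_set(self):
        sites = [(GenomicInterval("chr1", 98_000, 98_300), "A_only")]
        out = assign_gene_sets(self._domains(), sites)
        assert out["a"] == "A_only_set"

    def test_both_kinds_give_mixed_set(self):
        sites = [
            (GenomicInterval("chr1", 98_000, 98_300), "A_only"),
            (GenomicInterval("chr1", 99_000, 99_300), "B_only"),
        ]
        assert assign_gene_sets(self._domains(), sites)["a"] == "mixed_set"

    def test_no_site_gives_background_and_labels_partition(self):
        sites = [(GenomicInterval("chr1", 98_000, 98_300), "A_only")]
        out = assign_gene_sets(self._domains(), sites)
        assert out["c"] == "background_set"
        assert set(out) == {"a", "b", "c"}

    def test_invalid_site_label_rejected(self):
        with pytest.raises(ValueError):
            assign_gene_sets(
                self._domains(), [(GenomicInterval("chr1", 0, 10), "shared")]
            )


class TestExpressionRatioTest:
    def _study(self, seed, effect, n_genes=400, n_set=50):
        spec = SyntheticSpec(
            seed=seed, n_genes=n_genes, n_set_genes=n_set,
            expression_log2_effect=effect,
        )
        sizes = {"chr1": 4_000_000, "chr2": 4_000_000}
        placements, truth, qsites = make_gene_layout(spec, sizes)
        genes = make_expression(spec, truth, placements)
        assignments = assign_gene_sets(great_domains(genes, sizes), qsites)
        return assignments, compute_tpm(genes, "A"), compute_tpm(genes, "B")

    def test_planted_effect_recovered(self):
        assignments, tpm_A, tpm_B = self._study(13, effect=1.0)
        res = expression_ratio_test(assignments, tpm_A, tpm_B, rounds=1_000, seed=13)
        assert res["A_only_set"].normalized_median == pytest.approx(1.0, abs=0.15)
        assert res["B_only_set"].normalized_median == pytest.approx(-1.0, abs=0.15)
        assert res["A_only_set"].p < 0.01
        assert res["B_only_set"].p < 0.01

    def test_null_effect_not_significant_in_most_seeds(self):
        ok = 0
        for seed in range(10):
            assignments, tpm_A, tpm_B = self._study(40 + seed, effect=0.0)
            res = expression_ratio_test(
                assignments, tpm_A, tpm_B, rounds=400, seed=seed
            )
            if all(
                abs(r.normalized_median) < 0.1 and r.p >= 0.05 for r in res.values()
            ):
                ok += 1
        assert ok >= 8

    def test_species_swap_negates_medians_exactly(self):
        assignments, tpm_A, tpm_B = self._study(21, effect=0.7)
        swapped = {
            g: {"A_only_set": "B_only_set", "B_only_set": "A_only_set"}.get(v, v)
            for g, v in assignments.items()
        }
        fwd = expression_ratio_test(assignments, tpm_A, tpm_B, rounds=400, seed=5)
        rev = expression_ratio_test(swapped, tpm_B, tpm_A, rounds=400, seed=5)
        assert fwd["A_only_set"].normalized_median == pytest.approx(
            -rev["B_only_set"].normalized_median, abs=1e-9
        )
        assert fwd["B_only_set"].normalized_median == pytest.approx(
            -rev["A_only_set"].normalized_median, abs=1e-9
        )

    def test_small_set_flagged_underpowered(self):
        assignments, tpm_A, tpm_B = self._study(33, effect=0.0, n_set=3)
        res = expression_ratio_test(assignments, tpm_A, tpm_B, rounds=200, seed=0)
        assert all(r.underpowered for r in res.values())
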