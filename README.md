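# ocgi — orphan CpG island turnover and enhancer evolution

`ocgi` is a tested, reusable implementation of a comparative
epigenomics analysis: do gains and losses of **orphan CpG islands**
(oCGIs — CpG islands away from promoters and exons) across species
track gains and losses of enhancer activity, as read out by
histone-modification ChIP-seq peaks and by gene expression change?
It is aimed at regulatory-genomics researchers who want to run the
pipeline on their own interval data, or to study its statistical
behaviour on simulated genomes where the truth is known.

The package provides every stage as a library function with a thin CLI
on top:

1. **CGI calling** from repeat-masked sequence by a CpG-anchored
   windowing scan, with the canonical thresholds: length ≥ 200 bp,
   GC ≥ 50%, and observed/expected CpG ratio ≥ 0.6, where
   O/E = #CpG × L / (#C × #G).
2. **Orphan filtering**: exclusion of CGIs within 1 bp of exons,
   promoter windows (2 kb upstream of TSSs), blacklist regions or CAGE
   promoters, in the source genome and — after lifting through a
   liftover-style block map (minMatch 0.8) — in the human genome.
3. **Orthology**: pairwise orthologous sites via a human intermediate,
   labelled A-only / B-only / shared, with an optional minimal
   O/E-difference filter and outgroup-polarized gain/loss counts.
4. **Overlap statistics**: oCGI×peak overlap fractions against a
   length- and chromosome-preserving genomic shuffle null (20,000
   rounds by default), RPKM signal quantification, constrained-element
   (LOD) summaries, and sequence-age assignment.
5. **The 3×3 specificity grid**: enrichment of species-specific oCGIs
   in species-specific peaks, tested by label permutation with
   Benjamini–Hochberg correction, in oCGI-centric and peak-centric
   modes.
6. **HGE patterns**: 8-way three-species oCGI presence patterns at
   enhancers, comparing human-gain enhancers to signal-matched
   resamples of the background.
7. **Expression**: GREAT-rule regulatory domains (basal 5 kb up / 1 kb
   down, extended ≤ 1 Mb), A-only/B-only/mixed/background gene sets,
   TPM, and an expression-matched resampling test on per-gene
   log2(TPM_A/TPM_B).
8. **Synthetic data**: seeded generators for genomes with planted
   islands, indel-bearing coordinate maps, coupled peaks, enhancers and
   expression counts — every statistical stage has a planted effect it
   must recover.

## Worked example

Simulate a species pair with 40% shared / 30% A-only / 30% B-only oCGI
turnover and peaks coupled to oCGI specificity at 3× enrichment, then
recover that coupling end to end:

```python
from collections import Counter
from ocgi import SyntheticSpec
from ocgi.simulate import make_species_pair, make_peaks_and_signal
from ocgi.caller import call_genome
from ocgi.orthology import build_orthologous_sites
from ocgi.turnover import label_sites, permutation_grid_test

spec = SyntheticSpec(seed=42, n_chroms=2, chrom_length_bp=1_000_000,
                     n_islands=400, turnover_fractions=(0.4, 0.3, 0.3),
                     peak_coupling_odds=3.0)
pair = make_species_pair(spec)
ocgis_A = call_genome(pair.seq_A)
ocgis_B = call_genome(pair.seq_B)
print(f"CGIs called: {len(ocgis_A)} in species A, {len(ocgis_B)} in species B")

sites = build_orthologous_sites(ocgis_A, ocgis_B,
                                pair.map_A_to_human, pair.map_B_to_human)
print(f"orthologous sites: {len(sites)}  {dict(Counter(s.label for s in sites))}")

peaks = make_peaks_and_signal(spec, sites, pair.chrom_sizes_A, pair.chrom_sizes_B)
labeled = label_sites(sites, peaks.peaks_A, peaks.peaks_B)
result = permutation_grid_test(labeled, rounds=2000, seed=42)
print("enrichment (A-only, A-only):", round(result.enrichment[0, 0], 2),
      " p =", round(result.p[0, 0], 5), " q =", round(result.q[0, 0], 5))
```

This prints:

```
CGIs called: 293 in species A, 279 in species B
orthologous sites: 404  {'A_only': 125, 'shared': 167, 'B_only': 112}
enrichment (A-only, A-only): 2.94  p = 0.0005  q = 0.00056
```

The caller recovers the 400 planted islands minus those degraded per
species (plus a handful of borderline background calls); the
orthology stage recovers the planted turnover mixture within sampling
error; and the grid test estimates the planted 3× coupling as 2.94
with a permutation p-value at the resolution floor of 2,000 rounds.

The same run is available as a config-driven pipeline with a manifest
of checksums:

```bash
ocgi run --config run.yaml --outdir out/
```

where `run.yaml` holds a `spec:` section (any `SyntheticSpec` field)
and an optional `tests:` section (round/bin counts). Individual stages
are exposed as `ocgi call`, `ocgi filter`, `ocgi orthology`,
`ocgi enrich-overlap`, `ocgi grid-test`, `ocgi hge-test`,
`ocgi expr-test` and `ocgi simulate` on standard BED/TSV files.

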