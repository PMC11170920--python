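# Methods

This note documents the models, procedures and numerical choices behind
`ocgi`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## CpG island segmentation

CpG islands (CGIs) are called by a CpG-anchored windowing scan over each
chromosome. All positions of CpG dinucleotides are collected first
(soft-masked and ambiguous bases are converted to N beforehand and can
neither form CpGs nor contribute to base counts). A candidate island is
anchored at one CpG and extended CpG by CpG; once its span — from the
anchor's C to the current CpG's G inclusive — first reaches the minimum
length, it is tested against the canonical thresholds:

- length >= 200 bp,
- GC fraction >= 0.5, computed as (#C + #G) / (#A + #C + #G + #T),
- observed/expected CpG ratio >= 0.6, with the expected count in the
  Gardiner-Garden–Frommer form #C x #G / L (the ratio is defined as 0
  when #C x #G = 0).

A passing candidate keeps absorbing the next downstream CpG and is
re-tested; at the first failing extension (or at sequence end) the last
passing interval is emitted and scanning resumes at the first CpG past
it. A candidate that fails its first test drops its anchor CpG and
continues extending. Emitted calls are therefore non-overlapping,
sorted, CpG-delimited, and *locally maximal*: absorbing one more CpG
would break a criterion. This produces a deliberately permissive track
— no post-hoc pruning to the densest islands is applied.

Two numerical choices matter. First, "the interval between two CpGs
reaches 200 bp" is implemented as the candidate's *span* reaching the
minimum length; the alternative reading (a 200-bp gap between
consecutive CpGs) would terminate islands rather than found them.
Second, runs of >= 20 N bases act as scan barriers: because N bases are
excluded from base counts but not from interval length, a candidate
bridging a multi-kilobase masked block would earn an arbitrarily
inflated O/E ratio from an uninformative gap. Segmenting at long N runs
removes exactly those bridge artifacts; isolated Ns are unaffected.

## Orphan filtering

An orphan CGI (oCGI) is a CGI with no gene-associated annotation within
1 bp: exons, promoter windows (2 kb upstream of each TSS, strand-aware,
clipped at contig ends), blacklist regions, and CAGE-defined promoters
are all excluded. Which categories apply is configuration, not code —
every supplied feature set is excluded — so species with richer
annotation (human, mouse) simply supply more sets. A second filter then
lifts each surviving oCGI to the human genome and removes those without
orthologous human sequence or whose human ortholog overlaps any human
exclusion feature. The mappability requirement is the same min-match
rule used everywhere else (below).

## Coordinate maps and orthologous sites

Cross-species lifting runs through a `CoordinateMap`: paired, equal
length aligned blocks, non-overlapping and order-preserving per
chromosome, with everything between blocks an explicit unmapped gap.
An interval lifts if at least `min_match = 0.8` of its bases fall in
aligned blocks and all its blocks land co-linearly on one target
chromosome; the lifted interval spans the images of its first and last
mappable bases. Non-co-linear or split projections are treated as
unmapped rather than guessed at.

Orthologous sites for a species pair are built through the human
intermediate: both species' oCGIs are lifted to human, overlapping or
book-ended projections are merged into anchors (a source-tracking merge
that preserves each input's origin, the behaviour of
`bedtools merge -c 4 -o collapse`), and a site is emitted only when the
anchor lifts back to *both* species — the underlying sequence must
exist in both even when the oCGI was called in only one. Sites are
labelled A-only, B-only or shared. When a species lacks a call at a
site, its O/E ratio is recomputed from the orthologous sequence when
sequence is supplied, and is otherwise 0 — the conservative choice,
since a missing value then always counts as a maximal difference in the
minimal-O/E-difference filter. That filter removes species-specific
sites with |O/E_A − O/E_B| below a chosen delta, guarding turnover
calls against threshold-straddling artifacts; it is monotone in delta
and the identity at delta = 0.

Three-species presence/absence patterns are polarized against an
outgroup: a gain on the focal branch requires presence in the focal
species and absence in both sister and outgroup; a loss is the mirror;
everything else is unpolarized.

## Overlap quantification and the genomic shuffle null

The fraction of oCGIs overlapping peaks (>= 1 bp) is compared with a
length- and chromosome-preserving reshuffle: each round places every
oCGI uniformly at random on its own chromosome, avoiding excluded
regions (annotated features, repeat-masked intervals) and previously
placed intervals, by rejection sampling with a 10,000-attempt cap that
fails loudly naming the chromosome. Each shuffled set is then passed
through the same human-intermediate filter as the observed set before
its overlap fraction is recorded, so the null respects the ascertainment
of the observed data. The expected value is the mean over rounds and
the p-value is two-sided with an add-one pseudo-count,
p = (1 + #{|shuffled − expected| >= |observed − expected|}) / (1 + rounds),
which never returns 0. The reference round count is 20,000; smaller
counts are used in the packaged studies (stated below).

Peak signal is RPKM from supplied per-peak read counts:
reads / (length_kb x library_size_millions); BAM counting is out of
scope. Conservation summaries report the maximum and the sum of LOD
scores of overlapping constrained elements plus the fraction of bases
covered. Sequence ages take the most ancient overlapping segment of an
age segmentation map, collapse the three most ancient labels
(Tetrapoda, Gnathostomata, Vertebrata) into "Older than Amniota", and
convert ages naming clades that do not contain the analysed species to
Unknown (the map is human-anchored, so e.g. a pig interval dated
"Human" is meaningless for pig).

## The 3x3 specificity grid test

Each orthologous oCGI site is labelled by the species specificity of
the peaks it overlaps: shared if hit in both species, A-/B-only if hit
in exactly one, none otherwise; no-peak sites are excluded from the
grid but retained in the site table. The 3x3 observed counts are
compared against a label permutation: holding one label vector fixed
and permuting the other across included sites, which preserves both
grid marginals every round. Expected counts are per-cell means over
rounds (converging to the product of marginals over n), enrichment is
observed/expected, p-values are two-sided add-one, and q-values are
Benjamini-Hochberg across the nine cells. The peak-centric analysis is
the same operation with the roles of the two label vectors swapped
(one code path, a flag). The default is 20,000 rounds.

## HGE pattern analysis

Human enhancers are classified by their oCGI presence across human,
rhesus and mouse into eight patterns (human-only ... all-three, none).
Human-gain enhancers (HGEs) are compared with non-HGE enhancers for
pattern composition using a signal-matched resample: the HGE signal
distribution is cut into deciles (10 quantile bins by default), and
each round draws from the background, with replacement and per bin,
exactly the HGE count of that bin. Because draws within a bin are
uniform over its members, the per-round pattern counts are multinomial
on the bin's pattern frequencies and are sampled directly in that form;
per-bin totals equal the HGE bin counts by construction, which is the
matching property. Per-pattern p-values are doubled one-sided add-one
tail probabilities of the observed proportion within the resampled
distribution, BH-corrected across the eight patterns. Sampling *with*
replacement is a choice; without replacement would shrink the resample
variance slightly in small bins.

## Regulatory domains and the expression test

Regulatory domains follow the GREAT rules: a basal domain 5 kb upstream
and 1 kb downstream of the TSS (strand-aware), extended on each side to
the nearest other basal domain boundary, capped at 1 Mb from the basal
edge and clipped to the chromosome. Basal domains are never truncated;
a neighbouring basal domain overlapping ours blocks extension on that
side. The 1 Mb cap is measured from the basal edge (measuring from the
TSS differs by at most the basal half-width and is not separately
implemented).

Genes are sorted by the *qualifying* sites in their extended domains —
species-specific oCGIs inside same-species-specific peaks only — into
the A-only set, B-only set, mixed set (excluded from testing) and
background set. Expression is TPM from counts and exonic lengths
(rate = counts / exon_kb, scaled to sum to 1e6 per species). For each
gene r = log2(TPM_A / TPM_B); genes with zero TPM in either species are
dropped without pseudocounts and their count reported. Each test set's
median r is compared with resamples from the background matched in size
and in decile-bin composition of mean log2 TPM; the observed median is
normalized by subtracting the median of resampled medians (subtraction
in log space; division in linear space is the equivalent alternative),
with doubled one-sided add-one p-values and BH across the tested sets.
Each set's resampling stream is seeded identically, which makes the
sign symmetry of the test exact: swapping the two species negates every
normalized median to floating-point precision.

## The synthetic study

The generator plants every effect the statistical stages estimate, so
each stage has a parameter-recovery test against sidecar truth rather
than against re-derived labels.

- **Genomes.** Background sequence is i.i.d. at 40% GC with CpGs
  thinned to 0.25x the independence expectation (G -> A/T at destroyed
  CpGs), mimicking mammalian CpG depletion so caller specificity is
  actually exercised. Islands (400 bp, 60% GC, O/E target 1.0 by
  default) are i.i.d. sequence whose CpG count is then tuned to the
  target O/E — surpluses destroyed by composition-preserving CG -> GC
  swaps, deficits filled by planting CGs at positions that create
  exactly one new CpG — achieving the target within +-0.05. Optional
  soft-masked blocks are lowercased and recorded.
- **Species pairs.** Species A and B derive from a human anchor genome:
  islands planted absent in a species are degraded there by CpG -> TpG
  transitions (the deamination path, keeping sequence alignable), and
  background indels (rate 0.05/kb, <= 50 bp) break the coordinate maps
  into blocks. Turnover fractions default to 0.4 shared / 0.3 A-only /
  0.3 B-only.
- **Peaks.** Peak specificity labels are drawn from a joint
  distribution constructed so that, conditional on a peak being
  present, the matching species-specific diagonal cells are enriched
  exactly `peak_coupling_odds`-fold over the product of marginals,
  while the no-peak column stays independent of the oCGI label — so
  the grid test's population enrichment equals the planted odds, and
  odds 1 is exact independence. Signals are log-normal, multiplied by
  `signal_boost_at_ocgi` at oCGI-containing peaks; read counts are
  Poisson draws consistent with the signal as RPKM. Background peaks
  avoid oCGI sites by default (so they cannot contaminate planted
  labels); overlap-null studies place them fully independently.
- **Expression.** Per-gene counts are sums of 4 replicate
  negative-binomial draws (dispersion 0.05, log-normal base means),
  emulating a replicated RNA-seq experiment; genes planted in the
  A-only set get a 2^effect mean boost in species A (mirrored for B).
  Planted qualifying sites sit inside their gene's basal domain so the
  GREAT assignment recovers the planted sets exactly when TSSs are
  spaced.
- **Enhancers.** HGEs draw patterns with the human-only probability
  multiplied by `hge_pattern_multiplier` (renormalized) and signals
  from a log-shifted distribution, so the signal matching is genuinely
  exercised. Pattern probabilities are independent of signal within
  each group — real enhancers likely violate this, which the matching
  would absorb.

What the generator does **not** emulate: repeat families and
transposons (masking is plain lowercase blocks), inversions or
translocations (maps are co-linear by construction), GC-biased gene
conversion, replicate-level peak reproducibility (peaks arrive as
final reproducible sets), promoter/exon annotation in the synthetic
genomes (the feature-exclusion logic is tested on constructed
fixtures instead), and signal-dependent pattern frequencies. Passing
tests therefore demonstrate correctness and calibration of the
*procedures* under the planted statistical structure, not performance
on real genomes.

## Study sizes and runtimes

The packaged validation studies are sized to run on one CPU in minutes:
caller validation on 10 Mb (acceptance script) or 2 Mb (test suite);
turnover recovery over 500 islands; grid calibration over 200 (script)
or 120 (suite) replicate datasets of 2,000 sites at 300–500 permutation
rounds, with power runs at 1,000 rounds; shuffle validity over 1,000
rounds; expression studies of 600 genes with 80-gene test sets (the
median's sampling error, about 0.07 log2 units, must sit well inside
the 0.15 recovery tolerance); HGE studies of 300 HGEs against 3,000
background enhancers. The reference round counts for real analyses
(20,000 for shuffle and grid, 10,000 for the resampling tests) remain
the defaults on the public functions and the CLI.

## Known limitations

- The windowing caller matches the published description's
  post-conditions (thresholds, growth/backoff, local maximality), not
  byte-identity with the historical implementation it paraphrases.
- One-to-many projections (one oCGI splitting over two anchors) are
  dropped as non-co-linear and logged, not resolved.
- The shuffle's rejection sampler can fail on pathologically crowded
  chromosomes; it fails loudly rather than biasing placements.
- BH families are whatever the caller pools; the packaged analyses
  correct within test (9 grid cells, 8 patterns, 2 gene sets) and
  record the family in their output.
- Unmapped O/E values default to 0 in the minimal-difference filter,
  which maximizes differences; supplying sequence for absent species
  is strictly better.
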