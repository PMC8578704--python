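# Methods

## Scope and model

chronolink re-implements, as a tested pipeline over synthetic data, the
downstream integration of an acute-depletion chromatin time course: (i)
per-site first-change classification from differential tables, (ii)
interval linkage of changes to gene windows, (iii) cohort/quintile
enrichment scored with the hypergeometric point probability, and (iv)
nucleosome-midpoint barrier profiling around transcription-factor
motifs. Upstream steps (alignment, peak calling, differential testing,
motif discovery) are out of scope: the pipeline consumes their outputs,
and the synthetic-data module emulates those outputs directly.

## Time grid and differential gates

All tables carry log2 fold change and FDR at t ∈ {2, 6, 18, 54, 162} h
versus 0 h. Gates are per-assay configuration, never hard-coded:
fold change > 1.5 (strict inequality on |log2FC| > log2 1.5 ≈ 0.585)
with FDR < 10⁻⁵ for accessibility and histone marks; fold change > 1.2
with FDR < 0.2 for EP300 occupancy; FDR < 0.05 (no fold-change gate) for
expression. A site's direction is fixed by the sign at its first
qualifying time point; later sign reversals do not reclassify. This
makes classification monotone: relaxing either gate can only move the
first change earlier.

## Synthetic data: what is emulated

The generator plants one chromosome (200 Mb default) carrying 2,000
genes with minimum TSS spacing 20 kb. Each gene draws a trajectory class
with proportions {early_down .04, early_up .16, late_down .02,
late_up .13, stable .65}; early classes switch at 2 or 6 h (equal
probability), late classes at 18/54/162 h (uniform). Expression follows
a step-at-onset model: log2FC(t) = effect·1[t ≥ onset] + N(0, 0.2), with
effects ±2 (early) and ±1.5 (late). FDR columns are generated directly
rather than via p-values plus correction, because the pipeline consumes
FDR columns produced by out-of-scope callers: changed comparisons draw
log-uniformly around 10⁻⁷ (range 10⁻⁹–10⁻⁶, below every consumer gate),
null comparisons draw a sqrt-skewed value concentrated near 1 (range
0.1–1, ~1% below 0.2), mimicking the pile-up of BH-adjusted q-values of
unchanged features at the top of the unit interval.

Chromatin sites come in two populations. *Coupled* sites: a
`linked_site_rate` = 0.8 fraction of changed genes receives one site
uniformly inside the enhancer window (±50 kb of the TSS, outside
±500 bp). Down-regulated genes lose accessibility there at the gene's
onset; for early-down genes, a `dual_loss_fraction` = 0.5 of those sites
also lose EP300 at the same interval — the dual signature is tied to the
early/direct response, while late-down coupling is accessibility-only.
Up-regulated genes gain EP300 and H3K27ac within ±2 kb of the promoter.
*Background* sites are Poisson-placed genome-wide: stable sites at
20 per Mb per assay, plus changed-but-uncoupled sites (accessibility
lost 7.0/Mb, gained 2.0/Mb; EP300 lost 7.0/Mb; dual lost 0.8/Mb; H3K27ac
lost 3.0/Mb) with uniformly random first-change times. At these rates
roughly half of all genes carry some lost-accessibility site within
50 kb and ~8% carry a background dual-loss site, so adjacency alone is
common and only the *enrichment* above that background is informative —
the property the hypergeometric scoring is meant to expose. Every site
records its planted kind, direction, onset and coupled gene.

Nucleosome fragments: at each of 200 motif positions (Poisson depth,
mean 400 reads), fragment midpoints draw from a mixture of a central
barrier component N(0, central_sd²) with weight 0.25 and six flanking
components at ±(d₀ + k·repeat), k = 0..2 (per-side weights 0.5/0.3/0.2
of the flank mass, sd 30 bp, repeat 186 bp). When d₀ is not set
explicitly it follows the barrier model: d₀ = central_sd·√(2 ln 2) +
138.8 bp — the barrier's half-width at half maximum plus half a
nucleosome (73 bp) and a short linker — giving 180 bp at the default
central sd of 35 bp and, deliberately, a larger d₀ whenever the barrier
broadens. The depleted condition raises the central weight by 0.20 and
doubles the flank sd, emulating reads accumulating over the factor
binding site and degraded flank phasing.

What the generator does *not* emulate: replicate structure, GC or
mappability bias, raw reads, correlated FDR/fold-change errors,
multi-chromosome genomes (supported but not default), peak-width
heterogeneity, and genuinely ambiguous sites (lost-then-gained
trajectories are absent by construction). Passing tests therefore show
that the pipeline recovers structure of this planted form at these
noise levels — not that the upstream callers would produce such tables
from real libraries.

## Linkage and annotation conventions

Coordinates are 0-based half-open; overlap means ≥ 1 shared base.
Enhancer windows are TSS-centred (±50 kb minus the promoter), symmetric,
and strand-independent; a site may link to several genes, and promoter
versus enhancer linkage is exclusive per (gene, site) pair. Histone
genes are excluded via an explicit input flag (no name matching).
Change-set intersection reports, for each input set, the intervals
overlapping the other set, so "both" counts are per-input-interval.
Consensus filtering retains regions where peaks from ≥ k distinct
replicates share a base (in 1D pairwise mutual overlap of k intervals is
equivalent to a common base), and the output interval spans the union of
all contributing peaks. State annotation assigns each site to the
maximally overlapping segment, ties to the leftmost.

## Enrichment

Quintiles sort genes ascending by log2FC at the cohort's reference time
(6 h early, 162 h late; the first-significant time under the per-time
scheme), ties broken by gene id; remainder genes go to the
most-repressed end (11 genes → sizes 3,2,2,2,2). x counts *genes* with
≥ 1 linked change (duplicate sites cannot double-count); counting sites
instead is possible by supplying per-site keys but is not the default,
matching the percent-of-genes framing of the barplots the analysis
mirrors. The headline statistic is the hypergeometric point probability
itself, reported as −log₁₀ PMF; the upper-tail p-value is computed
alongside as a flagged extra, and no multiple-testing correction is
applied across quintiles. Binomial coefficients use log-gamma
arithmetic; for N ≤ 200 the implementation switches to exact integer
arithmetic (`fractions.Fraction`), which is also the path the
enumeration oracle compares against. Inconsistent counts (x > n, x > M,
n − x > N − M) raise rather than returning 0, signalling broken inputs.

## Nucleosome profiles and barrier metrics

Fragment midpoint = floor((start+end)/2) (even-length fragments round
down). Midpoints are summed per base across the ±1000 bp window (2001
offsets) at each motif centre; minus-strand motifs mirror offsets; when
a factor-bound interval list is supplied, motifs are restricted to those
overlapping it. Enrichment divides by (number of motifs × experiment-wide
read count) — the experiment-wide count is taken literally, defaulting
to the size of the supplied fragment table. Smoothing is a 30 bp moving
average whose window shrinks at the array edges; raw, normalised and
smoothed vectors are kept separately.

The figures that motivate d and w define what they denote but not how to
measure them; the operational definitions here are: central maximum =
largest smoothed value within ±100 bp of the centre; w (per side) =
first offset at which the profile falls below half the central maximum;
d (per side) = first local maximum beyond w + 20 bp, detected with a
prominence floor of 5% of the central maximum so single-bin counting
noise in the trough cannot masquerade as a flanking nucleosome. Per-side
values and their means are all reported; w is a per-side half-width, not
a full width. A missing flank peak flags d as NaN instead of raising.
Because a 30-wide (even) kernel cannot be centred symmetrically, metric
extraction smooths each side's outward-oriented unsmoothed profile
identically; this makes left/right metrics exact mirror images under
data mirroring while `smooth_profile` keeps the literal 30-point kernel
(impulse response: a 1/30 plateau spanning 30 offsets). Chem-seq-style
per-base cleavage scores can be fed through the same path by treating
them as pre-aggregated counts.

Condition comparison reports the per-offset difference (B − A) plus two
scalars: the mean difference within ±w of the centre (central gain) and
the change in peak-to-trough range within ±70 bp of each flank peak
(phasing definition).

## Determinism and orchestration

All randomness flows from one `numpy` SeedSequence; generator stages
consume independent child streams, so any stage is reproducible in
isolation and a fixed config yields byte-identical outputs. The
`run-all` manifest records the seed, the full configuration (including
every gate actually applied) and a sha256 per output file; no
timestamps. Sorting everywhere uses stable mergesort with documented
tie-breaks (classification ordering ends with site id, since a dual-loss
pair occupies identical coordinates in two assays). TSV readers parse
floats in round-trip mode so write-then-read reproduces in-memory values
exactly; malformed rows are reported with 1-based line numbers.

## Problem sizes

Defaults were sized so the full study runs in seconds on one core: 2,000
genes / 200 Mb (≈ 20,000 site rows across four assays), 200 motifs ×
400 reads for profiles, 10 seeds for the barrier-recovery sweep. These
sizes keep every planted effect many standard errors from chance while
remaining desk-scale; the genome-scale counts of the motivating study
are not reproducible at this scale and are not targeted.

## Known limitations

- The per-time stacked decomposition uses each site's first-change time;
  a gene is flagged per stratum, not assigned to its earliest stratum.
- `consensus_filter` treats book-ended peaks within one replicate as
  merged for coverage counting (they share no base with each other, but
  coverage is unaffected).
- The EP300-gain and H3K27me3 channels carry little planted structure
  (no background change kinds beyond those listed), so analyses of those
  channels on synthetic data are near-null by construction.
- Enrichment assumes cohort genes are a subset of the transcribed
  universe used for M and N; feeding flags from a different universe
  raises rather than silently renormalising.
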