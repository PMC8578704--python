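# chronolink

Integration analysis for acute-depletion (degron) time courses in
chromatin biology: when a chromatin regulator is degraded and the genome
is sampled at 2, 6, 18, 54 and 162 h, which chromatin changes come first,
which genes do they sit next to, and is that adjacency more than chance?

The package is aimed at computational genomicists who have per-site and
per-gene differential tables (log2 fold change + FDR per time point, as
produced by DiffBind/edgeR-style callers) and BED-style intervals, and
who want the downstream integration — not the upstream alignment, peak
calling or differential testing. Because the motivating datasets are
genome-scale, a first-class synthetic-data module generates all inputs
with *planted*, recoverable structure, so every stage of the analysis is
testable against known truth on a desk.

## What it computes

**First-change classification.** A site's first change time is the
smallest t with |log2FC(t)| > log2(1.5) and FDR(t) < 10⁻⁵ (for EP300
occupancy: fold change > 1.2, FDR < 0.2); its direction (lost/gained) is
the sign at that time. Sites are ordered by direction group, first
change time, then coordinate.

**Window linkage.** A change is promoter-linked to a gene when it
overlaps [TSS−500, TSS+500) by ≥ 1 bp, and enhancer-linked when it
overlaps [TSS−50 kb, TSS+50 kb) but not the promoter (0-based half-open
coordinates; histone genes excluded because they cluster within 50 kb).

**Cohorts and enrichment.** Genes first significant (FDR < 0.05) at
2–6 h form the early cohort, later genes the late cohort; each cohort is
split into fold-change quintiles (quintile 1 = most repressed 20%). A
control set is the 500 never-significant genes with the smallest maximum
squared log2FC. Each quintile's chromatin-change burden is scored with
the hypergeometric point probability

```
P(X = x) = C(M, x) · C(N − M, n − x) / C(N, n)
```

with x = quintile genes carrying the change, n = quintile size, M =
genes carrying the change among all N transcribed genes; the headline
value is −log₁₀ P, computed in log space so published parameter scales
(N ≈ 12,741, n ≈ 3,089) are exact.

**Nucleosome barrier profiling.** Midpoints of nucleosome-protected
fragments are summed per base over ±1 kb around transcription-factor
motifs, normalised by motif count × experiment-wide reads, and smoothed
with a 30 bp moving average. From the profile: w, the per-side
half-width at half maximum of the central (barrier) dyad distribution,
and d, the distance from the motif centre to the first flanking
nucleosome peak. Broadly distributed barrier nucleosomes push flanking
nucleosomes outward (larger w ⇒ larger d).

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic conditions (2,000 genes on a 200 Mb chromosome; 80% of changed
genes carry a coupled enhancer-window site; half of the early-repressed
coupling loses both accessibility and EP300):

```
python analysis/01_simulate.py --seed 1
python analysis/02_classify_sites.py
python analysis/03_link_changes.py
python analysis/04_cohort_enrichment.py
python analysis/05_nucleosome_profiles.py
```

Key lines of output (seed 1):

```
accessibility  fc>1.5  FDR<1e-05    1971/5849 changed, 100.00% exact recovery of planted calls
EP300          fc>1.2  FDR<0.2      2084/5981 changed, 99.63% exact recovery of planted calls
most-repressed early quintile (q1) vs control:
  accessibility_lost   q1  89.4% (-log10 PMF 11.17)   control  52.6% (-log10 PMF  2.01)
  ep300_lost           q1  70.6% (-log10 PMF  3.11)   control  55.0% (-log10 PMF  1.40)
  dual_lost            q1  45.9% (-log10 PMF 15.87)   control  10.0% (-log10 PMF  1.44)
t0        80223 reads at 200 motifs: d = 181.5 bp (L 182/R 181), w = 44.0 bp (L 44/R 44)
```

Reading: the classifier recovers essentially every planted change call.
EP300 loss is frequent but unenriched at repressed genes; accessibility
loss is enriched; *dual* loss (accessibility + EP300 at the same locus)
is rarest yet by far the most strongly concentrated at the most-repressed
early genes (−log₁₀ PMF ≈ 16 versus ≈ 1.4 for the control cohort), and
its ~46% quintile-1 rate matches the planted 0.8 × 0.5 coupling plus
background. The barrier metrics recover the planted geometry (central sd
35 bp ⇒ w ≈ 41–44 bp after 30 bp smoothing; flanks planted at 180 bp ⇒
d ≈ 181 bp).

The same pipeline is available as a CLI
(`chronolink simulate|classify|link|enrich|nucprofile|run-all`); a
`run-all` with a fixed seed writes a manifest with per-file checksums and
is byte-reproducible.

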