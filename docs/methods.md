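# Methods

## Renaturation and digestion model

Normalization is modeled in three steps.

1. **Renaturation.** Each sheared fragment belongs to a *duplex class*:
   the set of molecules it can renature with (the copies of a repeat
   family, a gene family, an organelle genome, or — for unique sequence —
   essentially itself). A class at relative concentration $c$ follows
   ideal second-order C₀t kinetics, so after $t$ hours the duplexed
   fraction is $f = kct/(1+kct)$ with rate
   $k = k_0\exp(\alpha_{GC}(g-0.5))$, $g$ the fragment GC fraction.
2. **Digestion.** DSN removes duplexes: a read survives independently
   with probability $1-f$ evaluated for its source fragment. An empty
   survivor set raises an explicit over-normalization error.
3. **Re-amplification.** Survivors are resampled with replacement to a
   fixed target depth. No PCR noise model is attached; multinomial
   resampling is what produces the signature relative enrichment of
   low-copy sequences without changing their absolute survival.

Closed-form expectations (`expected_depletion_table`) renormalize the
per-class survival so the treated composition sums to one; the
control/treated ratio is therefore $>1$ for high-copy classes and $<1$
(apparent enrichment) for low-copy ones, and is nondecreasing in copy
number at fixed GC.

### Rate-parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| $k_0$ (NaCl) | 10 | per (relative conc · hour) | places the 22 h time point in the partially-renatured regime for classes at percent-level concentration |
| $k_0$ (TMAC) | 4 | same | TMAC equalizes pairing at roughly the AT-pair rate, so its flat rate sits below the NaCl rate for GC-rich fragments and above it for AT-rich ones; this reproduces the observed ordering in which NaCl reduces most repeats slightly more than TMAC while AT-rich simple repeats go the other way |
| $\alpha_{GC}$ (NaCl) | 8 | per GC fraction | gives an ~11× rate spread between 30% and 60% GC, the magnitude implied by observed exponential GC-depletion curves |
| $\alpha_{GC}$ (TMAC) | 0 | — | TMAC removes the GC dependence |
| $t$ | 22 h (gDNA), 5 h (RNA) | hours | the study designs being emulated |

$k_0$ and $t$ enter only as a product; `fit_kinetics` therefore recovers
$(k_0 t, \alpha_{GC})$ by least squares on log depletion ratios, with
optional inverse-variance weights $1/\sqrt{1/n_c + 1/n_t}$ (delta-method
variance of a log count ratio) so sparsely counted classes do not dominate.
Weighted recovery at $10^5$ reads per library is accurate to a few percent.

## Synthetic data generator

`build_genome` plants repeat families (each copy independently mutated at
the family's divergence rate; substitutions only, no indels, so identity
arithmetic stays exact) and genes (exact copies) in random order between
background spacers, records every copy in a 0-based half-open feature
table with strand, and generates organelle genomes as 2 kb GC-mosaic
blocks (±12 GC points around the organelle mean) — the regional GC
variation that a tiling analysis resolves. Organelle read fractions
default to 16.8% chloroplast and 2.4% mitochondrion.

`fragment_source` shears to log-normal lengths (σ_log = 0.35, mean 300 nt,
truncated to [100, 900]; molecules at or below the mean shear to full
length). Genomic class abundance is automatically proportional to copy
number because copies occupy sequence; transcript abundance comes from a
log-normal expression profile (σ = 2.0, spanning ~4 orders of magnitude,
the dynamic range over which normalization is visible).

Duplex-class concentration is derived from class mass share as
`share × mean_len / max(unique_len, mean_len)`, where `unique_len` is the
distinct-sequence extent of the class: the tandem *period* for simple
repeats (a (TTTAGGG)ₙ array renatures in any register), the unit/CDS
length for repeat families and genes, the genome length for organelles and
background. Two deliberate corrections keep the scaled model honest:

* fragments are assigned to the feature with the largest overlap (≥30% of
  the fragment) rather than by midpoint, so array-border fragments do not
  masquerade as slow-renaturing unique sequence;
* organelle concentrations carry an explicit boost factor (default 30):
  organelle genomes are present at hundreds of copies per cell, and a
  nuclear genome scaled down ~1000× would otherwise compress the
  organelle-vs-single-copy concentration ratio far below reality.

Reads are single-end, uniform-strand, with i.i.d. substitution errors and
an optional quality-failure model: with probability `b_tail_prob` the
Phred+33 quality string switches to 'B' at a uniform position and stays
'B' to the read end.

## Analysis components

* **QC**: trimming keeps the prefix strictly before the first 'B' (the
  base under the first failure glyph is discarded — the conservative
  reading); length (40–80 nt) and GC (20–80%) windows are closed
  intervals. Trimming is idempotent and always yields a prefix.
* **Mapper**: exact k-mer seeds (default k=12, every read offset, both
  strands) propose diagonals; extension is ungapped; identity =
  matches/aligned columns over ≥75% of the read; presets 0.98
  ("stringent") and 0.80 ("weak"), thresholds inclusive. Each read counts
  once at its best hit; ties break by lower reference index, leftmost
  position, then + strand. Reads shorter than k fall back to an
  exhaustive scan. Ungapped alignment is exact for this generator (no
  indels); heavily mutated reads whose every k-mer is broken can be
  missed, which matters only far below the identity thresholds used.
* **GC tiling**: 500-nt windows stepping 490 (10-nt overlap) from
  position 0, plus an end-anchored final window when an uncovered tail of
  ≥50 nt remains. Ratios use a pseudocount of 1 on the treated side only
  when treated = 0; the exponential fit is unweighted least squares of
  ln(ratio) on GC over windows with both counts positive; per-5%-bin
  two-tailed one-sample t-tests act on ln(ratio).
* **Histograms and D statistic**: read GC categories are integer percent
  (floor); the Wilcoxon signed-rank pairing unit is the GC category.
  D = (A−B)/(A+B) is excluded (not zeroed) when both RPKMs vanish;
  coverage strata are defined on the mean RPKM of the two libraries, and
  the pipeline places stratum bounds at the panel's terciles so the
  low/medium/high split matches simulated depth.
* **Abundance bins**: 24 equal-count (quantile) bins on log₁₀ control
  RPKM (sizes differ by ≤1); fold changes use a 0.1-RPKM pseudocount on
  both sides; significance is a two-tailed one-sample t-test of the log
  fold change at p < 0.01. Whiskers are Q1−1.5·IQR and Q3+1.5·IQR.
* **Copy number**: reads-per-copy is the mean mapped count over known
  single-copy genes; estimated copies = count/coverage; log-spaced bin
  edges (1, 2, 5, … 2000) bracket the enrichment-to-depletion transition.
* **Gene set**: translated exact 8-mer seeds against the protein set
  anchor maximal stop-free six-frame windows (≥min_codons); duplicates
  are removed greedily longest-first at ≥90% identity over ≥80% of the
  shorter (edlib edit distance, both orientations, full and central
  fractions of the shorter); "single copy" requires uniqueness in the set
  (<60% identity over half-length), an ATG start, and exactly one
  gene-space locus at weak stringency (repeated best-hit search with
  masking).
* **Repeat consensus**: canonical 30-mer counts; seeds ranked by count
  then lexicographically, discarded below 10 occurrences; extension
  recruits reads containing the current window *exactly* (either
  orientation), votes columns beyond it, and appends the majority base
  while depth ≥5 and majority ≥0.6 (ties in fixed A<C<G<T order), sliding
  the window to the terminus until growth stops; the left end is extended
  as the right extension of the reverse complement. Merging is greedy
  longest-first over end-overlaps (≥50 nt at ≥95% identity) and
  containments, taking the deeper pileup's base at overlap columns.
  Everything is deterministic for fixed inputs.

## Scaled study conditions

Default scenarios run at desk scale: a ~2 Mb nuclear genome (simple
repeats as tandem-array blocks, centromeric/rDNA/pol-like families,
48 single-copy genes and a 2–1000-copy gene-family ladder), 40–60 k
fragments, 40–100 k reads. These sizes preserve the phenomena — organelle
fractions, GC-slope flattening (TMAC slope a few percent of NaCl),
the copy-number transition (enrichment through ~100 copies, depletion by
~200–1000), abundant-depleted/rare-enriched transcript bins, ≥99%
consensus recovery — while keeping any analysis under a minute or two.

What the scaling does *not* preserve: absolute depletion magnitudes. A
real 2.7 Gb genome gives single-copy loci concentrations ~10³× lower than
a 2 Mb surrogate, so fold reductions here are compressed (telomere ~2×
rather than hundreds-fold; mitochondrial reads can even enrich relative
to a repeat-heavy nuclear background, whereas a sparse real genome shows
them declining). The bundled published count tables carry the real-scale
numbers, and all ratio/percentage arithmetic on them is recomputed by the
package's own statistics. Passing simulation tests therefore demonstrates
the model's mechanics and the analysis code's correctness, not real-data
effect sizes.

## Other numerical choices

* Printed-table ratios round half-up (1.125 → 1.13), matching table
  conventions; a treated count of zero flags the reduction as infinite
  rather than producing a number.
* GC content excludes ambiguity codes from the denominator and is
  undefined (error) for all-ambiguous sequences.
* Boundary inclusivity everywhere ("40–80 nt", "≥98%") is closed.
* Coordinates are 0-based half-open with +/− strand throughout; FASTQ is
  Phred+33 with 'F' as the pass glyph and the literal 'B' as failure.
* Fixed seeds make every generator and pipeline output byte-identical
  across runs; each run log records seed and settings.

## Known limitations

* Cross-hybridization between diverged copies is not modeled: divergence
  reduces realized identity of planted copies but all copies of a family
  share one duplex class. A divergence-to-effective-concentration mapping
  is left as a config hook (off by default).
* No indels, no paired-end inserts, no position- or motif-dependent error
  profiles; no thermodynamic melting or enzyme-efficiency model.
* The mapper does not emit SAM and does not weight multi-mapped reads;
  family counts aggregate at the best exemplar hit.
* RPKM in treated libraries is normalized per mapped read of the
  reference set in question, so genome-composition shifts after
  normalization inflate absolute enrichment values relative to
  whole-library normalization; transitions and orderings are unaffected.
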