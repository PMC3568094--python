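# dsnnorm

Simulation and analysis of sequencing-library normalization with a
duplex-specific nuclease (DSN).

## The problem

Transcriptomes and plant genomes are dominated by a small number of
high-copy sequences: abundant transcripts, ribosomal RNA genes, organelle
DNA (chloroplast reads can be ~17% of a plant gDNA library), telomeric and
satellite repeats, and retrotransposon families with thousands of copies.
DSN normalization exploits renaturation kinetics to strip these out:
the library is denatured, allowed to renature — high-copy fragments find
complementary partners fast — and the double-stranded fraction is digested
by a duplex-specific nuclease before the survivors are re-amplified. The
net effect is depletion of the high-copy fraction and *relative* enrichment
of single- and low-copy sequences. Renaturation in 0.5 M NaCl is GC-biased
(GC-rich fragments pair faster and are over-depleted); 3 M
tetramethylammonium chloride (TMAC) equalizes AT and GC pairing rates and
flattens that bias.

This package is for anyone who wants to reason quantitatively about such
protocols: it pairs a ground-truth synthetic data generator (genomes with
repeat families across 1–1000+ copies, organelle contamination, log-normal
expression, quality-failure tails) with the analysis toolchain used to
characterize normalized libraries.

## The model

A fragment class at relative concentration $c$ renatures under
second-order C₀t kinetics; after $t$ hours the duplexed (hence digested)
fraction is

$$f = \frac{kx}{1+kx},\qquad x = c\,t,\qquad
  k = k_0\, e^{\alpha_{GC}(g-0.5)}$$

with $g$ the fragment GC fraction, $\alpha_{GC}>0$ in NaCl and
$\alpha_{GC}=0$ in TMAC. Each read survives with probability $1-f$;
survivors are multinomially resampled to fixed depth (re-amplification),
which converts absolute depletion of abundant classes into apparent
enrichment of rare ones. Around this core sit: 'B'-tail quality trimming
and length/GC read filters; a k-mer-seeded ungapped mapper (identity
presets 98%/80%, 0.75 overlap) with RPKM/reduction/enrichment statistics;
500-nt/10-nt-overlap GC tiling with exponential depletion fits
$y=ae^{bg}$; abundance binning and copy-number estimation calibrated on
single-copy genes; uninterrupted-ORF (QC set) extraction; and repeat
discovery by abundant-30-mer seeded consensus extension.

## Worked example

`analysis/03_salt_comparison.py` simulates one genomic library, normalizes
it after 22 h renaturation in either salt, and prints:

```
GC-depletion slope: NaCl b=0.0656, TMAC b=0.0029 (4.4% of NaCl - flattened)
mean read GC, TMAC - NaCl: +1.53 points (Wilcoxon p=0.553)
stratum  n_genes     slope      p_value
    low       50 -0.018330 4.965028e-12
 medium       50 -0.015794 1.890364e-01
   high       50 -0.009580 9.630240e-15
```

Reading this: in NaCl the control/treated count ratio of chloroplast
tiling windows grows exponentially with GC (b = 0.066 per GC point — a
window at 45% GC is depleted ~2.7× more than one at 30%); in TMAC the
fitted slope collapses to ~4% of that, i.e. depletion becomes
GC-independent. Consequently the TMAC library's mean read GC sits ~1.5
points above the NaCl library's, and the per-gene differential-abundance
statistic D = (RPKM_NaCl − RPKM_TMAC)/(RPKM_NaCl + RPKM_TMAC) falls with
GC in every coverage stratum (negative slopes): GC-rich genes are better
represented after TMAC normalization.

The other drivers follow the same pattern: `01` transcriptome
normalization (abundant transcripts depleted, rare enriched),
`02` renaturation time course (progressive organelle reduction),
`04` copy-number transition (single-copy genes enriched ~5×, transition to
depletion between ~50 and ~1000 copies), `05` repeat-consensus discovery
(planted unit recovered at ≥99% identity), `06` QC gene set and
single-copy identification.

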