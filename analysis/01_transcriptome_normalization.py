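#!/usr/bin/env python
"""Control vs DSN-normalized RNA-Seq libraries of a simulated transcriptome.

Simulates a log-normal expression profile, normalizes by renaturation (5 h,
NaCl) + DSN digestion + re-amplification, and summarizes per-abundance-bin
fold changes. Finding: transcripts in the top abundance bins are depleted,
the long tail of rare transcripts is enriched, reproducing the boxplot
pattern of normalized RNA-Seq libraries.
"""

from pathlib import Path

from dsnnorm.pipeline import run_transcriptome

OUT = Path("results/transcriptome")
OUT.mkdir(parents=True, exist_ok=True)

res = run_transcriptome(seed=1)
for name in ("per_gene", "abundance_bins", "binned_means"):
    res[name].to_csv(OUT / f"{name}.tsv", sep="\t", index=False,
                     float_format="%.6g")

bins = res["abundance_bins"]
rare = bins["mean_fold"].iloc[:6].mean()
top = bins["mean_fold"].iloc[-1]
print(f"rare transcripts (bottom 6 bins): mean fold change {rare:.2f} "
      f"(enriched)")
print(f"most abundant bin: mean fold change {top:.2f} "
      f"(depleted {1 / top:.1f}x)")
print(f"significant bins (p<0.01): {int(bins['significant'].sum())}/24")
print(f"tables in {OUT}/")
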