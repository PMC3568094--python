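"""Published count tables bundled as worked-example inputs.

Three small tables of mapped-read counts from the lettuce/Arabidopsis
normalization experiments ship with the package. They are *inputs*: the
derived columns those studies printed (reduction factors, enrichment
ratios, percentages remaining) are recomputed here from the raw counts with
this package's statistics, which makes the arithmetic mechanically
checkable.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mapping import enrichment_factor, reduction_factor


def _load(name: str) -> pd.DataFrame:
    with resources.files("dsnnorm.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def repeat_counts() -> pd.DataFrame:
    """Mapped reads (out of 28M) of lettuce repeat references in control,
    DSN+NaCl and DSN+TMAC genomic libraries, with recomputed reductions."""
    df = _load("lettuce_repeat_counts.tsv")
    df["reduction_nacl"] = [reduction_factor(c, t)
                            for c, t in zip(df["control"], df["nacl"])]
    df["reduction_tmac"] = [reduction_factor(c, t)
                            for c, t in zip(df["control"], df["tmac"])]
    return df


def repeat_totals() -> dict[str, float]:
    df = _load("lettuce_repeat_counts.tsv")
    tot = df[["control", "nacl", "tmac"]].sum()
    return {
        "control": float(tot["control"]), "nacl": float(tot["nacl"]),
        "tmac": float(tot["tmac"]),
        "reduction_nacl": reduction_factor(tot["control"], tot["nacl"],
                                           decimals=2),
        "reduction_tmac": reduction_factor(tot["control"], tot["tmac"],
                                           decimals=2),
    }


def pfam_enrichment() -> pd.DataFrame:
    """Reads/kb of the most abundant Pfam-domain gene families, with
    recomputed normalized/control enrichment ratios."""
    df = _load("lettuce_pfam_perkb.tsv")
    df["enrichment_nacl"] = [enrichment_factor(n, c) for n, c in
                             zip(df["per_kb_nacl"], df["per_kb_control"])]
    df["enrichment_tmac"] = [enrichment_factor(t, c) for t, c in
                             zip(df["per_kb_tmac"], df["per_kb_control"])]
    df["ratio_nacl_tmac"] = [enrichment_factor(n, t) for n, t in
                             zip(df["per_kb_nacl"], df["per_kb_tmac"])]
    return df


def organelle_timecourse() -> pd.DataFrame:
    """Arabidopsis organelle read counts over the NaCl renaturation time
    course, with percent-of-control remaining."""
    df = _load("arabidopsis_organelle_timecourse.tsv")
    for col in ("chloroplast_reads", "mitochondrion_reads"):
        ref = df.loc[df["hours"] == 0, col].iloc[0]
        df[col.replace("_reads", "_pct_of_control")] = 100.0 * df[col] / ref
    return df
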