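"""GC-stratified depletion analysis.

Three views of GC bias in normalized libraries:

* a tiling-window analysis of a reference (500 nt windows overlapping
  10 nt): per-fragment control/treated count ratios vs GC, an exponential
  fit y = a*exp(b*gc), and per-5%-GC-bin t-tests;
* read GC histograms of two libraries (integer-percent categories) with the
  mean-GC shift and a matched-pairs Wilcoxon signed-rank test over
  categories;
* a per-gene differential-abundance statistic
  D = (rpkm_A - rpkm_B) / (rpkm_A + rpkm_B) in [-1, 1], regressed on GC
  within coverage strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc import gc_content
from .synth import ReadLibrary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TileFragment:
    ref_id: str
    start: int
    end: int
    gc: float  # percent


@dataclass(frozen=True)
class ExpFit:
    a: float
    b: float
    r2: float


def tile_reference(seq: str, ref_id: str = "ref", window: int = 500,
                   overlap: int = 10, tail_min: int = 50) -> list[TileFragment]:
    """Tiling path of `window`-nt fragments overlapping by `overlap` nt.

    Starts at 0 with step window - overlap; when the loop leaves an
    uncovered tail of >= tail_min nt, a final end-anchored window is added.
    """
    if len(seq) < window:
        raise ValueError("sequence shorter than window")
    step = window - overlap
    tiles = []
    start = 0
    while start + window <= len(seq):
        tiles.append(TileFragment(ref_id, start, start + window,
                                  gc_content(seq[start:start + window])))
        start += step
    covered = tiles[-1].end
    if len(seq) - covered >= tail_min:
        s = len(seq) - window
        tiles.append(TileFragment(ref_id, s, len(seq),
                                  gc_content(seq[s:])))
    return tiles


def fit_exponential(gc: np.ndarray, ratio: np.ndarray) -> ExpFit:
    """Least squares of ln(ratio) on gc: ratio = a * exp(b * gc)."""
    y = np.log(ratio)
    slope, intercept, r, _, _ = stats.linregress(gc, y)
    return ExpFit(a=float(np.exp(intercept)), b=float(slope), r2=float(r ** 2))


def depletion_by_gc(control_counts: np.ndarray, treated_counts: np.ndarray,
                    fragments: list[TileFragment]
                    ) -> tuple[pd.DataFrame, pd.DataFrame, ExpFit]:
    """Per-fragment depletion ratios vs GC, 5%-bin stats, exponential fit.

    The per-fragment ratio is control/treated with a pseudocount of 1 on the
    treated side when treated is 0. The exponential fit uses only fragments
    with both counts positive; per-bin two-tailed t-tests ask whether the
    mean log ratio differs from 0.
    """
    c = np.asarray(control_counts, dtype=float)
    t = np.asarray(treated_counts, dtype=float)
    gc = np.array([f.gc for f in fragments])
    if not (c.size == t.size == gc.size):
        raise ValueError("counts and fragments must be aligned")
    ratio = c / np.where(t == 0, 1.0, t)
    per_frag = pd.DataFrame({
        "ref_id": [f.ref_id for f in fragments],
        "start": [f.start for f in fragments],
        "end": [f.end for f in fragments],
        "gc": gc, "control": c, "treated": t, "ratio": ratio,
    })

    both = (c > 0) & (t > 0)
    if both.sum() < 3:
        raise ValueError("fewer than 3 fragments with positive counts")
    fit = fit_exponential(gc[both], ratio[both])

    edges = np.arange(0, 105, 5)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (gc >= lo) & (gc < hi) if hi < 100 else (gc >= lo) & (gc <= hi)
        sel = in_bin & both
        if not sel.any():
            continue
        logr = np.log(ratio[sel])
        if sel.sum() >= 2 and np.ptp(logr) > 0:
            tstat, pval = stats.ttest_1samp(logr, 0.0)
        else:
            tstat, pval = np.nan, np.nan
        rows.append({
            "gc_bin_lo": lo, "gc_bin_hi": hi, "n_fragments": int(sel.sum()),
            "mean_ratio": float(ratio[sel].mean()),
            "fold_change": float(c[sel].sum() / max(t[sel].sum(), 1.0)),
            "t_stat": float(tstat), "p_value": float(pval),
        })
    return per_frag, pd.DataFrame(rows), fit


# ---------------------------------------------------------------------------
# read GC histograms
# ---------------------------------------------------------------------------

def gc_read_histogram(library_a: ReadLibrary, library_b: ReadLibrary
                      ) -> tuple[pd.DataFrame, float, tuple[float, float]]:
    """Integer-GC-category read percentages for two libraries.

    Returns (per-category table, mean-GC shift B - A, (wilcoxon stat, p))
    where the Wilcoxon signed-rank test pairs the two libraries' percentages
    per GC category.
    """
    if not library_a.reads or not library_b.reads:
        raise ValueError("both libraries must be nonempty")

    def cats(lib: ReadLibrary) -> tuple[np.ndarray, float]:
        gcs = np.array([gc_content(r.seq) for r in lib.reads])
        counts = np.bincount(np.floor(gcs).astype(int), minlength=101)[:101]
        return 100.0 * counts / counts.sum(), float(gcs.mean())

    pa, mean_a = cats(library_a)
    pb, mean_b = cats(library_b)
    table = pd.DataFrame({"gc_category": np.arange(101),
                          "percent_a": pa, "percent_b": pb})
    diffs = pb - pa
    if np.allclose(diffs, 0):
        w = (0.0, 1.0)
    else:
        res = stats.wilcoxon(pb, pa)
        w = (float(res.statistic), float(res.pvalue))
    return table, mean_b - mean_a, w


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def differential_abundance(rpkm_a: np.ndarray, rpkm_b: np.ndarray,
                           gc: np.ndarray,
                           strata_bounds: tuple = (20.0, 40.0, 300.0),
                           gene_ids: list[str] | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene D = (A - B)/(A + B) with per-stratum regression on GC.

    Genes with both RPKMs zero are excluded. Coverage strata are defined on
    the mean RPKM of the two libraries: low < bounds[0],
    medium [bounds[0], bounds[1]), high [bounds[1], bounds[2] or open).
    Per stratum: OLS slope of D on GC and a two-tailed paired t-test of the
    two libraries' RPKM values.
    """
    a = np.asarray(rpkm_a, dtype=float)
    b = np.asarray(rpkm_b, dtype=float)
    gc = np.asarray(gc, dtype=float)
    keep = (a + b) > 0
    a, b, gc = a[keep], b[keep], gc[keep]
    ids = ([gene_ids[i] for i in np.flatnonzero(keep)] if gene_ids
           else [f"g{i}" for i in range(a.size)])
    d = (a - b) / (a + b)
    cov = (a + b) / 2.0

    lo_hi, med_hi = strata_bounds[0], strata_bounds[1]
    cap = strata_bounds[2] if len(strata_bounds) > 2 else np.inf
    stratum = np.where(cov < lo_hi, "low",
                       np.where(cov < med_hi, "medium", "high"))
    in_range = cov <= cap

    records = pd.DataFrame({"gene_id": ids, "gc": gc, "rpkm_a": a,
                            "rpkm_b": b, "D": d, "stratum": stratum})
    rows = []
    for name in ("low", "medium", "high"):
        sel = (stratum == name) & in_range
        if sel.sum() < 3:
            logger.info("stratum %s has < 3 genes; slope omitted", name)
            continue
        slope, intercept, r, p_slope, _ = stats.linregress(gc[sel], d[sel])
        tstat, pval = stats.ttest_rel(a[sel], b[sel])
        rows.append({"stratum": name, "n_genes": int(sel.sum()),
                     "slope": float(slope), "intercept": float(intercept),
                     "slope_p": float(p_slope), "mean_D": float(d[sel].mean()),
                     "t_stat": float(tstat), "p_value": float(pval)})
    return records, pd.DataFrame(rows)
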