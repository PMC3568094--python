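"""Abundance binning and copy-number estimation.

Normalization depletes abundant sequences and (after re-amplification)
relatively enriches rare ones. Two complementary summaries:

* transcript-abundance bins: quantile bins on log10 control RPKM with
  per-bin fold-change boxplot statistics and one-sample t-tests;
* copy-number bins: per-gene copies estimated from mapped counts calibrated
  by the mean count over known single-copy genes, then per-bin mean
  treated/control enrichment and the enrichment-to-depletion transition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FOLD_PSEUDOCOUNT = 0.1  # RPKM added to both sides of a fold change

DEFAULT_COPY_BIN_EDGES = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000, 2000)


def _boxplot_stats(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_lo": float(lo), "whisker_hi": float(hi),
        "n_outliers": int(((x < lo) | (x > hi)).sum()),
    }


def bin_by_abundance(rpkm_control: np.ndarray, rpkm_dsn: np.ndarray,
                     n_bins: int = 24, alpha: float = 0.01) -> pd.DataFrame:
    """Quantile bins on log10 control RPKM with DSN/control fold changes.

    Only genes with control RPKM > 0 enter. Bin sizes differ by at most 1.
    Per bin: boxplot statistics of the fold change (pseudocount 0.1 RPKM on
    both sides), mean fold change, and a two-tailed one-sample t-test of the
    log fold change against 0, flagged significant at p < alpha.
    """
    c = np.asarray(rpkm_control, dtype=float)
    d = np.asarray(rpkm_dsn, dtype=float)
    keep = c > 0
    c, d = c[keep], d[keep]
    if c.size < n_bins:
        raise ValueError("fewer genes than bins")
    fold = (d + FOLD_PSEUDOCOUNT) / (c + FOLD_PSEUDOCOUNT)
    order = np.argsort(np.log10(c), kind="stable")
    rows = []
    for bi, idx in enumerate(np.array_split(order, n_bins)):
        f = fold[idx]
        logf = np.log(f)
        if idx.size >= 2 and np.ptp(logf) > 0:
            tstat, pval = stats.ttest_1samp(logf, 0.0)
        else:
            tstat, pval = np.nan, np.nan
        row = {
            "bin": bi, "n_genes": int(idx.size),
            "rpkm_lo": float(c[idx].min()), "rpkm_hi": float(c[idx].max()),
            "mean_fold": float(f.mean()),
            "t_stat": float(tstat), "p_value": float(pval),
            "significant": bool(pval < alpha) if np.isfinite(pval) else False,
        }
        row.update(_boxplot_stats(f))
        rows.append(row)
    return pd.DataFrame(rows)


def binned_mean_rpkm(rpkm_control: np.ndarray, rpkm_dsn: np.ndarray,
                     min_rpkm: float = 2.0, n_bins: int = 20,
                     genes_per_bin_sample: int = 100,
                     seed: int = 0) -> pd.DataFrame:
    """Per-bin mean RPKM in both libraries over log-spaced control bins.

    Genes with control RPKM < min_rpkm are omitted; at most
    genes_per_bin_sample genes are sampled per bin (all genes when the bin
    is smaller); deterministic for a fixed seed.
    """
    c = np.asarray(rpkm_control, dtype=float)
    d = np.asarray(rpkm_dsn, dtype=float)
    keep = c >= min_rpkm
    c, d = c[keep], d[keep]
    if c.size == 0:
        logger.info("no genes at or above min_rpkm=%s", min_rpkm)
        return pd.DataFrame(columns=["bin", "rpkm_lo", "rpkm_hi", "n_genes",
                                     "n_sampled", "mean_control", "mean_dsn"])
    rng = np.random.default_rng(seed)
    edges = np.logspace(np.log10(c.min()), np.log10(c.max()) + 1e-9,
                        n_bins + 1)
    which = np.clip(np.digitize(c, edges) - 1, 0, n_bins - 1)
    rows = []
    for bi in range(n_bins):
        idx = np.flatnonzero(which == bi)
        if idx.size == 0:
            continue
        if idx.size > genes_per_bin_sample:
            sampled = rng.choice(idx, size=genes_per_bin_sample, replace=False)
        else:
            sampled = idx
        rows.append({
            "bin": bi, "rpkm_lo": float(edges[bi]),
            "rpkm_hi": float(edges[bi + 1]), "n_genes": int(idx.size),
            "n_sampled": int(sampled.size),
            "mean_control": float(c[sampled].mean()),
            "mean_dsn": float(d[sampled].mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def per_copy_coverage(counts: dict[str, float],
                      single_copy_ids: list[str]) -> float:
    """Mean mapped-read count over known single-copy genes (reads/copy)."""
    if not single_copy_ids:
        raise ValueError("single_copy_ids must be nonempty")
    missing = [g for g in single_copy_ids if g not in counts]
    if missing:
        raise KeyError(f"ids missing from counts: {missing[:3]}...")
    return float(np.mean([counts[g] for g in single_copy_ids]))


@dataclass(frozen=True)
class CopyNumberEstimate:
    gene_id: str
    n_mapped: float
    copies: float
    enrichment: float  # treated RPKM / control RPKM


def estimate_copies(control_counts: dict[str, float], coverage: float,
                    rpkm_control: dict[str, float],
                    rpkm_treated: dict[str, float]) -> list[CopyNumberEstimate]:
    if coverage <= 0:
        raise ValueError("per-copy coverage must be > 0")
    out = []
    for gid, n in control_counts.items():
        rc = rpkm_control.get(gid, 0.0)
        rt = rpkm_treated.get(gid, 0.0)
        if rc <= 0:
            continue
        out.append(CopyNumberEstimate(gid, float(n), float(n) / coverage,
                                      rt / rc))
    return out


def enrichment_by_copy_bin(estimates: list[CopyNumberEstimate],
                           bin_edges: tuple = DEFAULT_COPY_BIN_EDGES
                           ) -> tuple[pd.DataFrame, dict]:
    """Mean enrichment per copy-number bin + the transition report.

    Bin i covers [edges[i], edges[i+1]); estimates below edges[0] join the
    first bin, above the last edge the final open bin. The transition report
    names the lowest bin whose mean enrichment falls below 1.
    """
    edges = np.asarray(bin_edges, dtype=float)
    copies = np.array([e.copies for e in estimates])
    enr = np.array([e.enrichment for e in estimates])
    which = np.clip(np.digitize(copies, edges) - 1, 0, edges.size - 1)
    rows = []
    for bi in range(edges.size):
        sel = which == bi
        if not sel.any():
            continue
        hi = edges[bi + 1] if bi + 1 < edges.size else np.inf
        rows.append({
            "bin": bi, "copies_lo": float(edges[bi]), "copies_hi": float(hi),
            "n_genes": int(sel.sum()),
            "mean_enrichment": float(enr[sel].mean()),
            "mean_copies": float(copies[sel].mean()),
        })
    table = pd.DataFrame(rows)
    depleted = table[table["mean_enrichment"] < 1.0]
    report = {
        "transition_bin": int(depleted["bin"].iloc[0]) if len(depleted) else None,
        "transition_copies_lo": (float(depleted["copies_lo"].iloc[0])
                                 if len(depleted) else None),
    }
    return table, report
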