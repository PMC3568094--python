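"""Experiment templates chaining simulate -> normalize -> qc -> map -> analyses.

Three templates mirror the study designs the package models:

* ``transcriptome``: control vs DSN-normalized RNA-Seq library from a
  log-normal expression profile; abundance-bin fold changes.
* ``timecourse``: genomic library renatured in NaCl for 0/22/46/70/94 h;
  organelle and repeat-class depletion over time.
* ``salt_compare``: control vs DSN(NaCl) vs DSN(TMAC) genomic libraries;
  repeat reduction table, chloroplast GC-tiling fits, read GC histograms,
  differential abundance, copy-number enrichment bins.

Default scenario sizes are scaled to desk-top problem sizes (a ~2 Mb
nuclear genome, tens of thousands of reads) while keeping the abundance
structure (repeat copy numbers to 1000, organelle contamination at
16.8%/2.4%, a copy-number ladder of genes) that drives the phenomena.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import gcbias, lib_io, mapping, qc
from .kinetics import KineticsParams, apply_dsn, expected_depletion_table
from .seqs import random_seq
from .synth import (ExpressionProfile, FragmentPool, GeneModel, GenomeConfig,
                    ReadLibrary, RepeatFamily, SyntheticGenome, build_genome,
                    fragment_source, make_gene, read_origins, simulate_reads)

logger = logging.getLogger(__name__)

TIMECOURSE_HOURS = (0.0, 22.0, 46.0, 70.0, 94.0)

# copy-number ladder spanning the enrichment-to-depletion transition
COPY_LADDER = (2, 5, 10, 20, 46, 100, 200, 500, 1000)


# ---------------------------------------------------------------------------
# default scenarios
# ---------------------------------------------------------------------------

def default_genome_config(seed: int, n_single_copy: int = 48) -> GenomeConfig:
    """A plant-like scaled genome: simple repeats, centromeric/rDNA/pol
    families, single-copy genes and a copy-number ladder of gene families."""
    rng = np.random.default_rng(seed)
    pol = make_gene(rng, "pol_cds", 500, 0.42)  # retroelement pol-like ORF
    # simple repeats planted as tandem-array blocks (telomeric and
    # satellite repeats occur in long arrays, so shotgun fragments fall
    # mostly inside them)
    families = [
        RepeatFamily("telomere", "TTTAGGG" * 72, 250, 0.0),
        RepeatFamily("CAA", "CAA" * 168, 75, 0.0),
        RepeatFamily("GAA", "GAA" * 168, 40, 0.0),
        RepeatFamily("centromeric", random_seq(rng, 340, 0.37), 400, 0.02),
        RepeatFamily("rDNA_18S", random_seq(rng, 500, 0.47), 150, 0.01),
        RepeatFamily("rDNA_28S", random_seq(rng, 450, 0.58), 80, 0.01),
        RepeatFamily("pol", pol.cds_seq, 300, 0.05),
    ]
    genes = [make_gene(rng, f"G{i:03d}", int(rng.integers(150, 250)),
                       float(rng.uniform(0.35, 0.55)))
             for i in range(n_single_copy)]
    genes += [make_gene(rng, f"M{c:04d}", 150,
                        float(rng.uniform(0.40, 0.50)), copies=c)
              for c in COPY_LADDER]
    return GenomeConfig(repeat_families=families, genes=genes,
                        background_len=300_000, background_gc=0.36)


def genomic_scenario(seed: int, n_fragments: int = 60_000
                     ) -> tuple[SyntheticGenome, FragmentPool]:
    genome = build_genome(default_genome_config(seed), seed)
    pool = fragment_source(genome, mean_len=300, n_fragments=n_fragments,
                           seed=seed + 1)
    return genome, pool


def transcriptome_scenario(seed: int, n_genes: int = 300,
                           n_fragments: int = 40_000
                           ) -> tuple[dict[str, str], ExpressionProfile,
                                      FragmentPool]:
    rng = np.random.default_rng(seed)
    genes = [make_gene(rng, f"T{i:04d}", int(rng.integers(100, 300)),
                       float(rng.uniform(0.35, 0.55))) for i in range(n_genes)]
    transcripts = {g.gene_id: g.cds_seq for g in genes}
    profile = ExpressionProfile.lognormal(list(transcripts), sigma=2.0,
                                          seed=seed + 1)
    pool = fragment_source(transcripts, expression=profile,
                           n_fragments=n_fragments, seed=seed + 2)
    return transcripts, profile, pool


# ---------------------------------------------------------------------------
# counting helpers (ground-truth-aware; the mapper is used where the
# reference set is the natural analysis target)
# ---------------------------------------------------------------------------

def origin_counts(library: ReadLibrary, pool: FragmentPool) -> dict[str, int]:
    out: dict[str, int] = {}
    for o in read_origins(library, pool):
        out[o] = out.get(o, 0) + 1
    return out


def origin_rpkm(library: ReadLibrary, pool: FragmentPool,
                lengths: dict[str, int]) -> dict[str, float]:
    counts = origin_counts(library, pool)
    total = len(library)
    return {name: mapping.rpkm(counts.get(name, 0), L, total)
            for name, L in lengths.items()}


def tile_counts(library: ReadLibrary, pool: FragmentPool,
                tiles: list[gcbias.TileFragment],
                src_name: str) -> np.ndarray:
    """Reads per tile, assigned by source-fragment midpoint (ground truth)."""
    starts = np.array([t.start for t in tiles])
    counts = np.zeros(len(tiles), dtype=int)
    for r in library.reads:
        f = pool.fragments[r.frag]
        if f.src_name != src_name:
            continue
        mid = f.src_start + len(f.seq) // 2
        i = int(np.clip(np.searchsorted(starts, mid, side="right") - 1,
                        0, len(tiles) - 1))
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def run_transcriptome(seed: int, n_genes: int = 300,
                      n_fragments: int = 40_000, n_reads: int = 40_000,
                      hours: float = 5.0) -> dict:
    """Control vs DSN-normalized RNA-Seq libraries (renaturation in NaCl)."""
    transcripts, profile, pool = transcriptome_scenario(seed, n_genes,
                                                        n_fragments)
    control = simulate_reads(pool, n_reads, read_len=50, err_rate=0.002,
                             seed=seed + 3)
    params = KineticsParams(t=hours, mode="NaCl", target_depth=n_reads)
    dsn = apply_dsn(control, pool, params, seed=seed + 4)

    lengths = {g: len(s) for g, s in transcripts.items()}
    r_c = origin_rpkm(control, pool, lengths)
    r_d = origin_rpkm(dsn, pool, lengths)
    gids = sorted(lengths)
    rc = np.array([r_c[g] for g in gids])
    rd = np.array([r_d[g] for g in gids])
    per_gene = pd.DataFrame({"gene_id": gids, "rpkm_control": rc,
                             "rpkm_dsn": rd,
                             "abundance": [profile.abundance[g] for g in gids]})
    bins = ab.bin_by_abundance(rc, rd, n_bins=24)
    means = ab.binned_mean_rpkm(rc, rd, min_rpkm=2.0, seed=seed)
    return {"per_gene": per_gene, "abundance_bins": bins,
            "binned_means": means}


def run_timecourse(seed: int, hours: tuple = TIMECOURSE_HOURS,
                   n_fragments: int = 60_000, n_reads: int = 50_000) -> dict:
    """NaCl renaturation time course; organelle and repeat depletion."""
    genome, pool = genomic_scenario(seed, n_fragments)
    control = simulate_reads(pool, n_reads, read_len=50, err_rate=0.002,
                             b_tail_prob=0.05, seed=seed + 3)
    libraries = {hours[0]: control}
    for i, t in enumerate(h for h in hours if h > 0):
        params = KineticsParams(t=t, mode="NaCl", target_depth=n_reads)
        libraries[t] = apply_dsn(control, pool, params, seed=seed + 10 + i)

    rows = []
    for t, lib in libraries.items():
        kept = qc.qc_library(lib, qc.QCParams(min_len=40, max_len=50))
        counts = origin_counts(kept, pool)
        label = "0 hrs-DSN" if t == 0 else f"{t:g} hrs+DSN"
        rows.append({"library": label, "hours": t,
                     "reads_total": len(kept),
                     "chloroplast_reads": counts.get("chloroplast", 0),
                     "mitochondrion_reads": counts.get("mitochondrion", 0)})
    organelle = pd.DataFrame(rows)

    # closed-form repeat depletion expectations over the time course
    classes = [(fam.copy_number, np.clip(
        sum(c == "G" or c == "C" for c in fam.unit_seq) / len(fam.unit_seq),
        0, 1)) for fam in genome.families.values()]
    names = list(genome.families)
    frames = []
    for t in hours:
        if t == 0:
            continue
        tab = expected_depletion_table(
            classes, KineticsParams(t=t, mode="NaCl"))
        tab.insert(0, "family", names)
        tab.insert(1, "hours", t)
        frames.append(tab)
    return {"organelle_counts": organelle,
            "repeat_depletion": pd.concat(frames, ignore_index=True)}


def run_salt_compare(seed: int, hours: float = 22.0,
                     n_fragments: int = 60_000, n_reads: int = 60_000,
                     map_sample: int = 20_000) -> dict:
    """Control vs DSN(NaCl) vs DSN(TMAC) genomic libraries."""
    genome, pool = genomic_scenario(seed, n_fragments)
    control = simulate_reads(pool, n_reads, read_len=50, err_rate=0.002,
                             b_tail_prob=0.05, seed=seed + 3)
    libs = {"control": control}
    for i, mode in enumerate(("NaCl", "TMAC")):
        params = KineticsParams(t=hours, mode=mode, target_depth=n_reads)
        libs[mode] = apply_dsn(control, pool, params, seed=seed + 20 + i)
    kept = {k: qc.qc_library(v, qc.QCParams(min_len=40, max_len=50))
            for k, v in libs.items()}

    # repeat reduction table (mapping to family exemplars, weak identity)
    refs = [(name, fam.unit_seq) for name, fam in genome.families.items()]
    params_map = mapping.MappingParams(min_identity=mapping.WEAK)
    tables = {}
    for k, lib in kept.items():
        sub = lib.reads[:map_sample]
        _, tab = mapping.map_reads(sub, refs, params_map)
        tables[k] = tab
    repeat_table = tables["control"][["ref_id", "length", "gc_percent"]].copy()
    for k in ("control", "NaCl", "TMAC"):
        repeat_table[f"n_mapped_{k}"] = tables[k]["n_mapped"]
        repeat_table[f"per_kb_{k}"] = tables[k]["reads_per_kb"]
        repeat_table[f"fraction_{k}"] = tables[k]["fraction_of_library"]
    repeat_table["reduction_NaCl"] = [
        mapping.reduction_factor(c, t) for c, t in
        zip(repeat_table["n_mapped_control"], repeat_table["n_mapped_NaCl"])]
    repeat_table["reduction_TMAC"] = [
        mapping.reduction_factor(c, t) for c, t in
        zip(repeat_table["n_mapped_control"], repeat_table["n_mapped_TMAC"])]

    # chloroplast GC tiling (exponential depletion fits per salt mode)
    tiles = gcbias.tile_reference(genome.organelle_seqs["chloroplast"],
                                  ref_id="chloroplast")
    c_ctrl = tile_counts(kept["control"], pool, tiles, "chloroplast")
    fits = {}
    tile_tables = {}
    for mode in ("NaCl", "TMAC"):
        c_trt = tile_counts(kept[mode], pool, tiles, "chloroplast")
        per_frag, per_bin, fit = gcbias.depletion_by_gc(c_ctrl, c_trt, tiles)
        fits[mode] = fit
        tile_tables[mode] = {"per_fragment": per_frag, "per_bin": per_bin}

    # read GC histograms (TMAC vs NaCl)
    hist, shift, wilcox = gcbias.gc_read_histogram(kept["NaCl"], kept["TMAC"])

    # per-gene differential abundance over a QC-set-like gene panel
    records, slopes = run_diff_abundance(seed, hours=hours)

    return {"libraries": kept, "pool": pool, "genome": genome,
            "repeat_table": repeat_table, "tiles": tile_tables, "fits": fits,
            "gc_histogram": hist, "gc_shift": shift, "wilcoxon": wilcox,
            "diff_abundance": records, "strata_slopes": slopes}


def gene_panel_scenario(seed: int, n_genes: int = 150,
                        n_fragments: int = 40_000
                        ) -> tuple[dict[str, str], FragmentPool]:
    """An equimolar panel of genes spanning 30-60% GC.

    Stands in for the QC set of uninterrupted ORFs onto which the deep
    libraries were mapped: with equal molarity, differential survival
    between salt modes is driven by GC alone.
    """
    rng = np.random.default_rng(seed)
    genes = [make_gene(rng, f"Q{i:04d}", 150,
                       float(rng.uniform(0.30, 0.60))) for i in range(n_genes)]
    transcripts = {g.gene_id: g.cds_seq for g in genes}
    profile = ExpressionProfile({g: 1.0 for g in transcripts})
    pool = fragment_source(transcripts, expression=profile,
                           n_fragments=n_fragments, seed=seed + 1)
    return transcripts, pool


def run_diff_abundance(seed: int, hours: float = 22.0,
                       n_reads: int = 40_000):
    """NaCl-vs-TMAC differential abundance (D statistic) over a gene panel.

    Coverage strata are placed at the terciles of the panel's mean RPKM so
    the low/medium/high split matches the simulated sequencing depth.
    """
    transcripts, pool = gene_panel_scenario(seed)
    control = simulate_reads(pool, n_reads, read_len=50, err_rate=0.002,
                             seed=seed + 3)
    libs = {}
    for i, mode in enumerate(("NaCl", "TMAC")):
        params = KineticsParams(t=hours, mode=mode, target_depth=n_reads)
        libs[mode] = apply_dsn(control, pool, params, seed=seed + 40 + i)
    lengths = {g: len(s) for g, s in transcripts.items()}
    gids = sorted(lengths)
    r_nacl = origin_rpkm(libs["NaCl"], pool, lengths)
    r_tmac = origin_rpkm(libs["TMAC"], pool, lengths)
    a = np.array([r_nacl[g] for g in gids])
    b = np.array([r_tmac[g] for g in gids])
    from .qc import gc_content
    gcs = np.array([gc_content(transcripts[g]) for g in gids])
    mean_rpkm = (a + b) / 2
    q1, q2 = np.percentile(mean_rpkm[mean_rpkm > 0], [33.3, 66.7])
    return gcbias.differential_abundance(a, b, gcs,
                                         strata_bounds=(q1, q2, np.inf),
                                         gene_ids=gids)


def run_copy_number(seed: int, hours: float = 22.0,
                    n_fragments: int = 60_000, n_reads: int = 60_000) -> dict:
    """Copy-number estimation from single-copy coverage + enrichment bins."""
    genome, pool = genomic_scenario(seed, n_fragments)
    control = simulate_reads(pool, n_reads, read_len=50, err_rate=0.002,
                             seed=seed + 3)
    refs = [(g, m.cds_seq) for g, m in sorted(genome.genes.items())]
    params_map = mapping.MappingParams(min_identity=mapping.WEAK)
    _, tab_c = mapping.map_reads(control.reads, refs, params_map)
    counts_c = dict(zip(tab_c["ref_id"], tab_c["n_mapped"]))
    rpkm_c = dict(zip(tab_c["ref_id"], tab_c["rpkm"]))

    single_ids = [g for g, m in genome.genes.items()
                  if m.copies == 1 and counts_c.get(g, 0) > 0]
    coverage = ab.per_copy_coverage(counts_c, single_ids)

    out = {"per_copy_coverage": coverage, "genome": genome}
    for i, mode in enumerate(("NaCl", "TMAC")):
        lib = apply_dsn(control, pool,
                        KineticsParams(t=hours, mode=mode,
                                       target_depth=n_reads),
                        seed=seed + 30 + i)
        _, tab_t = mapping.map_reads(lib.reads, refs, params_map)
        rpkm_t = dict(zip(tab_t["ref_id"], tab_t["rpkm"]))
        estimates = ab.estimate_copies(counts_c, coverage, rpkm_c, rpkm_t)
        bins, report = ab.enrichment_by_copy_bin(estimates)
        est_df = pd.DataFrame([dataclasses.asdict(e) for e in estimates])
        est_df["true_copies"] = [genome.genes[e.gene_id].copies
                                 for e in estimates]
        out[mode] = {"estimates": est_df, "bins": bins, "report": report}
    return out


# ---------------------------------------------------------------------------
# config + driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    template: str = "salt_compare"
    seed: int = 0
    outdir: str = "results/pipeline"
    hours: float = 22.0
    n_fragments: int = 60_000
    n_reads: int = 60_000

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _write_tables(outdir: Path, tables: dict, prefix: str = "") -> None:
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{prefix}{name}.tsv", sep="\t", index=False,
                       float_format="%.6g")
        elif isinstance(obj, dict):
            _write_tables(outdir, obj, prefix=f"{prefix}{name}_")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute a template and write its tables (plus a run log) to outdir.

    Re-running with the same config reproduces byte-identical TSVs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runners = {
        "transcriptome": lambda: run_transcriptome(config.seed),
        "timecourse": lambda: run_timecourse(
            config.seed, n_fragments=config.n_fragments,
            n_reads=config.n_reads),
        "salt_compare": lambda: run_salt_compare(
            config.seed, hours=config.hours,
            n_fragments=config.n_fragments, n_reads=config.n_reads),
        "copy_number": lambda: run_copy_number(
            config.seed, hours=config.hours,
            n_fragments=config.n_fragments, n_reads=config.n_reads),
    }
    if config.template not in runners:
        raise ValueError(f"unknown template: {config.template}")
    try:
        result = runners[config.template]()
    except Exception as exc:  # noqa: BLE001 - named stage failure
        logger.error("stage failure in template %s: %s", config.template, exc)
        raise
    tables = {k: v for k, v in result.items()
              if isinstance(v, (pd.DataFrame, dict))
              and k not in ("libraries", "pool", "genome", "tiles")}
    _write_tables(outdir, tables)
    if "libraries" in result:
        for name, lib in result["libraries"].items():
            lib_io.write_fastq(outdir / f"library_{name}.fastq", lib)
    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"template={config.template} seed={config.seed} "
                 f"hours={config.hours} n_fragments={config.n_fragments} "
                 f"n_reads={config.n_reads}\n")
    return result
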