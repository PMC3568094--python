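"""QC gene set construction: uninterrupted ORFs and single-copy genes.

Candidate coding regions are found by six-frame translation of assembly
contigs, seeded by exact translated 8-mer matches to a supplied protein set
and extended to the maximal stop-free window of the frame. The resulting
regions are de-duplicated, then single-copy genes are called as regions
that are unique within the set, start with ATG, and map to exactly one
locus of the gene-space assembly at weak stringency.

Pairwise identity uses edlib edit-distance alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
from Bio.Seq import Seq

from .seqs import revcomp

SEED_AA = 8  # translated seed length (amino acids)


@dataclass
class CdsRegion:
    contig_id: str
    start: int      # nt, 0-based half-open on the forward contig
    end: int
    strand: str
    frame: int      # 0/1/2 within the oriented contig
    seq: str        # oriented nucleotide sequence (reading direction)
    aa: str
    match_count: int = 0

    @property
    def region_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}({self.strand})"

    @property
    def n_codons(self) -> int:
        return len(self.aa)


@dataclass
class SingleCopyGene:
    region_id: str
    unique_in_set: bool
    atg_start: bool
    single_locus: bool
    n_loci: int = 0
    flags: dict = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return self.unique_in_set and self.atg_start and self.single_locus


def _protein_seed_set(protein_set: dict[str, str]) -> set[str]:
    seeds: set[str] = set()
    for aa in protein_set.values():
        aa = aa.upper().rstrip("*")
        for i in range(len(aa) - SEED_AA + 1):
            seeds.add(aa[i:i + SEED_AA])
    return seeds


def _stop_free_windows(aa: str) -> list[tuple[int, int]]:
    """Maximal stop-free windows as [start, end) codon intervals."""
    out = []
    start = 0
    for i, c in enumerate(aa):
        if c == "*":
            if i > start:
                out.append((start, i))
            start = i + 1
    if len(aa) > start:
        out.append((start, len(aa)))
    return out


def extract_cds_regions(contigs: dict[str, str], protein_set: dict[str, str],
                        min_codons: int = 100) -> list[CdsRegion]:
    """Six-frame CDS candidates seeded by translated 8-mer protein matches.

    A stop-free window of a frame becomes a region when it contains at least
    one exact translated seed match to the protein set and spans at least
    min_codons codons. Regions are ranked by seed match count.
    """
    if not protein_set:
        raise ValueError("protein set must be nonempty")
    seeds = _protein_seed_set(protein_set)
    regions: list[CdsRegion] = []
    for cid, seq in contigs.items():
        seq = seq.upper()
        L = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for frame in range(3):
                n_cod = (L - frame) // 3
                if n_cod < min_codons:
                    continue
                aa = str(Seq(s[frame:frame + 3 * n_cod]).translate())
                for ws, we in _stop_free_windows(aa):
                    if we - ws < min_codons:
                        continue
                    win = aa[ws:we]
                    hits = sum(1 for i in range(len(win) - SEED_AA + 1)
                               if win[i:i + SEED_AA] in seeds)
                    if hits == 0:
                        continue
                    nt_s, nt_e = frame + 3 * ws, frame + 3 * we
                    if strand == "+":
                        start, end = nt_s, nt_e
                    else:
                        start, end = L - nt_e, L - nt_s
                    regions.append(CdsRegion(cid, start, end, strand, frame,
                                             s[nt_s:nt_e], win, hits))
    regions.sort(key=lambda r: (-r.match_count, r.contig_id, r.start))
    return regions


# ---------------------------------------------------------------------------
# pairwise identity (edlib)
# ---------------------------------------------------------------------------

def _identity_over_shorter(a: str, b: str, coverage: float) -> float:
    """Best identity of the shorter sequence (either orientation) aligned
    inside the longer; `coverage` < 1 also tries the central fraction of the
    shorter, modelling partial-coverage duplicates."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0.0
    for frac in {1.0, coverage}:
        trim = int(len(short) * (1 - frac) / 2)
        q = short[trim:len(short) - trim] if trim else short
        if not q:
            continue
        for qq in (q, revcomp(q)):
            res = edlib.align(qq, long_, mode="HW", task="distance")
            if res["editDistance"] >= 0:
                best = max(best, 1.0 - res["editDistance"] / len(qq))
    return best


def dedup_regions(regions: list[CdsRegion], identity_threshold: float = 0.90,
                  coverage_threshold: float = 0.80) -> list[CdsRegion]:
    """Greedy non-redundant set: keep longest first, drop any region at or
    above identity_threshold over coverage_threshold of the shorter."""
    ordered = sorted(regions, key=lambda r: (-len(r.seq), r.region_id))
    kept: list[CdsRegion] = []
    for r in ordered:
        dup = any(_identity_over_shorter(r.seq, k.seq, coverage_threshold)
                  >= identity_threshold for k in kept)
        if not dup:
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# single-copy identification
# ---------------------------------------------------------------------------

def _count_loci(region_seq: str, refs: dict[str, str],
                min_identity: float = 0.80) -> int:
    """Distinct mapping loci of a region across gene-space references:
    repeated best-hit search with masking until identity drops."""
    n = 0
    max_dist = int(len(region_seq) * (1 - min_identity))
    for seq in refs.values():
        target = seq
        while len(target) >= len(region_seq) // 2:
            best = None
            for q in (region_seq, revcomp(region_seq)):
                res = edlib.align(q, target, mode="HW", task="locations",
                                  k=max_dist)
                if res["editDistance"] >= 0 and (
                        best is None or res["editDistance"] < best[0]):
                    best = (res["editDistance"], res["locations"][0])
            if best is None:
                break
            n += 1
            s, e = best[1]
            target = target[:s] + "N" * (e - s + 1) + target[e + 1:]
    return n


def identify_single_copy(regions: list[CdsRegion],
                         gene_space_refs: dict[str, str],
                         set_identity: float = 0.60,
                         set_coverage: float = 0.50) -> list[SingleCopyGene]:
    """Flag regions that are unique in the set, ATG-initiated, and map to a
    single gene-space locus at weak stringency; all three flags must hold."""
    out = []
    for i, r in enumerate(regions):
        unique = all(
            _identity_over_shorter(r.seq, o.seq, set_coverage) < set_identity
            for j, o in enumerate(regions) if j != i)
        atg = r.seq.startswith("ATG")
        n_loci = _count_loci(r.seq, gene_space_refs)
        out.append(SingleCopyGene(r.region_id, unique, atg,
                                  n_loci == 1, n_loci=n_loci))
    return out
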