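"""Read-to-reference mapping and counting statistics.

A lightweight seeded mapper in the style used for short (24-125 nt) reads:
k-mer seeds locate candidate diagonals, extension is ungapped on both
strands, identity is matches over aligned columns, and a read is assigned
to at most one reference (best identity; ties broken deterministically).
Identity presets follow common practice for repeat quantification:
0.98 "stringent" and 0.80 "weak", with a 0.75 read-overlap requirement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .qc import gc_content
from .seqs import revcomp, seq_to_codes
from .synth import Read

STRINGENT = 0.98
WEAK = 0.80


@dataclass
class MappingParams:
    min_identity: float = STRINGENT
    min_overlap: float = 0.75  # fraction of read length that must align
    seed_k: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_overlap <= 1:
            raise ValueError("min_overlap must be in (0, 1]")
        if self.seed_k < 4:
            raise ValueError("seed_k must be >= 4")


@dataclass(frozen=True)
class Assignment:
    read_index: int
    ref_index: int
    ref_id: str
    ref_start: int   # aligned interval on the reference, 0-based half-open
    ref_end: int
    strand: str
    identity: float
    aligned_len: int


class ReferenceIndex:
    """Exact k-mer position index over a reference set."""

    def __init__(self, references: list[tuple[str, str]], seed_k: int):
        if not references:
            raise ValueError("references must be nonempty")
        self.ids = [r[0] for r in references]
        self.seqs = [r[1].upper() for r in references]
        for rid, seq in zip(self.ids, self.seqs):
            if len(seq) < seed_k:
                raise ValueError(f"reference {rid} shorter than seed_k")
        self.codes = [seq_to_codes(s) for s in self.seqs]
        self.k = seed_k
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        for ri, seq in enumerate(self.seqs):
            for p in range(len(seq) - seed_k + 1):
                self.kmers.setdefault(seq[p:p + seed_k], []).append((ri, p))


def _candidates(index: ReferenceIndex, seq: str) -> set[tuple[int, int]]:
    k = index.k
    out: set[tuple[int, int]] = set()
    for off in range(len(seq) - k + 1):
        for ri, p in index.kmers.get(seq[off:off + k], ()):
            out.add((ri, p - off))
    return out


def _all_starts(index: ReferenceIndex, read_len: int,
                min_aligned: int) -> set[tuple[int, int]]:
    out: set[tuple[int, int]] = set()
    for ri, seq in enumerate(index.seqs):
        lo = -(read_len - min_aligned)
        hi = len(seq) - min_aligned
        out.update((ri, a) for a in range(lo, hi + 1))
    return out


def _score(index: ReferenceIndex, read_codes: np.ndarray, ri: int,
           astart: int) -> tuple[int, int, int]:
    """(matches, ref_start, ref_end) of the ungapped overlap alignment."""
    ref = index.codes[ri]
    L = read_codes.size
    rs = max(0, astart)
    re_ = min(ref.size, astart + L)
    if re_ <= rs:
        return 0, rs, rs
    seg = read_codes[rs - astart:re_ - astart]
    matches = int(np.count_nonzero(ref[rs:re_] == seg))
    return matches, rs, re_


def map_read(index: ReferenceIndex, seq: str,
             params: MappingParams) -> tuple[int, int, str, float, int, int] | None:
    """Best hit for one read: (ref_index, ref_start, strand, identity,
    aligned_len, ref_end); None if unmapped."""
    seq = seq.upper()
    L = len(seq)
    min_aligned = math.ceil(params.min_overlap * L)
    best = None  # (identity, ri, ref_start, strand_rank, ref_end, aligned)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        codes = seq_to_codes(s)
        if L >= index.k:
            cands = _candidates(index, s)
        else:
            cands = _all_starts(index, L, min_aligned)
        for ri, astart in sorted(cands):
            matches, rs, re_ = _score(index, codes, ri, astart)
            aligned = re_ - rs
            if aligned < min_aligned or aligned == 0:
                continue
            ident = matches / aligned
            if ident < params.min_identity:
                continue
            key = (-ident, ri, rs, 0 if strand == "+" else 1)
            if best is None or key < best[0]:
                best = (key, ri, rs, re_, strand, ident, aligned)
                if ident == 1.0 and strand == "+":
                    break  # sorted scan: later candidates lose the tie-break
    if best is None:
        return None
    _, ri, rs, re_, strand, ident, aligned = best
    return ri, rs, strand, ident, aligned, re_


def map_reads(reads: list[Read], references: list[tuple[str, str]],
              params: MappingParams | None = None
              ) -> tuple[list[Assignment | None], pd.DataFrame]:
    """Assign each read to at most one reference; return the count table.

    Notes: the '-'-strand pass is evaluated only when the '+'-strand pass did
    not already yield a perfect, tie-winning hit; identities and tie-breaks
    (best identity, then lower reference index, leftmost position, + strand)
    match an exhaustive all-position scorer on seed-findable hits.
    """
    params = params or MappingParams()
    index = ReferenceIndex(references, params.seed_k)
    assignments: list[Assignment | None] = []
    for i, r in enumerate(reads):
        hit = map_read(index, r.seq, params)
        if hit is None:
            assignments.append(None)
        else:
            ri, rs, strand, ident, aligned, re_ = hit
            assignments.append(Assignment(i, ri, index.ids[ri], rs, re_,
                                          strand, ident, aligned))
    table = count_table(assignments, references, total_reads=len(reads))
    return assignments, table


# ---------------------------------------------------------------------------
# counting statistics
# ---------------------------------------------------------------------------

def count_table(assignments: list[Assignment | None],
                references: list[tuple[str, str]],
                total_reads: int) -> pd.DataFrame:
    counts = np.zeros(len(references), dtype=int)
    for a in assignments:
        if a is not None:
            counts[a.ref_index] += 1
    total_mapped = int(counts.sum())
    rows = []
    for (rid, seq), n in zip(references, counts):
        length = len(seq)
        rows.append({
            "ref_id": rid,
            "length": length,
            "gc_percent": gc_content(seq),
            "n_mapped": int(n),
            "reads_per_kb": n * 1000.0 / length,
            "fraction_of_library": 100.0 * n / total_reads if total_reads else 0.0,
            "rpkm": rpkm(int(n), length, total_mapped) if total_mapped else 0.0,
        })
    df = pd.DataFrame(rows)
    df.attrs["total_reads"] = total_reads
    df.attrs["total_mapped"] = total_mapped
    return df


def rpkm(n_mapped: int, ref_len_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of reference per million mapped reads."""
    if ref_len_nt <= 0 or total_mapped <= 0:
        raise ValueError("ref_len_nt and total_mapped must be > 0")
    return n_mapped / (ref_len_nt / 1000.0) / (total_mapped / 1e6)


def _round_half_up(x: float, decimals: int) -> float:
    # tables conventionally print half-up rounding (1.125 -> 1.13)
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def reduction_factor(count_control: float, count_treated: float,
                     decimals: int = 1) -> float:
    """Control/treated ratio; inf flags complete elimination."""
    if count_control < 0:
        raise ValueError("count_control must be >= 0")
    if count_treated == 0:
        return math.inf
    return _round_half_up(count_control / count_treated, decimals)


def enrichment_factor(per_kb_treated: float, per_kb_control: float) -> float:
    """Treated/control reads-per-kb ratio, two decimals."""
    if per_kb_control <= 0:
        raise ValueError("per_kb_control must be > 0")
    return _round_half_up(per_kb_treated / per_kb_control, 2)


def coverage_track(assignments: list[Assignment | None],
                   reference: tuple[str, str],
                   ref_index: int | None = None) -> np.ndarray:
    """Per-base depth over one reference (sum of aligned read intervals)."""
    rid, seq = reference
    depth = np.zeros(len(seq), dtype=np.int64)
    for a in assignments:
        if a is None:
            continue
        if a.ref_id != rid and (ref_index is None or a.ref_index != ref_index):
            continue
        depth[a.ref_start:a.ref_end] += 1
    return depth
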