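"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's index/seeding machinery:
every candidate placement is enumerated and scored directly.
"""

from __future__ import annotations

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def exhaustive_best_hit(read: str, references: list[tuple[str, str]],
                        min_identity: float, min_overlap: float):
    """All-position, all-strand ungapped scorer with the documented
    tie-break (best identity, lower ref index, leftmost, + strand).

    Returns (ref_index, ref_start, strand, identity, aligned_len) or None.
    """
    L = len(read)
    min_aligned = math.ceil(min_overlap * L)
    best = None
    best_key = None
    for strand_rank, s in enumerate((read, rc(read))):
        strand = "+-"[strand_rank]
        for ri, (_, ref) in enumerate(references):
            for astart in range(-(L - min_aligned),
                                len(ref) - min_aligned + 1):
                lo = max(0, astart)
                hi = min(len(ref), astart + L)
                aligned = hi - lo
                if aligned < min_aligned:
                    continue
                matches = sum(ref[p] == s[p - astart] for p in range(lo, hi))
                ident = matches / aligned
                if ident < min_identity:
                    continue
                key = (-ident, ri, lo, strand_rank)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (ri, lo, strand, ident, aligned)
    return best


def dict_kmer_counts(seqs: list[str], k: int) -> dict[str, int]:
    out: dict[str, int] = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            if any(c not in "ACGT" for c in km):
                continue
            canon = min(km, rc(km))
            out[canon] = out.get(canon, 0) + 1
    return out
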