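"""Brute-force ungapped alignment oracle used to validate the mapper."""

from __future__ import annotations

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def exhaustive_best_hit(read: str, references, min_identity: float,
                        min_overlap: float):
    L = len(read)
    min_aligned = math.ceil(min_overlap * L)
    best, best_key = None, None
    for strand_rank, s in enumerate((read, rc(read))):
        strand = "+-"[strand_rank]
        for ri, (_, ref) in enumerate(references):
            for astart in range(-(L - min_aligned),
                                len(ref) - min_aligned + 1):
                lo, hi = max(0, astart), min(len(ref), astart + L)
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
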