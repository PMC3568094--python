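"""Repeat discovery by abundant-k-mer seeded consensus extension.

The most abundant canonical 30-mers of a library seed pileup alignments:
reads containing the current seed window exactly are recruited and oriented
by it, columns beyond the window are voted base-by-base, and the consensus
grows while column depth and majority fraction stay above thresholds. The
window then slides to the consensus terminus and extension iterates.
Everything is deterministic: voting ties break in fixed A<C<G<T order and
recruitment order never affects the vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqs import revcomp
from .synth import Read

BASE_ORDER = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASE_ORDER)}


def count_kmers(reads: list[Read], k: int = 30) -> dict[str, int]:
    """Exact canonical k-mer counts (canonical = min of k-mer and its
    reverse complement); reads shorter than k are skipped."""
    if k < 8:
        raise ValueError("k must be >= 8")
    table: dict[str, int] = {}
    for r in reads:
        s = r.seq.upper()
        if len(s) < k:
            continue
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            if any(c not in _BASE_IDX for c in km):
                continue
            rc = revcomp(km)
            canon = km if km <= rc else rc
            table[canon] = table.get(canon, 0) + 1
    return table


def top_seeds(table: dict[str, int], n: int = 10_000,
              min_seed_count: int = 10) -> list[str]:
    """Most abundant seeds, descending count, ties lexicographic."""
    items = [(km, c) for km, c in table.items() if c >= min_seed_count]
    items.sort(key=lambda kc: (-kc[1], kc[0]))
    return [km for km, _ in items[:n]]


@dataclass
class ConsensusRecord:
    consensus: str
    depth: list[int]
    majority: list[float]
    seed: str
    iterations: int = 0

    def __len__(self) -> int:
        return len(self.consensus)


class ReadKmerIndex:
    """Forward-strand k-mer position index over a read set."""

    def __init__(self, reads: list[Read], k: int):
        self.k = k
        self.seqs = [r.seq.upper() for r in reads]
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ri, s in enumerate(self.seqs):
            for p in range(len(s) - k + 1):
                self.index.setdefault(s[p:p + k], []).append((ri, p))

    def recruit(self, window: str) -> list[tuple[str, int]]:
        """(oriented read sequence, window offset) for every exact
        occurrence of `window` in either orientation."""
        out: list[tuple[str, int]] = []
        for ri, p in self.index.get(window, ()):
            out.append((self.seqs[ri], p))
        wrc = revcomp(window)
        if wrc != window:
            for ri, p in self.index.get(wrc, ()):
                s = self.seqs[ri]
                out.append((revcomp(s), len(s) - self.k - p))
        return out


def _vote(entries: list[tuple[str, int]], col: int) -> tuple[int, int, float]:
    """(winning base index, depth, majority fraction) at a column relative
    to the window start of each entry."""
    counts = np.zeros(4, dtype=int)
    for s, off in entries:
        j = off + col
        if 0 <= j < len(s):
            b = _BASE_IDX.get(s[j])
            if b is not None:
                counts[b] += 1
    depth = int(counts.sum())
    if depth == 0:
        return -1, 0, 0.0
    win = int(np.argmax(counts))  # argmax takes the first max: A<C<G<T ties
    return win, depth, counts[win] / depth


def _extend_right(consensus: str, index: ReadKmerIndex, min_depth: int,
                  majority_threshold: float, max_len: int
                  ) -> tuple[str, list[int], list[float], int]:
    depth_out: list[int] = []
    maj_out: list[float] = []
    iterations = 0
    while len(consensus) < max_len:
        window = consensus[-index.k:]
        entries = index.recruit(window)
        if len(entries) < min_depth:
            break
        grew = False
        col = index.k
        while len(consensus) < max_len:
            b, depth, maj = _vote(entries, col)
            if b < 0 or depth < min_depth or maj < majority_threshold:
                break
            consensus += BASE_ORDER[b]
            depth_out.append(depth)
            maj_out.append(maj)
            col += 1
            grew = True
        iterations += 1
        if not grew:
            break
    return consensus, depth_out, maj_out, iterations


def extend_consensus(seed: str, reads: list[Read], min_depth: int = 5,
                     majority_threshold: float = 0.6, max_len: int = 10_000,
                     index: ReadKmerIndex | None = None) -> ConsensusRecord:
    """Grow a consensus from a seed by iterative pileup majority vote.

    Reads containing the current window exactly (either orientation) are
    recruited and anchored at it; the majority base is appended while column
    depth >= min_depth and majority fraction >= majority_threshold; the
    window then slides to the terminus and extension repeats, on both ends.
    """
    if index is None:
        index = ReadKmerIndex(reads, len(seed))
    if index.k != len(seed):
        raise ValueError("index k does not match seed length")
    seed = seed.upper()
    seed_entries = index.recruit(seed)
    if len(seed_entries) < min_depth:
        raise ValueError(
            f"seed supported by {len(seed_entries)} reads < min_depth")

    # seed-column stats from the initial recruitment
    seed_depth: list[int] = []
    seed_maj: list[float] = []
    for col in range(index.k):
        _, d, m = _vote(seed_entries, col)
        seed_depth.append(d)
        seed_maj.append(m)

    cons, d_right, m_right, it_r = _extend_right(
        seed, index, min_depth, majority_threshold, max_len)
    # left extension = right extension of the reverse complement
    rc, d_left, m_left, it_l = _extend_right(
        revcomp(cons), index, min_depth, majority_threshold, max_len)
    consensus = revcomp(rc)
    left = len(consensus) - len(cons)
    depth = d_left[::-1] + seed_depth + d_right
    majority = m_left[::-1] + seed_maj + m_right
    assert len(depth) == len(consensus) and left == len(d_left)
    return ConsensusRecord(consensus, depth, majority, seed,
                           iterations=it_r + it_l)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _ungapped_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def _best_contained(small: "ConsensusRecord", big: "ConsensusRecord",
                    min_identity: float) -> bool:
    s, b = small.consensus, big.consensus
    for q in (s, revcomp(s)):
        for start in range(len(b) - len(q) + 1):
            if _ungapped_identity(q, b[start:]) >= min_identity:
                return True
    return False


def _try_end_merge(a: ConsensusRecord, b: ConsensusRecord, min_overlap: int,
                   min_identity: float) -> ConsensusRecord | None:
    """Merge by suffix/prefix overlap; overlap columns take the base backed
    by the larger pileup depth."""
    for bseq, bdepth, bmaj in ((b.consensus, b.depth, b.majority),
                               (revcomp(b.consensus), b.depth[::-1],
                                b.majority[::-1])):
        for left, ls, ld, lm, rs, rd, rm in (
                (True, a.consensus, a.depth, a.majority, bseq, bdepth, bmaj),
                (False, bseq, bdepth, bmaj, a.consensus, a.depth, a.majority)):
            max_o = min(len(ls), len(rs))
            for o in range(max_o, min_overlap - 1, -1):
                if _ungapped_identity(ls[-o:], rs[:o]) >= min_identity:
                    merged_seq = []
                    merged_depth = list(ld[:len(ls) - o])
                    merged_maj = list(lm[:len(ls) - o])
                    merged_seq.append(ls[:len(ls) - o])
                    for i in range(o):
                        li = len(ls) - o + i
                        if ld[li] >= rd[i]:
                            merged_seq.append(ls[li])
                            merged_depth.append(ld[li] + rd[i])
                            merged_maj.append(lm[li])
                        else:
                            merged_seq.append(rs[i])
                            merged_depth.append(ld[li] + rd[i])
                            merged_maj.append(rm[i])
                    merged_seq.append(rs[o:])
                    merged_depth.extend(rd[o:])
                    merged_maj.extend(rm[o:])
                    seed = a.seed if left else b.seed
                    return ConsensusRecord("".join(merged_seq), merged_depth,
                                           merged_maj, seed,
                                           a.iterations + b.iterations)
    return None


def merge_consensi(records: list[ConsensusRecord], min_overlap: int = 50,
                   min_identity: float = 0.95) -> list[ConsensusRecord]:
    """Greedy longest-first merge of end-overlapping or contained consensi."""
    pool = sorted(records, key=lambda r: (-len(r), r.consensus))
    merged: list[ConsensusRecord] = []
    for rec in pool:
        absorbed = False
        for i, m in enumerate(merged):
            if len(rec) <= len(m) and _best_contained(rec, m, min_identity):
                absorbed = True
                break
            joint = _try_end_merge(m, rec, min_overlap, min_identity)
            if joint is not None:
                merged[i] = joint
                absorbed = True
                break
        if not absorbed:
            merged.append(rec)
    return merged
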