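"""Small shared nucleotide-sequence helpers used across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTRYKMNacgtrykmn", "TGCAYRMKNtgcayrmkn")

# byte codes used for vectorized comparisons
_B2I = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _B2I[ord(_b)] = _i
    _B2I[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement (handles upper/lower case and N/ambiguity codes)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0 C=1 G=2 T=3, other=255)."""
    return _B2I[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases; NaN for an empty/all-N sequence."""
    s = seq.upper()
    atcg = sum(s.count(b) for b in "ACGT")
    if atcg == 0:
        return float("nan")
    return (s.count("G") + s.count("C")) / atcg


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random sequence with expected GC content `gc`."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return codes_to_seq(codes)


def minimal_period(seq: str) -> int:
    """Smallest p such that seq is a prefix of (seq[:p] * n); len(seq) if
    the sequence is not tandemly periodic."""
    n = len(seq)
    for p in range(1, n // 2 + 1):
        if all(seq[i] == seq[i % p] for i in range(n)):
            return p
    return n


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply i.i.d. substitutions at the given per-site rate (no indels)."""
    if rate <= 0:
        return seq
    codes = seq_to_codes(seq).copy()
    hit = rng.random(codes.size) < rate
    n = int(hit.sum())
    if n == 0:
        return seq
    # substitute with one of the three other bases, uniformly
    shift = rng.integers(1, 4, size=n).astype(np.uint8)
    codes[hit] = (codes[hit] + shift) % 4
    return codes_to_seq(codes)
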