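"""Read quality filtering.

Illumina pipelines of the GAII era flagged failed cycles with the quality
glyph 'B'; everything from the first failed score onward is trimmed. Reads
are then filtered to a length window and a GC window (closed intervals).
"""

from __future__ import annotations

from dataclasses import dataclass

from .synth import Read, ReadLibrary


@dataclass
class QCParams:
    fail_char: str = "B"
    min_len: int = 40
    max_len: int = 80
    min_gc: float = 20.0   # percent
    max_gc: float = 80.0

    def __post_init__(self) -> None:
        if self.min_len > self.max_len or self.min_gc > self.max_gc:
            raise ValueError("min must be <= max for length and GC ranges")


def trim_after_fail(read: Read, fail_char: str = "B") -> Read:
    """Keep the prefix strictly before the first failed quality score.

    The base aligned to the first fail glyph is discarded along with
    everything after it. A read failing at position 0 becomes empty (and is
    dropped by downstream filters). Idempotent.
    """
    if len(read.seq) != len(read.qual):
        raise ValueError(f"{read.id}: sequence/quality length mismatch")
    cut = read.qual.find(fail_char)
    if cut < 0:
        return read
    return Read(read.id, read.seq[:cut], read.qual[:cut], frag=read.frag)


def gc_content(seq: str) -> float:
    """GC percent over unambiguous bases (ambiguity codes excluded)."""
    s = seq.upper()
    denom = sum(s.count(b) for b in "ACGT")
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return 100.0 * (s.count("G") + s.count("C")) / denom


def filter_reads(reads: list[Read], params: QCParams | None = None) -> list[Read]:
    """Trim 'B' tails, then keep reads inside the length and GC windows."""
    params = params or QCParams()
    out = []
    for r in reads:
        t = trim_after_fail(r, params.fail_char)
        if not params.min_len <= len(t.seq) <= params.max_len:
            continue
        try:
            gc = gc_content(t.seq)
        except ValueError:
            continue
        if params.min_gc <= gc <= params.max_gc:
            out.append(t)
    return out


def qc_library(library: ReadLibrary, params: QCParams | None = None) -> ReadLibrary:
    kept = filter_reads(library.reads, params)
    return ReadLibrary(kept, treatment=library.treatment, salt=library.salt,
                       renat_hours=library.renat_hours, seed=library.seed)


def qc_summary(n_in: int, kept: list[Read]) -> dict:
    n = len(kept)
    return {
        "reads_in": n_in,
        "reads_out": n,
        "mean_length": sum(len(r.seq) for r in kept) / n if n else 0.0,
        "mean_gc": sum(gc_content(r.seq) for r in kept) / n if n else 0.0,
    }
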