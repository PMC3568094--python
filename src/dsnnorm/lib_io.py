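"""Standard-format I/O: FASTA, FASTQ (Phred+33), BED6, BedGraph, TSV."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synth import Feature, Read, ReadLibrary, SyntheticGenome


def write_fasta(path: str | Path, records: dict[str, str] | list) -> None:
    if isinstance(records, dict):
        records = list(records.items())
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | Path, library: ReadLibrary) -> None:
    # plain writer: Phred+33 qualities are kept verbatim as generated
    with open(path, "w") as fh:
        for r in library.reads:
            fh.write(f"@{r.id} frag={r.frag}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path: str | Path, treatment: str = "control",
               salt: str = "none", renat_hours: float = 0.0,
               seed: int = 0) -> ReadLibrary:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in
                       rec.letter_annotations["phred_quality"])
        frag = -1
        for tok in rec.description.split():
            if tok.startswith("frag="):
                frag = int(tok[5:])
        reads.append(Read(rec.id, str(rec.seq).upper(), qual, frag=frag))
    return ReadLibrary(reads, treatment=treatment, salt=salt,
                       renat_hours=renat_hours, seed=seed)


def write_bed6(path: str | Path, features: list[Feature],
               chrom: str = "nuclear") -> None:
    """Feature table as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for f in features:
            name = f"{f.feature_id}.{f.copy_index}"
            fh.write(f"{chrom}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


def write_genome(outdir: str | Path, genome: SyntheticGenome,
                 stem: str = "genome") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs = {"nuclear": genome.nuclear_seq, **genome.organelle_seqs}
    write_fasta(outdir / f"{stem}.fasta", seqs)
    write_bed6(outdir / f"{stem}.features.bed", genome.features)


def write_bedgraph(path: str | Path, ref_id: str, depth: np.ndarray) -> None:
    """Run-length encoded per-base coverage."""
    with open(path, "w") as fh:
        if depth.size == 0:
            return
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [depth.size]])
        for s, e in zip(starts, ends):
            fh.write(f"{ref_id}\t{s}\t{e}\t{int(depth[s])}\n")
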