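"""Synthetic genomes, expression profiles, fragment pools and read libraries.

The generator emulates the statistical structure of a plant nuclear genome
prepared for shotgun sequencing: repeat families spanning 1..~1e4 copies with
tunable per-copy divergence, single- and multi-copy protein-coding genes over
a GC spectrum, organelle contamination (chloroplast/mitochondrion) at fixed
read fractions, a log-normal transcript abundance profile, and reads whose
quality strings can fail into a terminal run of 'B' characters.

Every planted feature is recorded with 0-based half-open coordinates and a
+/- strand, so analyses can be validated against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqs import gc_fraction, minimal_period, mutate, random_seq, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}

# organelle contamination defaults: chloroplast and mitochondrial read shares
DEFAULT_ORGANELLE_FRACTIONS = {"chloroplast": 0.168, "mitochondrion": 0.024}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatFamily:
    """A repeat family planted as `copy_number` diverged copies of one unit."""

    name: str
    unit_seq: str
    copy_number: int
    divergence: float = 0.0  # per-site substitution rate applied per copy
    target_gc: float | None = None

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError(f"{self.name}: copy_number must be >= 1")
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError(f"{self.name}: divergence must be in [0, 0.3]")
        if len(self.unit_seq) < 7:
            raise ValueError(f"{self.name}: unit length must be >= 7")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with an uninterrupted reading frame."""

    gene_id: str
    cds_seq: str
    copies: int = 1

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError(f"{self.gene_id}: copies must be >= 1")
        s = self.cds_seq.upper()
        if len(s) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        if not s.startswith("ATG"):
            raise ValueError(f"{self.gene_id}: CDS must start with ATG")
        internal = [s[i:i + 3] for i in range(0, len(s) - 3, 3)]
        if any(c in STOP_CODONS for c in internal):
            raise ValueError(f"{self.gene_id}: internal stop codon")

    @property
    def gc(self) -> float:
        return gc_fraction(self.cds_seq)


@dataclass(frozen=True)
class Feature:
    """A planted genomic feature; 0-based half-open, strand '+'/'-'."""

    feature_id: str  # repeat family name or gene id
    kind: str        # 'repeat' | 'gene'
    copy_index: int
    start: int
    end: int
    strand: str


@dataclass
class SyntheticGenome:
    nuclear_seq: str
    features: list[Feature]
    organelle_seqs: dict[str, str]
    organelle_read_fractions: dict[str, float]
    families: dict[str, RepeatFamily] = field(default_factory=dict)
    genes: dict[str, GeneModel] = field(default_factory=dict)
    organelle_conc_boost: float = 30.0

    def extract_feature(self, f: Feature) -> str:
        s = self.nuclear_seq[f.start:f.end]
        return revcomp(s) if f.strand == "-" else s

    def feature_copies(self, feature_id: str) -> list[str]:
        return [self.extract_feature(f) for f in self.features
                if f.feature_id == feature_id]


@dataclass
class ExpressionProfile:
    """Relative molar transcript abundances (normalized to sum to 1)."""

    abundance: dict[str, float]
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.abundance.values())
        if total <= 0:
            raise ValueError("abundances must have positive sum")
        self.abundance = {g: a / total for g, a in self.abundance.items()}

    @classmethod
    def lognormal(cls, gene_ids: list[str], mu: float = 0.0,
                  sigma: float = 2.0, seed: int = 0) -> "ExpressionProfile":
        """Log-normal abundance spectrum over the given genes.

        sigma = 2.0 (natural log) spans roughly four orders of magnitude of
        expression, the dynamic range over which normalization visibly
        depletes abundant transcripts and enriches rare ones.
        """
        rng = np.random.default_rng(seed)
        ab = np.exp(rng.normal(mu, sigma, size=len(gene_ids)))
        return cls(dict(zip(gene_ids, ab)), lognormal_mu=mu,
                   lognormal_sigma=sigma)


@dataclass
class Read:
    id: str
    seq: str
    qual: str
    frag: int = -1  # index of the source fragment in its pool (-1: unknown)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass
class ReadLibrary:
    """An ordered read collection plus treatment metadata."""

    reads: list[Read]
    treatment: str = "control"   # 'control' | 'dsn'
    salt: str = "none"           # 'none' | 'NaCl' | 'TMAC'
    renat_hours: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.salt == "none") != (self.treatment == "control"):
            raise ValueError("salt must be 'none' iff treatment is 'control'")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class Fragment:
    """A sheared molecule with its duplex-class label and concentrations.

    `abundance` is the fragment's molar share of the pool (sums to 1 over the
    pool); `conc` is the relative concentration of the fragment's duplex
    class, i.e. of molecules able to renature with it, which drives kinetics.
    """

    seq: str
    gc: float
    origin: str       # feature id / organelle name / 'background'
    abundance: float
    conc: float
    src_name: str = ""   # source sequence name (nuclear/organelle/gene id)
    src_start: int = -1  # 0-based start of the fragment on its source


@dataclass
class FragmentPool:
    fragments: list[Fragment]
    mean_len: int

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def abundances(self) -> np.ndarray:
        return np.array([f.abundance for f in self.fragments])

    def class_shares(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for f in self.fragments:
            out[f.origin] = out.get(f.origin, 0.0) + f.abundance
        return out


# ---------------------------------------------------------------------------
# gene synthesis
# ---------------------------------------------------------------------------

def _repair_stops(codes: list[str]) -> None:
    for i in range(1, len(codes) - 1):
        if codes[i] in STOP_CODONS:
            # mutate third base away from the stop, keeping A/T<->G/C class
            codes[i] = codes[i][:2] + {"A": "T", "G": "C", "T": "C"}[codes[i][2]]
            if codes[i] in STOP_CODONS:  # TAA->TAT etc. handled above; safety
                codes[i] = codes[i][:2] + "C"


def make_gene(rng: np.random.Generator, gene_id: str, n_codons: int,
              gc: float, copies: int = 1, gc_tol: float = 0.03) -> GeneModel:
    """Generate a stop-free CDS whose realized GC is within gc_tol of target."""
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    body = random_seq(rng, 3 * (n_codons - 1), gc)
    codons = ["ATG"] + [body[i:i + 3] for i in range(0, len(body), 3)]
    _repair_stops(codons)
    # nudge third positions until realized GC matches the target
    for _ in range(10 * n_codons):
        seq = "".join(codons)
        delta = gc_fraction(seq) - gc
        if abs(delta) <= gc_tol - 0.005:
            break
        i = int(rng.integers(1, len(codons) - 1))
        c = codons[i]
        if delta < 0 and c[2] in "AT":
            cand = c[:2] + ("G" if c[2] == "A" else "C")
        elif delta > 0 and c[2] in "GC":
            cand = c[:2] + ("A" if c[2] == "G" else "T")
        else:
            continue
        if cand not in STOP_CODONS:
            codons[i] = cand
    return GeneModel(gene_id, "".join(codons), copies=copies)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    """Generator settings for one synthetic genome."""

    repeat_families: list[RepeatFamily] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    background_len: int = 100_000
    background_gc: float = 0.36
    organelle_lengths: dict[str, int] = field(
        default_factory=lambda: {"chloroplast": 20_000, "mitochondrion": 15_000})
    organelle_gc: dict[str, float] = field(
        default_factory=lambda: {"chloroplast": 0.36, "mitochondrion": 0.45})
    organelle_read_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORGANELLE_FRACTIONS))
    # Organelle genomes are present at hundreds to thousands of copies per
    # cell, so a specific organelle locus is vastly more concentrated than a
    # single-copy nuclear locus. A genome scaled down ~1000x in nuclear
    # length compresses that ratio; this factor restores it explicitly.
    organelle_conc_boost: float = 30.0

    def validate(self) -> None:
        if sum(self.organelle_read_fractions.values()) >= 1.0:
            raise ValueError("organelle read fractions must sum to < 1")
        for fam in self.repeat_families:
            _ = fam  # dataclass validation ran at construction
        if self.background_len < 0:
            raise ValueError("background_len must be >= 0")


def build_genome(config: GenomeConfig, seed: int) -> SyntheticGenome:
    """Assemble a nuclear sequence with planted repeats/genes + organelles.

    Deterministic for a fixed seed. Every planted copy is recorded in the
    feature table; copies of a repeat family are independently mutated at the
    family's divergence rate; gene copies are exact duplicates.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    segments: list[tuple[str, str, str, int]] = []  # (seq, feature_id, kind, copy_index)
    for fam in config.repeat_families:
        for i in range(fam.copy_number):
            segments.append((mutate(rng, fam.unit_seq, fam.divergence),
                             fam.name, "repeat", i))
    for gene in config.genes:
        for i in range(gene.copies):
            segments.append((gene.cds_seq, gene.gene_id, "gene", i))
    order = rng.permutation(len(segments))
    segments = [segments[i] for i in order]

    # split the background into spacers around the planted segments
    n_spacers = len(segments) + 1
    if config.background_len > 0:
        cuts = np.sort(rng.integers(0, config.background_len + 1,
                                    size=n_spacers - 1))
        spacer_lens = np.diff(np.concatenate([[0], cuts,
                                              [config.background_len]]))
    else:
        spacer_lens = np.zeros(n_spacers, dtype=int)

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    for i, (seq, fid, kind, ci) in enumerate(segments):
        sp = random_seq(rng, int(spacer_lens[i]), config.background_gc)
        parts.append(sp)
        pos += len(sp)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = seq if strand == "+" else revcomp(seq)
        parts.append(placed)
        features.append(Feature(fid, kind, ci, pos, pos + len(seq), strand))
        pos += len(seq)
    parts.append(random_seq(rng, int(spacer_lens[-1]), config.background_gc))

    # organelle genomes are GC mosaics: gene-rich and AT-rich regions
    # alternate, which is what a GC tiling analysis resolves
    organelles = {}
    for name, length in config.organelle_lengths.items():
        gc0 = config.organelle_gc.get(name, 0.4)
        blocks = []
        remaining = length
        while remaining > 0:
            blk = int(min(remaining, 2000))
            gc_blk = float(np.clip(rng.uniform(gc0 - 0.12, gc0 + 0.12),
                                   0.05, 0.95))
            blocks.append(random_seq(rng, blk, gc_blk))
            remaining -= blk
        organelles[name] = "".join(blocks)
    return SyntheticGenome(
        nuclear_seq="".join(parts),
        features=features,
        organelle_seqs=organelles,
        organelle_read_fractions=dict(config.organelle_read_fractions),
        families={f.name: f for f in config.repeat_families},
        genes={g.gene_id: g for g in config.genes},
        organelle_conc_boost=config.organelle_conc_boost,
    )


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

def _draw_lengths(rng: np.random.Generator, n: int, mean_len: int) -> np.ndarray:
    """Log-normal fragment lengths centered on mean_len, truncated to
    [100, 3*mean_len] (shearing produces positively skewed lengths)."""
    sigma = 0.35
    mu = math.log(mean_len) - sigma ** 2 / 2
    lens = rng.lognormal(mu, sigma, size=n)
    for _ in range(20):
        bad = (lens < 100) | (lens > 3 * mean_len)
        if not bad.any():
            break
        lens[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
    return np.clip(lens, 100, 3 * mean_len).astype(int)


def _class_concentrations(shares: dict[str, float],
                          unique_lens: dict[str, int],
                          mean_len: int) -> dict[str, float]:
    """Relative concentration of each duplex class.

    A class whose distinct sequence is no longer than a fragment (tandem
    repeats, short units) renatures as one species: concentration equals its
    molar share. A class spread over a longer distinct sequence (a gene, an
    organelle genome, unique background) dilutes the share over the number of
    fragment-sized windows it spans.
    """
    return {
        cls: share * mean_len / max(unique_lens.get(cls, mean_len), mean_len)
        for cls, share in shares.items()
    }


def fragment_source(source, mean_len: int = 300, n_fragments: int = 20_000,
                    seed: int = 0,
                    expression: ExpressionProfile | None = None) -> FragmentPool:
    """Shear a genome (or transcript set) into a fragment pool.

    `source` is a SyntheticGenome (genomic library; organelle fragments are
    included at the configured read fractions, and class abundance is
    proportional to copy number because copies occupy sequence), or a mapping
    gene_id -> transcript sequence together with an ExpressionProfile
    (transcriptomic library; molar abundance taken from the profile).
    """
    if mean_len < 100:
        raise ValueError("mean_len must be >= 100")
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)

    if isinstance(source, SyntheticGenome):
        return _fragment_genome(source, mean_len, n_fragments, rng)
    if expression is None:
        raise ValueError("transcript fragmentation requires an ExpressionProfile")
    transcripts = dict(source)
    if not transcripts:
        raise ValueError("empty source")
    return _fragment_transcripts(transcripts, expression, mean_len,
                                 n_fragments, rng)


def _take_fragment(seq: str, length: int, rng: np.random.Generator,
                   mean_len: int) -> tuple[int, int]:
    L = len(seq)
    if L <= mean_len or length >= L:
        return 0, L  # short molecules shear to (nearly) full length
    start = int(rng.integers(0, L - length + 1))
    return start, start + length


def _fragment_genome(genome: SyntheticGenome, mean_len: int,
                     n_fragments: int, rng: np.random.Generator) -> FragmentPool:
    if not genome.nuclear_seq:
        raise ValueError("empty source")
    names = list(genome.organelle_seqs)
    fracs = np.array([genome.organelle_read_fractions.get(n, 0.0)
                      for n in names])
    p = np.concatenate([[1.0 - fracs.sum()], fracs])
    counts = rng.multinomial(n_fragments, p)

    # feature lookup over the nuclear sequence (features are non-overlapping)
    feats = sorted(genome.features, key=lambda f: f.start)
    starts = np.array([f.start for f in feats])
    ends = np.array([f.end for f in feats])

    unique_lens: dict[str, int] = {"background": max(len(genome.nuclear_seq), 1)}
    for name, fam in genome.families.items():
        # tandem units (e.g. telomeric motifs) renature in any register:
        # their distinct sequence is the repeat period, not the unit length
        unique_lens[name] = minimal_period(fam.unit_seq)
    for gid, gene in genome.genes.items():
        unique_lens[gid] = len(gene.cds_seq)
    for name, seq in genome.organelle_seqs.items():
        unique_lens[name] = len(seq)

    def classify(s: int, e: int) -> str:
        # duplex class = feature with the largest overlap, provided it
        # covers >= 30% of the fragment; border fragments dominated by
        # unique sequence renature like background
        i = int(np.searchsorted(starts, s, side="right")) - 1
        best_ov, best = 0, "background"
        while i < len(feats):
            if i >= 0:
                ov = min(e, int(ends[i])) - max(s, int(starts[i]))
                if ov > best_ov:
                    best_ov, best = ov, feats[i].feature_id
            i += 1
            if i >= len(feats) or starts[i] >= e:
                break
        return best if best_ov >= 0.3 * (e - s) else "background"

    raw: list[tuple[str, str, str, int]] = []  # (seq, origin, src, start)
    lens = _draw_lengths(rng, int(counts[0]), mean_len)
    for length in lens:
        s, e = _take_fragment(genome.nuclear_seq, int(length), rng, mean_len)
        raw.append((genome.nuclear_seq[s:e], classify(s, e), "nuclear", s))
    for name, n_org in zip(names, counts[1:]):
        seq = genome.organelle_seqs[name]
        for length in _draw_lengths(rng, int(n_org), mean_len):
            s, e = _take_fragment(seq, int(length), rng, mean_len)
            raw.append((seq[s:e], name, name, s))

    w = 1.0 / len(raw)
    shares: dict[str, float] = {}
    for _, origin, _, _ in raw:
        shares[origin] = shares.get(origin, 0.0) + w
    conc = _class_concentrations(shares, unique_lens, mean_len)
    for name in names:
        if name in conc:
            conc[name] *= genome.organelle_conc_boost
    frags = [Fragment(seq, gc_fraction(seq), origin, w, conc[origin],
                      src_name=src, src_start=s)
             for seq, origin, src, s in raw]
    return FragmentPool(frags, mean_len)


def _fragment_transcripts(transcripts: dict[str, str],
                          profile: ExpressionProfile, mean_len: int,
                          n_fragments: int,
                          rng: np.random.Generator) -> FragmentPool:
    gids = [g for g in transcripts if profile.abundance.get(g, 0.0) > 0]
    if not gids:
        raise ValueError("no expressed transcripts in source")
    p = np.array([profile.abundance[g] for g in gids])
    p = p / p.sum()
    counts = rng.multinomial(n_fragments, p)
    unique_lens = {g: len(transcripts[g]) for g in gids}

    raw: list[tuple[str, str, int]] = []
    for g, n_g in zip(gids, counts):
        seq = transcripts[g]
        for length in _draw_lengths(rng, int(n_g), mean_len):
            s, e = _take_fragment(seq, int(length), rng, mean_len)
            raw.append((seq[s:e], g, s))
    w = 1.0 / max(len(raw), 1)
    shares: dict[str, float] = {}
    for _, origin, _ in raw:
        shares[origin] = shares.get(origin, 0.0) + w
    conc = _class_concentrations(shares, unique_lens, mean_len)
    frags = [Fragment(seq, gc_fraction(seq), origin, w, conc[origin],
                      src_name=origin, src_start=s)
             for seq, origin, s in raw]
    return FragmentPool(frags, mean_len)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

PASS_QUAL = "F"
FAIL_QUAL = "B"


def simulate_reads(pool: FragmentPool, n_reads: int, read_len: int = 50,
                   err_rate: float = 0.0, b_tail_prob: float = 0.0,
                   seed: int = 0) -> ReadLibrary:
    """Sample single-end reads from a fragment pool.

    Reads start uniformly within their fragment and truncate at the fragment
    end; strand is uniform; substitution errors are i.i.d. at err_rate. With
    probability b_tail_prob the quality string fails into a run of 'B'
    characters starting at a uniform position and continuing to the end.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    rng = np.random.default_rng(seed)
    n_frag = len(pool)
    w = pool.abundances
    if abs(w.sum() - 1.0) < 1e-9 and np.allclose(w, w[0]):
        frag_idx = rng.integers(0, n_frag, size=n_reads)
    else:
        frag_idx = rng.choice(n_frag, size=n_reads, p=w / w.sum())

    reads: list[Read] = []
    for i in range(n_reads):
        fi = int(frag_idx[i])
        fseq = pool.fragments[fi].seq
        L = len(fseq)
        if L <= read_len:
            sub = fseq
        else:
            s = int(rng.integers(0, L - read_len + 1))
            sub = fseq[s:s + read_len]
        if rng.random() < 0.5:
            sub = revcomp(sub)
        if err_rate > 0:
            sub = mutate(rng, sub, err_rate)
        qual = PASS_QUAL * len(sub)
        if b_tail_prob > 0 and rng.random() < b_tail_prob:
            p = int(rng.integers(0, len(sub)))
            qual = qual[:p] + FAIL_QUAL * (len(sub) - p)
        reads.append(Read(f"r{i:07d}", sub, qual, frag=fi))
    return ReadLibrary(reads, treatment="control", salt="none",
                       renat_hours=0.0, seed=seed)


def read_origins(library: ReadLibrary, pool: FragmentPool) -> list[str]:
    """Ground-truth origin class of each read (via its source fragment)."""
    return [pool.fragments[r.frag].origin if r.frag >= 0 else "unknown"
            for r in library.reads]
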