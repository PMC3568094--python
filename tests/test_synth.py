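"""Synthetic genome / fragment pool / read simulator."""

import itertools

import numpy as np
import pytest

from dsnnorm.lib_io import write_fastq
from dsnnorm.seqs import minimal_period, revcomp
from dsnnorm.synth import (ExpressionProfile, GenomeConfig, RepeatFamily,
                           build_genome, fragment_source, make_gene,
                           simulate_reads)


def _config(families=(), genes=(), bg=2000, **kw):
    return GenomeConfig(repeat_families=list(families), genes=list(genes),
                        background_len=bg,
                        organelle_lengths={"chloroplast": 3000,
                                           "mitochondrion": 2000}, **kw)


class TestBuildGenome:
    def test_single_undiverged_copy_is_planted_verbatim(self):
        fam = RepeatFamily("u", "ATGCATGCATGCA", 1, 0.0)
        g = build_genome(_config([fam]), seed=1)
        feats = [f for f in g.features if f.feature_id == "u"]
        assert len(feats) == 1
        assert g.extract_feature(feats[0]) == fam.unit_seq

    def test_telomeric_family_plants_identical_copies(self):
        fam = RepeatFamily("tel", "TTTAGGG", 1000, 0.0)
        g = build_genome(_config([fam], bg=5000), seed=2)
        copies = g.feature_copies("tel")
        assert len(copies) == 1000
        assert set(copies) == {"TTTAGGG"}

    def test_pairwise_identity_matches_substitution_model(self, rng):
        # two copies mutated at rate p agree per site with prob
        # (1-p)^2 + p^2/3; checked against brute-force pairwise comparison
        p = 0.05
        fam = RepeatFamily("r", "".join(rng.choice(list("ACGT"), 400)),
                           50, p)
        g = build_genome(_config([fam], bg=1000), seed=3)
        copies = g.feature_copies("r")
        idents = [sum(a == b for a, b in zip(x, y)) / len(x)
                  for x, y in itertools.combinations(copies, 2)]
        expected = (1 - p) ** 2 + p ** 2 / 3
        assert abs(np.mean(idents) - expected) < 0.01

    def test_gene_gc_realized_within_tolerance(self, rng):
        for target in (0.35, 0.45, 0.55):
            gene = make_gene(rng, "g", 200, target)
            assert abs(gene.gc - target) <= 0.03
            assert gene.cds_seq.startswith("ATG")

    def test_features_lie_in_bounds_and_do_not_overlap(self):
        fams = [RepeatFamily("a", "ACGTACGTAA", 20, 0.1),
                RepeatFamily("b", "TTGCATGCAC", 30, 0.0)]
        g = build_genome(_config(fams), seed=4)
        feats = sorted(g.features, key=lambda f: f.start)
        for f in feats:
            assert 0 <= f.start < f.end <= len(g.nuclear_seq)
        for f1, f2 in zip(feats, feats[1:]):
            assert f1.end <= f2.start

    @pytest.mark.parametrize("bad", [
        dict(copy_number=0), dict(divergence=0.31), dict(divergence=-0.1),
    ])
    def test_invalid_family_rejected(self, bad):
        kw = dict(name="x", unit_seq="ACGTACGT", copy_number=2,
                  divergence=0.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            RepeatFamily(**kw)

    def test_organelle_fractions_must_sum_below_one(self):
        cfg = _config()
        cfg.organelle_read_fractions = {"chloroplast": 0.7,
                                        "mitochondrion": 0.3}
        with pytest.raises(ValueError):
            build_genome(cfg, seed=0)

    def test_deterministic_for_fixed_seed(self):
        cfg = _config([RepeatFamily("a", "ACGTACGTAA", 5, 0.2)])
        g1 = build_genome(cfg, seed=7)
        g2 = build_genome(cfg, seed=7)
        assert g1.nuclear_seq == g2.nuclear_seq
        assert g1.organelle_seqs == g2.organelle_seqs
        assert g1.features == g2.features


class TestMinimalPeriod:
    def test_tandem_and_aperiodic_units(self):
        assert minimal_period("TTTAGGG" * 10) == 7
        assert minimal_period("CAACAACAA") == 3
        assert minimal_period("ACGTTGCA") == 8


class TestFragmentSource:
    def test_short_source_shears_to_itself(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        profile = ExpressionProfile({"g": 1.0})
        pool = fragment_source({"g": seq}, mean_len=300, n_fragments=1,
                               seed=0, expression=profile)
        assert len(pool) == 1
        assert pool.fragments[0].seq == seq

    def test_transcript_shares_follow_expression(self, rng):
        seqs = {"a": "".join(rng.choice(list("ACGT"), 300)),
                "b": "".join(rng.choice(list("ACGT"), 300))}
        profile = ExpressionProfile({"a": 0.9, "b": 0.1})
        n = 100_000
        pool = fragment_source(seqs, mean_len=300, n_fragments=n, seed=1,
                               expression=profile)
        n_a = sum(f.origin == "a" for f in pool.fragments)
        sigma = (n * 0.9 * 0.1) ** 0.5
        assert abs(n_a - 0.9 * n) < 3 * sigma

    def test_copy_number_drives_fragment_share(self, rng):
        unit = "".join(rng.choice(list("ACGT"), 450))
        fam = RepeatFamily("rep", unit, 100, 0.0)
        gene = make_gene(rng, "g1", 150, 0.45)  # same 450 nt length
        g = build_genome(_config([fam], [gene], bg=2000), seed=5)
        g.organelle_read_fractions = {}
        g.organelle_seqs = {}
        pool = fragment_source(g, mean_len=300, n_fragments=50_000, seed=2)
        shares = pool.class_shares()
        ratio = shares["rep"] / shares["g1"]
        assert 70 < ratio < 140  # expectation 100:1

    def test_organelle_share_matches_fractions(self):
        g = build_genome(_config(bg=20000), seed=6)
        n = 50_000
        pool = fragment_source(g, mean_len=300, n_fragments=n, seed=3)
        shares = pool.class_shares()
        for name, frac in g.organelle_read_fractions.items():
            sigma = (frac * (1 - frac) / n) ** 0.5
            assert abs(shares[name] - frac) < 3 * sigma

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError):
            fragment_source({}, expression=ExpressionProfile({"x": 1.0}))


class TestSimulateReads:
    @pytest.fixture
    def pool(self, rng):
        seqs = {"a": "".join(rng.choice(list("ACGT"), 600))}
        return fragment_source(seqs, mean_len=300, n_fragments=200, seed=4,
                               expression=ExpressionProfile({"a": 1.0}))

    def test_error_free_reads_are_exact_substrings(self, pool):
        lib = simulate_reads(pool, 500, read_len=50, seed=5)
        frags = [f.seq for f in pool.fragments]
        for r in lib.reads:
            f = frags[r.frag]
            assert r.seq in f or revcomp(r.seq) in f

    def test_b_tail_prob_one_marks_every_read(self, pool):
        lib = simulate_reads(pool, 300, read_len=50, b_tail_prob=1.0, seed=6)
        assert all("B" in r.qual for r in lib.reads)
        for r in lib.reads:  # failure runs extend to the end of the read
            assert r.qual.endswith("B")

    def test_error_rate_recovered_from_mismatches(self, rng):
        src = "".join(rng.choice(list("ACGT"), 400))
        pool = fragment_source({"g": src}, mean_len=300, n_fragments=1,
                               seed=0, expression=ExpressionProfile({"g": 1}))
        n, L, e = 20_000, 50, 0.01
        lib = simulate_reads(pool, n, read_len=L, err_rate=e, seed=7)
        mism = 0
        for r in lib.reads:
            # locate by trying both orientations at every offset
            best = min(
                min(sum(a != b for a, b in zip(cand, src[i:i + L]))
                    for i in range(len(src) - L + 1))
                for cand in (r.seq, revcomp(r.seq)))
            mism += best
        frac = mism / (n * L)
        sigma = (e * (1 - e) / (n * L)) ** 0.5
        assert abs(frac - e) < 3 * sigma

    def test_fixed_seed_gives_byte_identical_fastq(self, pool, tmp_path):
        paths = []
        for i in (1, 2):
            lib = simulate_reads(pool, 200, read_len=50, err_rate=0.01,
                                 b_tail_prob=0.2, seed=99)
            p = tmp_path / f"lib{i}.fastq"
            write_fastq(p, lib)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_n_reads_must_be_positive(self, pool):
        with pytest.raises(ValueError):
            simulate_reads(pool, 0)
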