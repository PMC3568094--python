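"""ORF extraction, de-duplication and single-copy gene identification."""

import numpy as np
import pytest
from Bio.Seq import Seq

from dsnnorm.geneset import (dedup_regions, extract_cds_regions,
                             identify_single_copy)
from dsnnorm.seqs import random_seq, revcomp
from dsnnorm.synth import make_gene


def _translate(cds):
    return str(Seq(cds).translate())


@pytest.fixture
def genes(rng):
    return [make_gene(rng, f"g{i}", int(rng.integers(60, 120)), 0.45)
            for i in range(25)]


class TestExtractCds:
    def test_exact_coding_contig_recovered_in_frame_one(self, rng):
        gene = make_gene(rng, "g", 80, 0.45)
        regions = extract_cds_regions({"c1": gene.cds_seq},
                                      {"p": _translate(gene.cds_seq)},
                                      min_codons=50)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.strand, r.frame) == (0, len(gene.cds_seq),
                                                       "+", 0)
        assert r.seq == gene.cds_seq

    def test_internal_stop_truncates_or_discards(self, rng):
        gene = make_gene(rng, "g", 100, 0.45)
        cds = gene.cds_seq
        broken = cds[:150] + "TAA" + cds[153:]  # stop at codon 50
        regions = extract_cds_regions({"c1": broken},
                                      {"p": _translate(cds)}, min_codons=40)
        for r in regions:
            assert "*" not in r.aa
            assert not (r.start <= 150 < r.end and r.strand == "+"
                        and (150 - r.start) % 3 == r.frame == 0
                        and r.seq[150 - r.start:153 - r.start] == "TAA")

    def test_planted_genes_recovered_with_exact_coordinates(self, genes):
        contigs = {g.gene_id: g.cds_seq for g in genes}
        proteins = {f"p_{g.gene_id}": _translate(g.cds_seq) for g in genes}
        regions = extract_cds_regions(contigs, proteins, min_codons=50)
        exact = {(r.contig_id, r.start, r.end, r.strand) for r in regions}
        hits = sum((g.gene_id, 0, len(g.cds_seq), "+") in exact
                   for g in genes)
        assert hits >= 0.95 * len(genes)

    def test_reverse_strand_gene_found(self, rng):
        gene = make_gene(rng, "g", 80, 0.45)
        contig = revcomp(gene.cds_seq)
        regions = extract_cds_regions({"c1": contig},
                                      {"p": _translate(gene.cds_seq)},
                                      min_codons=50)
        assert any(r.strand == "-" and r.seq == gene.cds_seq
                   for r in regions)

    def test_emitted_regions_translate_without_stops(self, genes):
        contigs = {g.gene_id: g.cds_seq for g in genes}
        proteins = {"p0": _translate(genes[0].cds_seq)}
        for r in extract_cds_regions(contigs, proteins, min_codons=30):
            assert "*" not in _translate(r.seq)

    def test_empty_protein_set_rejected(self):
        with pytest.raises(ValueError):
            extract_cds_regions({"c": "ATGAAA"}, {})


class TestDedup:
    def _regions(self, rng, seqs):
        gene = make_gene(rng, "g", 60, 0.45)
        out = []
        for i, s in enumerate(seqs):
            regions = extract_cds_regions({f"c{i}": s},
                                          {"p": _translate(s[:len(s) // 3 * 3])},
                                          min_codons=10)
            if regions:
                out.append(regions[0])
        return out

    def test_identical_regions_collapse_to_one(self, rng):
        cds = make_gene(rng, "g", 60, 0.45).cds_seq
        regions = self._regions(rng, [cds, cds])
        assert len(dedup_regions(regions)) == 1

    def test_disjoint_regions_both_kept(self, rng):
        a = make_gene(rng, "a", 60, 0.35).cds_seq
        b = make_gene(rng, "b", 60, 0.55).cds_seq
        regions = self._regions(rng, [a, b])
        assert len(dedup_regions(regions)) == 2

    def test_redundant_set_matches_transitive_filter(self, rng):
        bases = [make_gene(rng, f"b{i}", 80, 0.45).cds_seq for i in range(4)]
        seqs, truth = [], []
        for i, b in enumerate(bases):
            seqs.append(b)
            truth.append(i)
            if i % 2 == 0:  # an exact duplicate of the full sequence
                seqs.append(b)
                truth.append(i)
        regions = self._regions(rng, seqs)
        kept = dedup_regions(regions)
        # exactly one representative per base sequence survives
        assert len(kept) == len(bases)
        assert len({r.seq for r in kept}) == len(bases)


class TestSingleCopy:
    def test_unique_atg_single_locus_accepted(self, rng):
        genes = [make_gene(rng, f"g{i}", 60, 0.35 + 0.05 * i)
                 for i in range(3)]
        contigs = {g.gene_id: g.cds_seq for g in genes}
        proteins = {f"p{g.gene_id}": _translate(g.cds_seq) for g in genes}
        regions = dedup_regions(extract_cds_regions(contigs, proteins,
                                                    min_codons=40))
        spacer = random_seq(np.random.default_rng(0), 200, 0.4)
        gene_space = {"scaf1": spacer + genes[0].cds_seq + spacer,
                      "scaf2": spacer + genes[1].cds_seq + spacer +
                               genes[2].cds_seq + spacer}
        calls = identify_single_copy(regions, gene_space)
        assert calls and all(c.accepted for c in calls)

    def test_two_genomic_loci_rejected(self, rng):
        gene = make_gene(rng, "g", 60, 0.45)
        regions = dedup_regions(extract_cds_regions(
            {"c": gene.cds_seq}, {"p": _translate(gene.cds_seq)},
            min_codons=40))
        spacer = random_seq(np.random.default_rng(1), 150, 0.4)
        gene_space = {"scaf": spacer + gene.cds_seq + spacer +
                              gene.cds_seq + spacer}
        calls = identify_single_copy(regions, gene_space)
        assert calls and not calls[0].single_locus
        assert not calls[0].accepted

    def test_precision_on_synthetic_truth(self, rng):
        # 10 unique genes; two of them planted twice in the gene space
        genes = [make_gene(rng, f"g{i}", 70, float(rng.uniform(0.35, 0.55)))
                 for i in range(10)]
        contigs = {g.gene_id: g.cds_seq for g in genes}
        proteins = {f"p{g.gene_id}": _translate(g.cds_seq) for g in genes}
        regions = dedup_regions(extract_cds_regions(contigs, proteins,
                                                    min_codons=40))
        sp = random_seq(rng, 150, 0.4)
        multi = {"g0", "g1"}
        parts = []
        for g in genes:
            parts += [sp, g.cds_seq]
            if g.gene_id in multi:
                parts += [sp, g.cds_seq]
        gene_space = {"scaf": "".join(parts) + sp}
        calls = identify_single_copy(regions, gene_space)
        by_id = {}
        for r, c in zip(regions, calls):
            by_id[r.contig_id] = c.accepted
        accepted = {g for g, ok in by_id.items() if ok}
        true_single = {g.gene_id for g in genes} - multi
        precision = len(accepted & true_single) / max(len(accepted), 1)
        assert precision >= 0.95
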