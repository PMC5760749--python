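"""Genome model, translation, statistics and marker comparison."""

import numpy as np
import pytest
from Bio.Seq import Seq

import strainpair as sp
from strainpair.genome import (
    FeatureKind,
    _extract_gene,
    load_genome,
    write_fasta,
    write_genbank,
    write_gff3,
)


def _write_pair(tmp_path, genome):
    write_fasta(genome, tmp_path / "g.fasta")
    write_gff3(genome, tmp_path / "g.gff3")
    return tmp_path / "g.fasta", tmp_path / "g.gff3"


class TestTranslation:
    def test_forward_cds_translates_and_trims_stop(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        gff = tmp_path / "g.gff3"
        fasta.write_text(">chr1\nATGAAATAA\n")
        gff.write_text(
            "##gff-version 3\nchr1\t.\tCDS\t1\t9\t.\t+\t0\tID=g1;locus_tag=g1\n"
        )
        g = load_genome(fasta, "fasta+gff3", gff)
        assert g.genes[0].aa_seq == "MK"
        assert g.genes[0].nt_seq == "ATGAAATAA"

    def test_reverse_strand_matches_revcomp_oracle(self, tmp_path):
        # brute-force oracle: reverse complement by hand, then codon lookup
        rng = np.random.default_rng(7)
        codons = ["ATG"] + ["".join(rng.choice(list("ACGT"), 3)) for _ in range(20)]
        codons = [c for c in codons if c not in ("TAA", "TAG", "TGA")] + ["TAA"]
        coding = "".join(codons)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        genome_seq = "".join(comp[b] for b in reversed(coding))
        fasta = tmp_path / "g.fasta"
        gff = tmp_path / "g.gff3"
        fasta.write_text(f">chr1\n{genome_seq}\n")
        gff.write_text(
            f"##gff-version 3\nchr1\t.\tCDS\t1\t{len(coding)}\t.\t-\t0\tID=g1;locus_tag=g1\n"
        )
        g = load_genome(fasta, "fasta+gff3", gff)
        expected = str(Seq(coding).translate(table=11)).rstrip("*")
        expected = "M" + expected[1:]
        assert g.genes[0].nt_seq == coding
        assert g.genes[0].aa_seq == expected

    def test_non_atg_start_rendered_as_m(self):
        gene = _extract_gene("GTGAAATAA", "g", 0, 9, "+", FeatureKind.CDS, "")
        assert gene.aa_seq == "MK"

    def test_partial_cds_flagged_and_excluded(self):
        gene = _extract_gene("ATGAAAT", "g", 0, 7, "+", FeatureKind.CDS, "")
        assert gene.partial and gene.aa_seq == ""

    def test_cds_length_identity(self, paper_like_pair):
        genome_a, _, _ = paper_like_pair
        for g in genome_a.cds:
            assert 3 * len(g.aa_seq) + 3 == len(g.nt_seq)


class TestSummary:
    def test_all_gc_sequence(self):
        g = sp.Genome("t", "GGCC", [])
        s = sp.summarize(g)
        assert s.gc_percent == 100.0 and s.n_genes == 0

    def test_gc_matches_base_tally_oracle(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGTN"), 10_000, p=[0.3, 0.18, 0.19, 0.3, 0.03]))
        tally = {b: 0 for b in "ACGTN"}
        for b in seq:  # independent single-pass oracle
            tally[b] += 1
        assert sum(tally.values()) == len(seq)
        expected = round(100 * (tally["G"] + tally["C"]) / (len(seq) - tally["N"]), 1)
        assert sp.summarize(sp.Genome("t", seq, [])).gc_percent == expected

    def test_counts_partition_genes(self, paper_like_pair):
        genome_a, _, _ = paper_like_pair
        s = sp.summarize(genome_a)
        assert s.n_genes == s.n_cds + s.n_trna + s.n_rrna + s.n_other_rna
        assert s.length_bp == len(genome_a)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            sp.summarize(sp.Genome("t", "", []))


class TestRoundTrip:
    def test_genbank_and_gff3_round_trips(self, tmp_path, backbone_only_pair):
        genome_a, _, _ = backbone_only_pair
        write_genbank(genome_a, tmp_path / "a.gbk")
        fasta, gff = _write_pair(tmp_path, genome_a)
        for reloaded in (
            load_genome(tmp_path / "a.gbk", "genbank"),
            load_genome(fasta, "fasta+gff3", gff),
        ):
            assert reloaded.sequence == genome_a.sequence
            assert len(reloaded.genes) == len(genome_a.genes)
            for g1, g2 in zip(reloaded.genes, genome_a.genes):
                assert (g1.start, g1.end, g1.strand, g1.nt_seq, g1.aa_seq) == (
                    g2.start, g2.end, g2.strand, g2.nt_seq, g2.aa_seq,
                )

    def test_multi_record_file_rejected(self, tmp_path):
        fasta = tmp_path / "two.fasta"
        fasta.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(ValueError, match="2 records"):
            load_genome(fasta, "fasta+gff3", tmp_path / "missing.gff3")

    def test_coordinates_outside_sequence_rejected(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        gff = tmp_path / "g.gff3"
        fasta.write_text(">chr1\nATGAAATAA\n")
        gff.write_text("##gff-version 3\nchr1\t.\tCDS\t1\t90\t.\t+\t0\tID=g1\n")
        with pytest.raises(ValueError, match="outside"):
            load_genome(fasta, "fasta+gff3", gff)


class TestMarkerCopies:
    def _rrna_genome(self, gid, copies):
        seq_parts, genes, pos = [], [], 0
        for i, c in enumerate(copies):
            seq_parts.append(c)
            genes.append(
                sp.Gene(
                    locus_tag=f"{gid}_r{i}", ordinal=i, start=pos, end=pos + len(c),
                    strand="+", feature_kind=FeatureKind.rRNA,
                    product="16S ribosomal RNA", nt_seq=c,
                )
            )
            pos += len(c)
        return sp.Genome(gid, "".join(seq_parts), genes)

    def test_self_comparison_is_zero(self):
        rng = np.random.default_rng(0)
        c = "".join(rng.choice(list("ACGT"), 1500))
        g = self._rrna_genome("a", [c, c])
        assert [d for _, d in sp.compare_marker_copies(g, g)] == [0, 0]

    def test_enumerated_substitutions_counted(self):
        rng = np.random.default_rng(1)
        c1 = "".join(rng.choice(list("ACGT"), 1500))
        c2 = list(c1)
        for p in (10, 700, 1400):  # positional diff oracle: 3 known changes
            c2[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[c2[p]]
        one_off = list(c1)
        one_off[33] = {"A": "C", "C": "G", "G": "T", "T": "A"}[one_off[33]]
        a = self._rrna_genome("a", [c1, "".join(one_off)])
        b = self._rrna_genome("b", [c1, "".join(c2)])
        dists = sorted(d for _, d in sp.compare_marker_copies(a, b))
        assert dists == [0, 1]

    def test_missing_marker_errors(self):
        g = sp.Genome("t", "ACGT", [])
        with pytest.raises(ValueError, match="16S"):
            sp.compare_marker_copies(g, g)
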