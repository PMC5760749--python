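"""Codon counting, modal usage estimation, mode distance, shuffled null."""

import numpy as np
import pytest

import strainpair as sp
from strainpair.codon import (
    CODONS,
    CODON_INDEX,
    FAMILIES,
    CodonCounts,
    compute_mode,
    count_codons,
    counts_from_tsv,
    counts_tsv,
    mode_distance,
    shuffled_null,
)


def cds_gene(nt, locus="g1"):
    return sp.Gene(
        locus_tag=locus, ordinal=0, start=0, end=len(nt), strand="+",
        feature_kind=sp.FeatureKind.CDS, nt_seq=nt, aa_seq="M" * (len(nt) // 3 - 1),
    )


from helpers_codon import family_noise_floor, family_tvs, weighted_tv


class TestCounting:
    def test_counts_with_termini(self):
        c = count_codons(cds_gene("ATGAAAAAATAA"), exclude_termini=False)
        assert c.n_codons == 4
        assert c.counts[CODON_INDEX["ATG"]] == 1
        assert c.counts[CODON_INDEX["AAA"]] == 2
        assert c.counts[CODON_INDEX["TAA"]] == 1

    def test_counts_excluding_termini(self):
        c = count_codons(cds_gene("ATGAAAAAATAA"), exclude_termini=True)
        assert c.n_codons == 2
        assert c.counts[CODON_INDEX["AAA"]] == 2
        assert c.counts[CODON_INDEX["ATG"]] == 0

    def test_random_cds_matches_sliding_tally_oracle(self):
        rng = np.random.default_rng(12)
        body = "".join(rng.choice(CODONS, 300))
        nt = "ATG" + body + "TAA"
        c = count_codons(cds_gene(nt), exclude_termini=True)
        oracle = {}
        for i in range(3, len(nt) - 3, 3):  # independent sliding-index tally
            oracle[nt[i : i + 3]] = oracle.get(nt[i : i + 3], 0) + 1
        for codon, n in oracle.items():
            assert c.counts[CODON_INDEX[codon]] == n
        assert c.n_codons == sum(oracle.values())

    def test_ambiguous_codons_skipped(self):
        c = count_codons(cds_gene("ATGAANAAATAA"))
        assert c.n_codons == 1

    def test_non_cds_and_partial_rejected(self):
        rna = sp.Gene(
            locus_tag="r", ordinal=0, start=0, end=9, strand="+",
            feature_kind=sp.FeatureKind.rRNA, nt_seq="ATGAAATAA",
        )
        with pytest.raises(ValueError):
            count_codons(rna)
        bad = cds_gene("ATGAAAAAATAA")
        bad.partial = True
        with pytest.raises(ValueError):
            count_codons(bad)

    def test_tsv_round_trip(self):
        genes = sp.sample_codon_counts(sp.default_backbone_bias(), 5, 3)
        back = counts_from_tsv(counts_tsv(genes))
        for g1, g2 in zip(genes, back):
            assert g1.gene_id == g2.gene_id
            assert (g1.counts == g2.counts).all()


class TestComputeMode:
    def test_single_gene_is_its_own_mode(self):
        g = sp.sample_codon_counts(sp.default_backbone_bias(), 1, 5)[0]
        mode = compute_mode([g])
        assert mode.conforming_genes == {g.gene_id}
        for aa, idx in FAMILIES.items():
            fam = g.counts[list(idx)]
            if fam.sum():
                assert mode.freqs[aa] == pytest.approx(fam / fam.sum())

    def test_homogeneous_set_recovers_bias(self):
        bias = sp.default_backbone_bias()
        genes = sp.sample_codon_counts(bias, 200, 17)
        mode = compute_mode(genes)
        assert mode.converged
        # aggregate recovery within 0.02; each family within its binomial
        # noise floor (rare amino acids carry few codons at this scale)
        assert weighted_tv(mode, bias) <= 0.02
        floors = family_noise_floor(mode)
        for aa, tv in family_tvs(mode, bias).items():
            assert tv <= max(0.02, floors[aa]), (aa, tv, floors[aa])
        assert len(mode.conforming_genes) >= 0.7 * len(genes)

    def test_mode_is_fixed_point(self):
        genes = sp.sample_codon_counts(sp.default_backbone_bias(), 100, 23)
        mode = compute_mode(genes)
        conforming = [g for g in genes if g.gene_id in mode.conforming_genes]
        pooled = np.sum([g.counts for g in conforming], axis=0)
        for aa, idx in FAMILIES.items():
            fam = pooled[list(idx)]
            if fam.sum():
                assert mode.freqs[aa] == pytest.approx(fam / fam.sum(), abs=1e-12)

    def test_contaminated_set_converges_to_majority(self):
        bias = sp.default_backbone_bias()
        donor = sp.shifted_bias(bias, 0.5)
        rng = np.random.default_rng(31)
        majority = sp.sample_codon_counts(bias, 160, rng, prefix="f1_")
        minority = sp.sample_codon_counts(donor, 40, rng, prefix="f2_")
        mode = compute_mode(majority + minority)
        kept_majority = sum(1 for g in mode.conforming_genes if g.startswith("f1_"))
        kept_minority = sum(1 for g in mode.conforming_genes if g.startswith("f2_"))
        # the p>0.1 fixed point retains ~3/4 of even perfectly conforming
        # genes; what matters is that the divergent cluster is rejected and
        # the mode tracks the majority bias
        assert kept_majority >= 0.7 * 160
        assert kept_minority <= 2
        assert weighted_tv(mode, bias) <= 0.03
        floors = family_noise_floor(mode)
        for aa, tv in family_tvs(mode, bias).items():
            assert tv <= max(0.03, floors[aa]), (aa, tv, floors[aa])

    def test_invariant_to_order_and_duplication(self):
        genes = sp.sample_codon_counts(sp.default_backbone_bias(), 60, 41)
        mode1 = compute_mode(genes)
        mode2 = compute_mode(genes[::-1])
        doubled = genes + [CodonCounts(g.gene_id + "_dup", g.counts, g.n_codons) for g in genes]
        mode3 = compute_mode(doubled)
        for aa in FAMILIES:
            assert mode1.freqs[aa] == pytest.approx(mode2.freqs[aa])
            assert mode1.freqs[aa] == pytest.approx(mode3.freqs[aa], abs=1e-9)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            compute_mode([])


class TestModeDistance:
    def test_identical_modes_distance_zero(self):
        genes = sp.sample_codon_counts(sp.default_backbone_bias(), 50, 7)
        m = compute_mode(genes)
        assert mode_distance(m, m) == 0.0

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(19)
        bias = sp.default_backbone_bias()
        m1 = compute_mode(sp.sample_codon_counts(bias, 40, rng))
        m2 = compute_mode(sp.sample_codon_counts(sp.shifted_bias(bias, 0.3), 40, rng))
        d12, d21 = mode_distance(m1, m2), mode_distance(m2, m1)
        assert d12 == pytest.approx(d21)
        assert 0 <= d12 <= 1

    def test_two_family_toy_matches_hand_computation(self):
        # two synthetic "modes" built from explicit counts:
        # gene set 1: 60 Lys codons (AAA:40, AAG:20), 40 Asn (AAC:10, AAT:30)
        # gene set 2: 60 Lys codons (AAA:10, AAG:50), 40 Asn (AAC:30, AAT:10)
        def counts(k_aaa, k_aag, n_aac, n_aat, gid):
            v = np.zeros(64, dtype=np.int64)
            v[CODON_INDEX["AAA"]], v[CODON_INDEX["AAG"]] = k_aaa, k_aag
            v[CODON_INDEX["AAC"]], v[CODON_INDEX["AAT"]] = n_aac, n_aat
            return CodonCounts(gid, v, int(v.sum()))

        m1 = compute_mode([counts(40, 20, 10, 30, "x")])
        m2 = compute_mode([counts(10, 50, 30, 10, "y")])
        # weights: K = 0.6, N = 0.4 in both sets; TV(K) = |2/3-1/6| = 0.5,
        # TV(N) = |1/4-3/4| = 0.5 -> distance 0.6*0.5 + 0.4*0.5 = 0.5
        assert mode_distance(m1, m2) == pytest.approx(0.5)

    def test_mismatched_family_structure_errors(self):
        genes = sp.sample_codon_counts(sp.default_backbone_bias(), 10, 3)
        m1 = compute_mode(genes)
        m2 = compute_mode(genes)
        broken = dict(m2.freqs)
        broken.pop("K")
        m2.freqs = broken
        with pytest.raises(ValueError):
            mode_distance(m1, m2)


class TestShuffledNull:
    def test_identical_sets_observed_zero(self):
        genes = sp.sample_codon_counts(sp.default_backbone_bias(), 30, 3)
        res = shuffled_null(genes, list(genes), n_rounds=3, seed=1)
        assert res.observed_distance == 0.0

    def test_reproducible_from_seed(self):
        bias = sp.default_backbone_bias()
        s1 = sp.sample_codon_counts(bias, 30, 5, prefix="a")
        s2 = sp.sample_codon_counts(bias, 60, 6, prefix="b")
        r1 = shuffled_null(s1, s2, n_rounds=5, seed=42)
        r2 = shuffled_null(s1, s2, n_rounds=5, seed=42)
        assert r1.per_round_distances == r2.per_round_distances
        r3 = shuffled_null(s1, s2, n_rounds=5, seed=43)
        assert r1.per_round_distances != r3.per_round_distances

    def test_planted_divergence_detected(self):
        bias = sp.default_backbone_bias()
        donor = sp.shifted_bias(bias, 0.4)
        s1 = sp.sample_codon_counts(donor, 40, 8, prefix="d")
        s2 = sp.sample_codon_counts(bias, 200, 9, prefix="b")
        res = shuffled_null(s1, s2, n_rounds=10, seed=2)
        assert res.observed_distance > res.null_mean + 3 * res.null_sd

    def test_empty_set_errors(self):
        genes = sp.sample_codon_counts(sp.default_backbone_bias(), 5, 1)
        with pytest.raises(ValueError):
            shuffled_null([], genes)


class TestHgtReport:
    def test_row_structure_and_flags(self, paper_like_pair, paper_like_map):
        genome_a, genome_b, _ = paper_like_pair
        regions = sp.call_regions(paper_like_map, genome_a, genome_b)
        df = sp.hgt_report(genome_a, genome_b, regions, n_rounds=3, seed=0)
        # 1 whole-chromosome row + per genome: each region vs rest + region pairs
        n_regions = len(regions)
        per_genome = n_regions + n_regions * (n_regions - 1) // 2
        assert len(df) == 1 + 2 * per_genome
        assert (df["flag"] == "").all()
        assert df["observed_distance"].between(0, 1).all()

    def test_self_comparison_distance_zero(self, backbone_only_pair):
        genome_a, _, _ = backbone_only_pair
        df = sp.hgt_report(genome_a, genome_a, [], n_rounds=3, seed=0)
        assert df.iloc[0]["observed_distance"] == pytest.approx(0.0, abs=1e-12)
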