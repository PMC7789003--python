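"""Intron catalog: filter semantics, strand handling, splice-site
classification and frequency matrices, gene typing."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from introner._utils import revcomp
from introner.introns import (Intron, classify_splice_sites,
                              extract_validated_introns, gene_intron_typing,
                              splice_site_frequency)
from introner.io import GeneModel, GenomeSeq, JunctionRecord


def make_scaffold(name, seq):
    return GenomeSeq(name, seq)


def intron_on(seq, start=1, end=None, strand="+"):
    end = end or len(seq)
    return Intron("s", start, end, strand, seq, support=5)


class TestFiltering:
    def setup_method(self):
        rng = np.random.default_rng(0)
        body = "".join(rng.choice(list("ACGT"), size=5000))
        self.genome = [make_scaffold("s1", body)]

    def test_support_threshold_inclusive_at_three(self):
        juncs = [JunctionRecord("s1", 101, 200, "+", s) for s in (2,)] + \
                [JunctionRecord("s1", 301, 400, "+", 3),
                 JunctionRecord("s1", 501, 600, "+", 5)]
        out = extract_validated_introns(juncs, self.genome, [])
        assert len(out) == 2

    def test_length_window_closed_40_1000(self):
        juncs = [JunctionRecord("s1", 100, 100 + L - 1, "+", 9)
                 for L in (39, 40, 1000, 1001)]
        out = extract_validated_introns(juncs, self.genome, [])
        assert sorted(i.length for i in out) == [40, 1000]

    def test_duplicates_merge_support_before_threshold(self):
        juncs = [JunctionRecord("s1", 101, 200, "+", 2),
                 JunctionRecord("s1", 101, 200, "+", 2)]
        out = extract_validated_introns(juncs, self.genome, [])
        assert len(out) == 1 and out[0].support == 4

    def test_out_of_bounds_junction_skipped_not_fatal(self):
        juncs = [JunctionRecord("s1", 4990, 5100, "+", 9)]
        assert extract_validated_introns(juncs, self.genome, []) == []

    def test_ten_junction_toy_attrition(self):
        # supports {2,3,5,1,8,4,9,3,2,7} with lengths straddling the window:
        # three fail support (2,1,2), two fail length (39, 1001) -> 5 retained
        cases = [(2, 100), (3, 100), (5, 39), (1, 500), (8, 1001),
                (4, 100), (9, 40), (3, 1000), (2, 41), (7, 100)]
        juncs = []
        pos = 10
        for support, length in cases:
            juncs.append(JunctionRecord("s1", pos, pos + length - 1, "+", support))
            pos += 5
        out = extract_validated_introns(juncs, self.genome, [])
        assert len(out) == 5


class TestStrandHandling:
    def test_minus_strand_sense_sequence_reverse_complemented(self):
        # plus-strand slice CT...AC becomes sense GT...AG on '-'
        plus = "CT" + "GCAA" * 12 + "AC"
        genome = [make_scaffold("s1", "T" * 10 + plus + "T" * 10)]
        juncs = [JunctionRecord("s1", 11, 10 + len(plus), "-", 5)]
        (out,) = extract_validated_introns(juncs, genome, [])
        assert out.seq.startswith("GT") and out.seq.endswith("AG")
        assert out.klass == "canonical"

    def test_unknown_strand_resolved_from_splice_dinucleotides(self):
        plus = "CT" + "GCAA" * 12 + "AC"
        genome = [make_scaffold("s1", "T" * 10 + plus + "T" * 10)]
        juncs = [JunctionRecord("s1", 11, 10 + len(plus), "?", 5)]
        (out,) = extract_validated_introns(juncs, genome, [])
        assert out.strand == "-"

    def test_unresolvable_unknown_strand_defaults_plus(self):
        plus = "TT" + "GCAA" * 12 + "TT"
        genome = [make_scaffold("s1", "T" * 10 + plus + "T" * 10)]
        juncs = [JunctionRecord("s1", 11, 10 + len(plus), "?", 5)]
        (out,) = extract_validated_introns(juncs, genome, [])
        assert out.strand == "+"

    def test_sense_sequence_invariant_under_scaffold_reverse_complement(self):
        rng = np.random.default_rng(1)
        body = "".join(rng.choice(list("ACGT"), size=500))
        fwd = [make_scaffold("s", body)]
        rev = [make_scaffold("s", revcomp(body))]
        j_fwd = JunctionRecord("s", 101, 200, "+", 5)
        j_rev = JunctionRecord("s", 500 - 200 + 1, 500 - 101 + 1, "-", 5)
        (a,) = extract_validated_introns([j_fwd], fwd, [])
        (b,) = extract_validated_introns([j_rev], rev, [])
        assert a.seq == b.seq


class TestClassification:
    @pytest.mark.parametrize("donor,acceptor,cat,klass", [
        ("GT", "AG", "GT-AG", "canonical"),
        ("GC", "AG", "GC/GA-AG", "NCI"),
        ("GA", "AG", "GC/GA-AG", "NCI"),
        ("TT", "CA", "other", "NCI"),
        ("AT", "AC", "other", "NCI"),
    ])
    def test_site_categories(self, donor, acceptor, cat, klass):
        i = intron_on(donor + "A" * 60 + acceptor)
        assert classify_splice_sites(i) == cat
        assert i.klass == klass

    def test_class_partition_exhaustive(self, catalog_a):
        n_can = sum(1 for i in catalog_a if i.klass == "canonical")
        n_nci = sum(1 for i in catalog_a if i.klass == "NCI")
        assert n_can + n_nci == len(catalog_a)


class TestFrequencies:
    def test_pure_gt_ag_catalog_fills_single_cell(self):
        introns = [intron_on("GT" + "ACGT" * 15 + "AG") for _ in range(10)]
        table, _ = splice_site_frequency(introns)
        assert table.loc["GT", "AG"] == 10
        assert table.values.sum() == 10

    def test_uniform_random_dinucleotides_respect_binomial_bound(self):
        rng = np.random.default_rng(2)
        introns = []
        for _ in range(2000):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            introns.append(intron_on(seq))
        table, _ = splice_site_frequency(introns)
        # 99% binomial bound around n/256, Bonferroni over 256 cells
        bound = binom.ppf(1 - 0.01 / 256, 2000, 1 / 256)
        assert table.values.max() <= bound

    def test_matrix_columns_and_scaffold_edge_padding(self):
        genome = [make_scaffold("s", "GT" + "A" * 56 + "AG")]  # intron = whole scaffold
        introns = [Intron("s", 1, 60, "+", genome[0].sequence, 5)]
        _, mats = splice_site_frequency(introns, genome)
        five = mats["five_prime"]
        assert list(five.columns[:5]) == ["E-5", "E-4", "E-3", "E-2", "E-1"]
        # no flanking sequence exists: exonic columns have no counts
        assert five[["E-5", "E-4", "E-3", "E-2", "E-1"]].to_numpy().sum() == 0
        assert five["I1"]["G"] == 1.0

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            splice_site_frequency([])


class TestGeneTyping:
    def mk(self, klasses):
        introns = []
        for k, klass in enumerate(klasses):
            seq = ("GT" + "A" * 60 + "AG") if klass == "canonical" else ("TT" + "A" * 60 + "CA")
            introns.append(Intron("s", 100 * (k + 1), 100 * (k + 1) + 63, "+", seq, 5,
                                  host_gene="g1"))
        return introns

    @pytest.mark.parametrize("klasses,label", [
        (["canonical", "canonical"], "canonical-only"),
        (["NCI", "NCI"], "NCI-only"),
        (["canonical", "NCI"], "heterogeneous"),
        ([], "intronless"),
    ])
    def test_labels(self, klasses, label):
        gene = GeneModel("g1", "s", "+", [(50, 1000)])
        assert gene_intron_typing([gene], self.mk(klasses))["g1"] == label

    def test_hostless_introns_do_not_contribute(self):
        gene = GeneModel("g1", "s", "+", [(50, 1000)])
        introns = self.mk(["canonical"])
        orphan = Intron("s", 2000, 2063, "+", "TT" + "A" * 60 + "CA", 5, host_gene=None)
        assert gene_intron_typing([gene], introns + [orphan])["g1"] == "canonical-only"


def test_recovered_gt_ag_fraction_matches_config(default_truth, catalog_a):
    frac = default_truth.config.class_fractions[0]
    n = len(catalog_a)
    observed = sum(1 for i in catalog_a if i.site_cat == "GT-AG") / n
    sd = math.sqrt(frac * (1 - frac) / n)
    assert abs(observed - frac) <= 3 * sd
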