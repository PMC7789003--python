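"""Alignment scores vs an independent DP oracle, best-reciprocal-hit
orthology, synteny chaining, and identity distributions."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from oracles import gotoh_global, gotoh_local

from introner.align import AlignmentHit, global_align, local_align, local_score
from introner.io import GeneModel
from introner.orthology import (OrthologPair, best_reciprocal_hits,
                                filter_hits, identity_distribution,
                                synteny_blocks)

AA = list("ACDEFGHIKLMNPQRSTVWY")
_B62 = substitution_matrices.load("BLOSUM62")


def blosum(x, y):
    if x == "X" or y == "X":
        return 0.0
    return float(_B62[x, y])


class TestAlignmentOracle:
    def test_wwww_scores_44(self):
        assert local_align("WWWW", "WWWW").score == 44.0

    def test_mkvl_scores_18(self):
        assert local_align("MKVL", "MKVL").score == 18.0

    def test_dissimilar_single_letters_floor_at_zero(self):
        hit = local_align("W", "P")  # W/P = -4 in BLOSUM62
        assert hit.score == 0.0 and hit.length == 0

    def test_empty_vs_nonempty_global_is_all_gaps(self):
        row_a, row_b, score = global_align("", "MKVL")
        assert row_a == "----" and row_b == "MKVL"

    def test_internal_deletion_makes_single_gap_run(self):
        a = "MKVLWQERTYIPASDF"
        b = a[:8] + a[11:]  # 3-residue internal deletion
        row_a, row_b, _ = global_align(a, b)
        assert row_a == a
        assert row_b.count("-") == 3 and "---" in row_b

    def test_local_and_global_match_dp_oracle_on_200_random_pairs(self):
        rng = np.random.default_rng(606)
        for _ in range(200):
            a = "".join(rng.choice(AA, size=int(rng.integers(5, 61))))
            b = "".join(rng.choice(AA, size=int(rng.integers(5, 61))))
            assert local_score(a, b) == pytest.approx(gotoh_local(a, b, blosum))
            got_global = global_align(a, b)[2]
            assert got_global == pytest.approx(gotoh_global(a, b, blosum))

    def test_x_scores_zero_against_anything(self):
        assert local_score("XXXX", "WWWW") == 0.0
        assert global_align("WXW", "WWW")[2] == pytest.approx(11 + 0 + 11)


class TestFilterHits:
    def mk(self, score):
        return AlignmentHit("a", "b", score, 0.0, 0)

    def test_strictly_greater_than_threshold(self):
        assert filter_hits([self.mk(300)]) == []
        assert len(filter_hits([self.mk(301)])) == 1
        assert filter_hits([]) == []


class TestBRH:
    def hit(self, q, s, score):
        return AlignmentHit(q, s, score, 0.0, 0)

    def test_mutual_best_is_pair(self):
        ab = [self.hit("a1", "b1", 500), self.hit("a1", "b2", 400)]
        ba = [self.hit("b1", "a1", 500), self.hit("b2", "a1", 400)]
        (p,) = best_reciprocal_hits(ab, ba)
        assert (p.gene_a, p.gene_b) == ("a1", "b1")

    def test_non_reciprocal_best_is_no_pair(self):
        ab = [self.hit("a1", "b1", 500)]
        ba = [self.hit("b1", "a2", 600), self.hit("b1", "a1", 500)]
        assert best_reciprocal_hits(ab, ba) == []

    def test_score_tie_broken_lexicographically_then_reciprocity(self):
        ab = [self.hit("a1", "b2", 500), self.hit("a1", "b1", 500)]
        ba = [self.hit("b1", "a1", 500), self.hit("b2", "a1", 500)]
        (p,) = best_reciprocal_hits(ab, ba)
        assert p.gene_b == "b1"

    def test_symmetric_under_genome_swap(self):
        rng = np.random.default_rng(77)
        ab, ba = [], []
        for i in range(8):
            for j in range(8):
                s = float(rng.integers(301, 900))
                ab.append(self.hit(f"a{i}", f"b{j}", s))
                ba.append(self.hit(f"b{j}", f"a{i}", s))
        fwd = {(p.gene_a, p.gene_b) for p in best_reciprocal_hits(ab, ba)}
        rev = {(p.gene_b, p.gene_a) for p in best_reciprocal_hits(ba, ab)}
        assert fwd == rev


def ranked_genes(n, prefix, scaffold):
    out = []
    for i in range(n):
        g = GeneModel(f"{prefix}{i:03d}", scaffold, "+", [(100 * i + 1, 100 * i + 50)])
        g.rank = i
        out.append(g)
    return out


def pairs_for(mapping, identity=0.5):
    return [OrthologPair(a, b, 400.0, identity) for a, b in mapping]


class TestSynteny:
    def test_identity_mapping_single_ascending_block(self):
        ga = ranked_genes(20, "a", "sa")
        gb = ranked_genes(20, "b", "sb")
        mapping = [(f"a{i:03d}", f"b{i:03d}") for i in range(20)]
        blocks, dot, metrics = synteny_blocks(pairs_for(mapping), ga, gb)
        assert len(blocks) == 1 and blocks[0].direction == "ascending"
        assert blocks[0].n_anchors == 20
        assert metrics["frac_genes_in_blocks"] == 1.0

    def test_reversed_mapping_single_descending_block(self):
        ga = ranked_genes(20, "a", "sa")
        gb = ranked_genes(20, "b", "sb")
        mapping = [(f"a{i:03d}", f"b{19 - i:03d}") for i in range(20)]
        blocks, _, _ = synteny_blocks(pairs_for(mapping), ga, gb)
        assert len(blocks) == 1 and blocks[0].direction == "descending"

    def test_rank_gap_sixteen_splits_chain(self):
        ga = ranked_genes(30, "a", "sa")
        gb = ranked_genes(30, "b", "sb")
        mapping = [(f"a{i:03d}", f"b{i:03d}") for i in range(7)] + \
                  [(f"a{i:03d}", f"b{i:03d}") for i in range(23, 30)]
        blocks, _, _ = synteny_blocks(pairs_for(mapping), ga, gb)
        assert len(blocks) == 2 and all(b.n_anchors == 7 for b in blocks)

    def test_random_permutation_rarely_forms_blocks(self):
        rng = np.random.default_rng(909)
        ga = ranked_genes(200, "a", "sa")
        gb = ranked_genes(200, "b", "sb")
        with_blocks = 0
        for _ in range(100):
            perm = rng.permutation(200)
            mapping = [(f"a{i:03d}", f"b{perm[i]:03d}") for i in range(200)]
            blocks, _, _ = synteny_blocks(pairs_for(mapping), ga, gb)
            if blocks:
                with_blocks += 1
        assert with_blocks <= 5

    def test_direction_fixed_at_second_anchor(self):
        ga = ranked_genes(12, "a", "sa")
        gb = ranked_genes(12, "b", "sb")
        # ascending run of 6 then a descending step breaks the chain
        order = [0, 1, 2, 3, 4, 5, 4 - 1]
        mapping = [(f"a{i:03d}", f"b{order[i]:03d}") for i in range(len(order))]
        blocks, _, _ = synteny_blocks(pairs_for(mapping), ga, gb)
        assert len(blocks) == 1 and blocks[0].n_anchors == 6


class TestIdentityDistribution:
    def test_identical_proteomes_median_one(self):
        summary, _ = identity_distribution(pairs_for([("a", "b")] * 3, identity=1.0))
        assert summary["median"] == 1.0

    def test_single_pair_median_is_its_identity(self):
        summary, _ = identity_distribution(pairs_for([("a", "b")], identity=0.42))
        assert summary["median"] == pytest.approx(0.42)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            identity_distribution([])


def test_synthetic_divergence_median_identity(default_truth, emitted):
    """BRH identity on the synthetic pair recovers the simulated divergence."""
    from introner.orthology import all_vs_all_hits

    prot_a = {k: v for k, v in default_truth.proteins["A"].items() if not k.endswith("d")}
    prot_b = {k: v for k, v in default_truth.proteins["B"].items() if not k.endswith("d")}
    keep = sorted(prot_a)[:60]  # subset keeps the all-vs-all scan fast
    keep_b = [k.replace("A_", "B_") for k in keep]
    ab, ba = all_vs_all_hits({k: prot_a[k] for k in keep},
                             {k: prot_b[k] for k in keep_b})
    pairs = best_reciprocal_hits(ab, ba, prot_a, prot_b)
    assert len(pairs) >= 50
    correct = sum(1 for p in pairs if p.gene_b == p.gene_a.replace("A_", "B_"))
    assert correct / len(pairs) >= 0.95
    summary, _ = identity_distribution(pairs)
    assert abs(summary["median"] - default_truth.config.target_protein_identity) <= 0.05
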