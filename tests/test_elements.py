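"""Introner-element detection: IR/DR oracle equivalence, IE calling,
family clustering, profiles and scanning, superfamilies, identical pairs."""

import numpy as np
import pytest

from oracles import brute_force_drs, brute_force_irs, gotoh_global

from introner._utils import revcomp
from introner.elements import (DRMotif, IRMotif, build_family_profile,
                               call_introners, catalog_background,
                               cluster_families, cluster_superfamilies,
                               find_direct_repeats, find_identical_ie_pairs,
                               find_inverted_repeats, hairpin_stem,
                               ie_pairwise_identity, IntronerElement,
                               scan_for_family_members, SINGLETON)
from introner.introns import Intron


def mk_intron(seq, key=0):
    return Intron("s", 1000 * key + 1, 1000 * key + len(seq), "+", seq, 5)


def mk_ie(seq, key=0):
    intron = mk_intron(seq, key)
    ir = find_inverted_repeats(seq)[0]
    return IntronerElement(intron, ir)


class TestInvertedRepeats:
    def test_planted_eight_mer_arms(self):
        seq = "TTAAGCGG" + "ACGTACGTACGTA" + "CCGCTTAA"
        (motif,) = find_inverted_repeats(seq)
        assert (motif.arm_len, motif.arm5_seq, motif.arm3_seq) == (8, "TTAAGCGG", "CCGCTTAA")

    def test_poly_a_has_no_ir(self):
        assert find_inverted_repeats("A" * 60) == []

    def test_primary_ir_is_longest(self):
        arm10 = "TTAAGCGGCA"
        seq = arm10 + "T" * 20 + revcomp(arm10)
        motifs = find_inverted_repeats(seq)
        assert motifs[0].arm_len == 10
        # its length-8/9 sub-arms at the same offsets are not reported
        assert all(m.arm_len == 10 or (m.arm5_offset, m.arm3_offset_from_end) != (0, 0)
                   for m in motifs)

    def test_equals_brute_force_on_500_random_introns(self):
        rng = np.random.default_rng(101)
        for _ in range(500):
            n = int(rng.integers(30, 301))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            if rng.random() < 0.3:  # plant an IR to exercise positives
                arm = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 21))))
                seq = arm + seq + revcomp(arm)
            got = {(m.arm5_offset, m.arm3_offset_from_end, m.arm_len)
                   for m in find_inverted_repeats(seq)}
            assert got == brute_force_irs(seq), seq

    def test_n_never_matches(self):
        seq = "TTANGCGG" + "T" * 20 + revcomp("TTANGCGG")
        assert all(("N" not in m.arm5_seq) for m in find_inverted_repeats(seq))


class TestDirectRepeats:
    def test_planted_common_substring(self):
        # exon windows share CGTTAG (maximal common substring, length 6)
        drs = find_direct_repeats("ACGTTAGC", "C" * 25 + "G" * 25, "TCGTTAGA")
        assert any(d.seq == "CGTTAG" and d.length == 6 for d in drs)

    def test_no_common_three_mer(self):
        # w5 = A8+C8 and w3 = G8+T8 share no 3-mer at all
        drs = find_direct_repeats("AAAAAAAA", "C" * 8 + "A" * 30 + "G" * 8, "TTTTTTTT")
        assert drs == []

    def test_long_commonality_reported_as_capped_substrings(self):
        common = "ACGTAACCG"  # length 9 > cap 8
        drs = find_direct_repeats("X" in "" or common[:8].rjust(8, "T") + "", "G" * 50, "")
        # build explicitly: 9-mer split across the exon boundary windows
        e5 = "ACGTAACCG"  # last 8 used: CGTAACCG
        e3 = "ACGTAACCG"
        drs = find_direct_repeats(e5, "T" * 50, e3)
        lengths = {d.length for d in drs}
        assert 8 in lengths and 9 not in lengths

    def test_equals_brute_force_on_random_windows(self):
        rng = np.random.default_rng(202)
        for _ in range(500):
            e5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 9))))
            e3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 9))))
            intron = "".join(rng.choice(list("ACGT"), size=int(rng.integers(16, 80))))
            got = {(d.offset5, d.offset3, d.length, d.seq)
                   for d in find_direct_repeats(e5, intron, e3)}
            assert got == brute_force_drs(e5, intron, e3), (e5, intron, e3)


class TestIECalling:
    def setup_method(self):
        arm = "TTAAGCGGCA"
        self.ie_seq = arm + "ACCGTTACGGTTAACCGTAGGCAT" + revcomp(arm)
        self.nci_plain = "TT" + "ACCA" * 15 + "CA"
        self.canonical_ie = "GT" + self.ie_seq + "AG"

    def test_nci_with_ir_is_candidate_without_requiring_dr(self):
        introns = [mk_intron(self.ie_seq, 0)]
        irs = {introns[0].intron_id: find_inverted_repeats(self.ie_seq)}
        cands, flagged, counts = call_introners(introns, irs)
        assert len(cands) == 1 and not flagged

    def test_nci_without_ir_is_not_ie(self):
        introns = [mk_intron(self.nci_plain, 0)]
        cands, _, _ = call_introners(introns, {introns[0].intron_id: []})
        assert cands == []

    def test_canonical_with_ir_flagged_separately(self):
        introns = [mk_intron(self.canonical_ie, 0)]
        irs = {introns[0].intron_id: find_inverted_repeats(self.canonical_ie)}
        cands, flagged, counts = call_introners(introns, irs)
        assert cands == [] and len(flagged) == 1
        assert counts["canonical_with_IR"] == 1


class TestFamilies:
    def _pair(self, loop_a, loop_b):
        arm = "TTAAGCGGCA"
        a = mk_ie(arm + loop_a + revcomp(arm), 1)
        b = mk_ie(arm + loop_b + revcomp(arm), 2)
        return a, b

    def test_identical_arms_high_identity_same_family(self):
        a, b = self._pair("ACCGTTACGGTTAACCGTAGGCAT", "ACCGTTACGGTTAACCGTTGGCAT")
        fams, singles = cluster_families([a, b])
        assert len(fams) == 1 and singles == []
        assert a.family_id == b.family_id != SINGLETON

    def test_identical_arms_low_identity_split_to_singletons(self):
        a, b = self._pair("ACCGGCAT" * 12, "TTTTATAA" * 3)
        ident, _ = ie_pairwise_identity(a, b)
        assert ident < 0.30
        fams, singles = cluster_families([a, b])
        assert fams == [] and len(singles) == 2
        assert a.family_id == SINGLETON

    def test_unique_arms_singleton(self):
        a = mk_ie("TTAAGCGGCA" + "ACCGT" * 6 + revcomp("TTAAGCGGCA"), 1)
        fams, singles = cluster_families([a])
        assert fams == [] and singles == [a]

    def test_membership_invariant_to_input_order(self):
        arm = "TTAAGCGGCA"
        ies = [mk_ie(arm + "ACCGTTACGG" * 3 + "T" * k + revcomp(arm), k) for k in range(6)]
        f1, _ = cluster_families(list(ies))
        f2, _ = cluster_families(list(reversed(ies)))
        as_sets = lambda fams: {frozenset(ie.ie_id for ie in f.members) for f in fams}
        assert as_sets(f1) == as_sets(f2)


class TestProfiles:
    def _family(self, n=6, seed=5):
        rng = np.random.default_rng(seed)
        arm = "TTAAGCGGCA"
        ies = []
        for k in range(n):
            # loop ends fixed so the detected arms never extend into the loop
            loop = "ACCGTTACGGTTAACCGTAGGC" + "".join(rng.choice(list("ACGT"), size=4)) + "AG"
            ies.append(mk_ie(arm + loop + revcomp(arm), k))
        fams, _ = cluster_families(ies)
        assert len(fams) == 1
        return fams[0], ies

    def test_identical_members_score_maximum_and_pass_tau(self):
        arm = "TTAAGCGGCA"
        seq = arm + "ACCGTTACGGTTAACCGTAGGCAT" + revcomp(arm)
        ies = [mk_ie(seq, k) for k in range(4)]
        fams, _ = cluster_families(ies)
        profile = build_family_profile(fams[0], np.full(4, 0.25))
        scores = {profile.score5(ie.intron.seq) for ie in fams[0].members}
        assert len(scores) == 1
        assert min(scores) >= profile.tau5

    def test_all_members_pass_tau_by_construction(self):
        fam, ies = self._family()
        profile = build_family_profile(fam, np.full(4, 0.25))
        for ie in fam.members:
            assert profile.score5(ie.intron.seq) >= profile.tau5
            assert profile.score3(ie.intron.seq) >= profile.tau3

    def test_dinucleotide_shuffled_decoys_rejected(self):
        fam, ies = self._family(n=8, seed=6)
        profile = build_family_profile(fam, np.full(4, 0.25))
        rng = np.random.default_rng(7)
        template = list(ies[0].intron.seq)
        rejected = 0
        for _ in range(1000):
            # dinucleotide shuffle: permute the sequence in 2-nt chunks
            chunks = ["".join(template[i:i + 2]) for i in range(0, len(template), 2)]
            rng.shuffle(chunks)
            decoy = "".join(chunks)
            if profile.score5(decoy) < profile.tau5 or profile.score3(decoy) < profile.tau3:
                rejected += 1
        assert rejected >= 990

    def test_scan_recovers_all_planted_members(self):
        fam, ies = self._family(n=10, seed=8)
        build_family_profile(fam, np.full(4, 0.25))
        hits = scan_for_family_members([fam], [ie.intron for ie in ies])
        assert set(hits) == {ie.ie_id for ie in ies}

    def test_scan_requires_both_windows(self):
        fam, ies = self._family(n=6, seed=9)
        profile = build_family_profile(fam, np.full(4, 0.25))
        good = ies[0].intron.seq
        # destroy only the 3' window
        broken = good[:-14] + "GGGGGGGGGGGGGG"
        probe = mk_intron(broken, 99)
        assert profile.score5(broken) >= profile.tau5
        assert scan_for_family_members([fam], [probe]) == {}


class TestSuperfamilies:
    def _template_ies(self, head, n, seed, key0):
        """IEs from one arm-motif template: n distinct arms, 2 members each."""
        rng = np.random.default_rng(seed)
        ies = []
        for k in range(n):
            arm = head + "".join(rng.choice(list("ACG"), size=3)) + "G"
            for j in range(2):
                loop = "ACCGTTACGGTTAACCG" + "".join(rng.choice(list("ACG"), size=3)) + "AG"
                ies.append(mk_ie(arm + loop + revcomp(arm), key0 + 2 * k + j))
        return ies

    def _two_template_families(self):
        ies = (self._template_ies("TTAAGGTA", 3, seed=1, key0=0)
               + self._template_ies("CGCCTACC", 3, seed=2, key0=50))
        fams, _ = cluster_families(ies)
        assert len(fams) == 6
        return fams

    def test_two_templates_separate_at_k2(self):
        fams = self._two_template_families()
        assignment, newick = cluster_superfamilies(fams, k=2)
        labels = {}
        for f in fams:
            head = f.ir_key[0][:8]
            labels.setdefault(head, set()).add(assignment[f.family_id])
        (la, lb) = labels.values()
        assert len(la) == 1 and len(lb) == 1 and la != lb
        assert newick.count("(") >= 1

    def test_zero_distance_families_share_superfamily(self):
        fams = self._two_template_families()
        assignment, _ = cluster_superfamilies(fams, k=2)
        # two families with identical arm consensus composition
        same = [f for f in fams if f.ir_key[0].startswith("TTAAGGTA")]
        assert len({assignment[f.family_id] for f in same}) == 1

    def test_k1_groups_everything(self):
        fams = self._two_template_families()
        assignment, _ = cluster_superfamilies(fams, k=1)
        assert len(set(assignment.values())) == 1

    def test_k_exceeding_family_count_rejected(self):
        fams = self._two_template_families()
        with pytest.raises(ValueError):
            cluster_superfamilies(fams, k=7)


class TestIdenticalPairs:
    def test_pair_counts_follow_binomial_coefficient(self):
        arm = "TTAAGCGGCA"
        seq = arm + "ACCGTTACGGTTAACCGTAGGCAT" + revcomp(arm)
        other = arm + "ACCGTTACGGTTAACCGTAGGCAA" + revcomp(arm)
        two = [mk_ie(seq, k) for k in range(2)]
        assert len(find_identical_ie_pairs(two)) == 1
        three = [mk_ie(seq, k) for k in range(3)]
        assert len(find_identical_ie_pairs(three)) == 3
        assert len(find_identical_ie_pairs([mk_ie(seq, 0), mk_ie(other, 1)])) == 0


class TestHairpin:
    def test_perfect_stem_and_loop(self):
        arm = "TTAAGCGG"
        seq = arm + "AAAAAAAAAAAAG" + revcomp(arm)  # 13-nt spacer, ends A/G unpaired
        (ir,) = find_inverted_repeats(seq)
        stem, loop = hairpin_stem(ir, seq)
        assert (stem, loop) == (8, 13)

    def test_gu_wobble_extends_stem(self):
        arm = "TTAAGCGG"
        # inward bases G...T pair only under G.U wobble
        seq = arm + "G" + "AAAAAAAAAAA" + "T" + revcomp(arm)
        (ir,) = find_inverted_repeats(seq)
        stem_wc, _ = hairpin_stem(ir, seq, allow_GU=False)
        stem_gu, _ = hairpin_stem(ir, seq, allow_GU=True)
        assert stem_wc == 8 and stem_gu == 9


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        seq = "TTAAGCGGCA" * 4
        ident, length = ie_pairwise_identity(seq, seq)
        assert ident == 1.0 and length == len(seq)

    def test_single_substitution_over_100(self):
        a = ("ACGT" * 25)
        b = a[:50] + ("C" if a[50] != "C" else "G") + a[51:]
        ident, length = ie_pairwise_identity(a, b)
        assert length == 100 and ident == pytest.approx(0.99)

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(303)
        sub = lambda x, y: 5 if x == y else -4
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 80))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 80))))
            from introner.align import dna_aligner
            assert dna_aligner("global").score(a, b) == pytest.approx(gotoh_global(a, b, sub))
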