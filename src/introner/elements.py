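"""Introner-element (IE) detection and family analysis.

An IE is a non-canonical intron carrying an inverted-repeat (IR) arm pair
near both splice sites: the 3' arm is the exact reverse complement of the
5' arm, with each arm anchored within a few nucleotides of its intron end.
The hairpin the IR can fold into is the structural hallmark; direct repeats
(DRs) overlapping the exon/intron boundaries are recorded as an attribute
but are not required for the IE call.  Families group IEs with byte-equal
arm pairs whose full intronic sequences align at >= 30% global identity;
position-specific log-odds profiles over the arm windows then recover
additional family members ("repeated introns") from the whole catalog.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from skbio.tree import TreeNode

from ._utils import revcomp
from .align import global_identity
from .introns import BASES, Intron

logger = logging.getLogger(__name__)

SINGLETON = "SINGLETON"


@dataclass(frozen=True)
class IRMotif:
    """An inverted-repeat arm pair inside one intron.

    ``arm5_offset`` is the 0-based offset of the 5' arm start from the intron
    start; ``arm3_offset_from_end`` the 0-based offset of the 3' arm end from
    the intron end.  ``arm3_seq`` is always the reverse complement of
    ``arm5_seq``.
    """

    arm5_offset: int
    arm3_offset_from_end: int
    arm_len: int
    arm5_seq: str
    arm3_seq: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.arm5_seq, self.arm3_seq)


@dataclass(frozen=True)
class DRMotif:
    """A direct repeat found in both exon/intron boundary windows.

    Offsets are signed positions of the repeat start relative to the first
    intronic base (5' boundary) and to the first exonic base after the
    intron (3' boundary): negative = exonic at 5', intronic at 3'.
    """

    length: int
    seq: str
    offset5: int
    offset3: int


@dataclass
class IntronerElement:
    intron: Intron
    ir: IRMotif
    drs: list[DRMotif] = field(default_factory=list)
    family_id: str = SINGLETON

    @property
    def ie_id(self) -> str:
        return self.intron.intron_id


@dataclass
class FamilyProfile:
    """Position-specific log-odds windows over the 5' and 3' intron ends.

    Scores are log2 odds against the 0-order base composition of the whole
    intron catalog; tau thresholds are 0.8 x the minimum member self-score
    per window, and candidate members must fall inside the family's
    empirical length range.
    """

    w5: np.ndarray  # 4 x len5 log-odds
    w3: np.ndarray
    tau5: float
    tau3: float
    min_len: int
    max_len: int

    def score5(self, seq: str) -> float:
        return _score_window(self.w5, seq[: self.w5.shape[1]])

    def score3(self, seq: str) -> float:
        return _score_window(self.w3, seq[-self.w3.shape[1] :].rjust(self.w3.shape[1], "N"))


@dataclass
class IEFamily:
    family_id: str
    members: list[IntronerElement]
    ir_key: tuple[str, str]
    profile: FamilyProfile | None = None
    superfamily_id: str | None = None


# ---------------------------------------------------------------------------
# IR / DR detection
# ---------------------------------------------------------------------------

def find_inverted_repeats(
    intron_seq: str,
    min_len: int = 8,
    max_len: int = 20,
    end_window: int = 6,
    min_loop: int = 3,
) -> list[IRMotif]:
    """All maximal IR arm pairs anchored near the two intron ends.

    For every (arm5_offset, arm3_offset_from_end) pair with both offsets in
    [0, end_window), the longest arm length L in [min_len, max_len] is
    reported for which the 3' arm equals the reverse complement of the 5'
    arm and the unpaired loop between the arms is >= min_loop.  Sorted by
    (arm_len desc, arm5_offset asc, arm3_offset_from_end asc); the first
    element is the primary IR.  N never matches.
    """
    n = len(intron_seq)
    out = []
    for o5 in range(end_window):
        for o3 in range(end_window):
            best = 0
            for L in range(min_len, max_len + 1):
                if o5 + L + min_loop + L + o3 > n:
                    break
                arm5 = intron_seq[o5 : o5 + L]
                arm3 = intron_seq[n - o3 - L : n - o3]
                if "N" in arm5 or "N" in arm3:
                    break
                if arm3 != revcomp(arm5):
                    break
                best = L
            if best >= min_len:
                arm5 = intron_seq[o5 : o5 + best]
                out.append(IRMotif(o5, o3, best, arm5, revcomp(arm5)))
    out.sort(key=lambda m: (-m.arm_len, m.arm5_offset, m.arm3_offset_from_end))
    return out


def find_direct_repeats(
    exon5_flank: str,
    intron_seq: str,
    exon3_flank: str,
    min_len: int = 3,
    max_len: int = 8,
    boundary_window: int = 8,
) -> list[DRMotif]:
    """Common substrings of the two exon/intron boundary windows.

    The 5' window is the last ``boundary_window`` exonic + first
    ``boundary_window`` intronic nucleotides; the 3' window the last
    ``boundary_window`` intronic + first ``boundary_window`` exonic.  Flanks
    shorter than the window are N-padded (N never matches).  A match is
    reported when it is maximal (not extendable on either side within the
    windows) or when it is a length-``max_len`` substring of a longer
    commonality.  Sorted longest first, then by offsets.
    """
    bw = boundary_window
    e5 = exon5_flank[-bw:].rjust(bw, "N")
    e3 = exon3_flank[:bw].ljust(bw, "N")
    i5 = intron_seq[:bw].ljust(bw, "N")
    i3 = intron_seq[-bw:].rjust(bw, "N")
    w5 = e5 + i5  # index bw = first intronic base
    w3 = i3 + e3  # index bw = first exonic base after the intron

    def valid(p5: int, p3: int, L: int) -> bool:
        if p5 < 0 or p3 < 0 or p5 + L > len(w5) or p3 + L > len(w3):
            return False
        s = w5[p5 : p5 + L]
        return "N" not in s and s == w3[p3 : p3 + L]

    out = []
    for L in range(min_len, max_len + 1):
        for p5 in range(len(w5) - L + 1):
            for p3 in range(len(w3) - L + 1):
                if not valid(p5, p3, L):
                    continue
                extendable = valid(p5, p3, L + 1) or valid(p5 - 1, p3 - 1, L + 1)
                if extendable and L < max_len:
                    continue
                out.append(DRMotif(L, w5[p5 : p5 + L], p5 - bw, p3 - bw))
    out.sort(key=lambda d: (-d.length, d.offset5, d.offset3))
    return out


# ---------------------------------------------------------------------------
# IE calling and family clustering
# ---------------------------------------------------------------------------

def call_introners(
    introns: list[Intron],
    irs: dict[str, list[IRMotif]],
    drs: dict[str, list[DRMotif]] | None = None,
) -> tuple[list[IntronerElement], list[Intron], dict[str, int]]:
    """Call IE candidates and flag canonical introns with IE-like structure.

    A non-canonical intron with at least one IR becomes an IE candidate
    (DRs recorded when supplied, never required).  Canonical GT-AG introns
    with an IR are flagged separately — they share the structural
    organization but are not counted as IEs.  Returns (candidates,
    canonical_flagged, per-class counts).
    """
    drs = drs or {}
    candidates, flagged = [], []
    counts = Counter()
    for intr in introns:
        motifs = irs.get(intr.intron_id, [])
        if not motifs:
            counts[f"{intr.klass}_no_IR"] += 1
            continue
        if intr.klass == "NCI":
            candidates.append(IntronerElement(intr, motifs[0], drs.get(intr.intron_id, [])))
            counts["NCI_with_IR"] += 1
        else:
            flagged.append(intr)
            counts["canonical_with_IR"] += 1
    logger.info("IE calling: %s", dict(counts))
    return candidates, flagged, dict(counts)


def cluster_families(
    ie_candidates: list[IntronerElement],
    min_intron_identity: float = 0.30,
) -> tuple[list[IEFamily], list[IntronerElement]]:
    """Two-stage deterministic family clustering.

    Stage 1 groups candidates by exact primary-IR arm-pair key.  Stage 2,
    within each group, clusters greedily: candidates sorted by intron length
    descending (ties by id) join the first cluster whose founding
    representative they match at >= ``min_intron_identity`` global DNA
    identity, else found a new cluster.  Clusters of size 1 become
    singletons.  Family ids are assigned in (arm key, founder id) order,
    making membership invariant to input order.
    """
    groups: dict[tuple[str, str], list[IntronerElement]] = {}
    for ie in ie_candidates:
        groups.setdefault(ie.ir.key, []).append(ie)

    families: list[IEFamily] = []
    singletons: list[IntronerElement] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda e: (-e.intron.length, e.ie_id))
        clusters: list[list[IntronerElement]] = []
        for ie in members:
            for cluster in clusters:
                rep = cluster[0]
                ident, _ = global_identity(ie.intron.seq, rep.intron.seq, dna=True)
                if ident >= min_intron_identity:
                    cluster.append(ie)
                    break
            else:
                clusters.append([ie])
        for cluster in clusters:
            if len(cluster) >= 2:
                families.append(IEFamily("", cluster, key))
            else:
                singletons.extend(cluster)
    families.sort(key=lambda f: (f.ir_key, f.members[0].ie_id))
    for i, fam in enumerate(families):
        fam.family_id = f"IEF{i + 1:04d}"
        for ie in fam.members:
            ie.family_id = fam.family_id
    for ie in singletons:
        ie.family_id = SINGLETON
    return families, singletons


# ---------------------------------------------------------------------------
# Family profiles and scanning
# ---------------------------------------------------------------------------

def _log_odds(counts: np.ndarray, background: np.ndarray, pseudocount: float) -> np.ndarray:
    probs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
    return np.log2(probs / background[:, None])


def _score_window(w: np.ndarray, seq: str) -> float:
    score = 0.0
    for pos in range(min(len(seq), w.shape[1])):
        base = seq[pos]
        if base in BASES:
            score += w[BASES.index(base), pos]
    return score


def catalog_background(introns: list[Intron]) -> np.ndarray:
    """0-order base composition of the whole intron catalog."""
    counts = np.zeros(4)
    for intr in introns:
        for i, b in enumerate(BASES):
            counts[i] += intr.seq.count(b)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def build_family_profile(
    family: IEFamily,
    background: np.ndarray,
    flank: int = 5,
    pseudocount: float = 0.5,
) -> FamilyProfile:
    """Position-specific log-odds model over the family's intron-end windows.

    The 5' window spans from the intron start through the farthest member
    arm end plus ``flank``; the 3' window mirrors it from the intron end.
    tau per window = 0.8 x the minimum member self-score, so every member
    passes by construction.
    """
    members = family.members
    if len(members) < 2:
        raise ValueError("profiles require >= 2 members")
    len5 = max(ie.ir.arm5_offset + ie.ir.arm_len for ie in members) + flank
    len3 = max(ie.ir.arm3_offset_from_end + ie.ir.arm_len for ie in members) + flank

    c5, c3 = np.zeros((4, len5)), np.zeros((4, len3))
    for ie in members:
        s = ie.intron.seq
        for pos, base in enumerate(s[:len5].ljust(len5, "N")):
            if base in BASES:
                c5[BASES.index(base), pos] += 1
        for pos, base in enumerate(s[-len3:].rjust(len3, "N")):
            if base in BASES:
                c3[BASES.index(base), pos] += 1
    w5 = _log_odds(c5, background, pseudocount)
    w3 = _log_odds(c3, background, pseudocount)
    profile = FamilyProfile(w5, w3, 0.0, 0.0,
                            min(ie.intron.length for ie in members),
                            max(ie.intron.length for ie in members))
    self5 = [profile.score5(ie.intron.seq) for ie in members]
    self3 = [profile.score3(ie.intron.seq) for ie in members]
    # tau relaxes the minimum member self-score by 20% so that every member
    # passes regardless of the score's sign
    profile.tau5 = min(self5) - 0.2 * abs(min(self5))
    profile.tau3 = min(self3) - 0.2 * abs(min(self3))
    family.profile = profile
    return profile


def scan_for_family_members(
    families: list[IEFamily],
    introns: list[Intron],
) -> dict[str, str]:
    """Scan the intron catalog with the family profiles.

    An intron is a repeated-intron member of a family when it scores >= tau
    at both windows and its length lies in the family range.  Multi-family
    hits resolve to the maximum total score; ties to the lexicographically
    smallest family id (logged).  Returns intron_id -> family_id.
    """
    hits: dict[str, str] = {}
    for intr in introns:
        best: tuple[float, str] | None = None
        tied = False
        for fam in families:
            p = fam.profile
            if p is None or not (p.min_len <= intr.length <= p.max_len):
                continue
            s5, s3 = p.score5(intr.seq), p.score3(intr.seq)
            if s5 >= p.tau5 and s3 >= p.tau3:
                total = s5 + s3
                if best is None or total > best[0] or (total == best[0] and fam.family_id < best[1]):
                    tied = best is not None and total == best[0]
                    best = (total, fam.family_id)
        if best is not None:
            if tied:
                logger.info("intron %s: tied profile hit resolved to %s", intr.intron_id, best[1])
            hits[intr.intron_id] = best[1]
    return hits


# ---------------------------------------------------------------------------
# Superfamilies, identical pairs, hairpins, identity
# ---------------------------------------------------------------------------

def _kmer_vector(seq: str, k: int = 3) -> np.ndarray:
    kmers = ["".join(p) for p in itertools.product(BASES, repeat=k)]
    index = {km: i for i, km in enumerate(kmers)}
    v = np.zeros(len(kmers))
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in index:
            v[index[km]] += 1
    total = v.sum()
    return v / total if total else v


def _consensus(seqs: list[str]) -> str:
    width = max(len(s) for s in seqs)
    out = []
    for pos in range(width):
        col = Counter(s[pos] for s in seqs if pos < len(s) and s[pos] in BASES)
        out.append(col.most_common(1)[0][0] if col else "N")
    return "".join(out)


def cluster_superfamilies(families: list[IEFamily], k: int = 4) -> tuple[dict[str, str], str]:
    """Ward/Euclidean agglomerative clustering of families into superfamilies.

    Features are 3-mer frequency vectors of each family's arm consensus
    (5' arm consensus + 3' arm consensus concatenated).  Returns the
    family -> superfamily assignment and the dendrogram in Newick format.
    """
    if len(families) < 2:
        raise ValueError("superfamily clustering requires >= 2 families")
    if k > len(families):
        raise ValueError(f"k={k} exceeds number of families ({len(families)})")
    ids = [f.family_id for f in families]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate family ids (families must come from one clustering run)")
    vectors = []
    for fam in families:
        arm5 = _consensus([ie.ir.arm5_seq for ie in fam.members])
        arm3 = _consensus([ie.ir.arm3_seq for ie in fam.members])
        vectors.append(np.concatenate([_kmer_vector(arm5), _kmer_vector(arm3)]))
    X = np.vstack(vectors)
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    assignment = {}
    for fam, lab in zip(families, labels):
        fam.superfamily_id = f"SF{lab}"
        assignment[fam.family_id] = fam.superfamily_id
    tree = TreeNode.from_linkage_matrix(Z, [f.family_id for f in families])
    return assignment, str(tree)


def find_identical_ie_pairs(ies: list[IntronerElement]) -> list[tuple[str, str]]:
    """All unordered pairs of distinct IE loci with byte-identical sense
    sequences (a group of m identical loci yields C(m,2) pairs)."""
    by_seq: dict[str, list[str]] = {}
    for ie in ies:
        by_seq.setdefault(ie.intron.seq, []).append(ie.ie_id)
    pairs = []
    for ids in by_seq.values():
        ids = sorted(ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.append((ids[i], ids[j]))
    return sorted(pairs)


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def hairpin_stem(ir: IRMotif, intron_seq: str, allow_GU: bool = False) -> tuple[int, int]:
    """Stem/loop descriptor of the hairpin implied by an IR.

    Returns (paired stem length, unpaired loop length).  The IR arms pair by
    construction; with ``allow_GU`` the stem is extended inward while the
    next base pair is Watson-Crick or G.U.
    """
    n = len(intron_seq)
    stem = ir.arm_len
    i = ir.arm5_offset + ir.arm_len  # next base inward on the 5' side
    j = n - ir.arm3_offset_from_end - ir.arm_len - 1  # next inward on the 3' side
    pairs = _WC | _GU if allow_GU else _WC
    while j - i + 1 > 2 and (intron_seq[i], intron_seq[j]) in pairs:
        stem += 1
        i += 1
        j -= 1
    return stem, j - i + 1


def ie_pairwise_identity(ie_a: IntronerElement | str, ie_b: IntronerElement | str) -> tuple[float, int]:
    """Global (Needle-style) identity and aligned length of two IE sequences."""
    a = ie_a if isinstance(ie_a, str) else ie_a.intron.seq
    b = ie_b if isinstance(ie_b, str) else ie_b.intron.seq
    if not a or not b:
        raise ValueError("empty IE sequence")
    return global_identity(a, b, dna=True)


def ie_table(ies: list[IntronerElement], families: list[IEFamily]) -> pd.DataFrame:
    """IE catalog as a tidy table."""
    superfamily = {f.family_id: f.superfamily_id or "" for f in families}
    rows = []
    for ie in ies:
        dr = ie.drs[0] if ie.drs else None
        rows.append(dict(
            ie_id=ie.ie_id, arm5=ie.ir.arm5_seq, arm3=ie.ir.arm3_seq,
            arm_len=ie.ir.arm_len, arm5_offset=ie.ir.arm5_offset,
            arm3_offset_from_end=ie.ir.arm3_offset_from_end,
            n_dr=len(ie.drs), dr_seq=dr.seq if dr else "",
            family=ie.family_id, superfamily=superfamily.get(ie.family_id, ""),
            length=ie.intron.length,
        ))
    return pd.DataFrame(rows)
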