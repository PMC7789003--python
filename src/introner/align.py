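"""Pairwise alignment backends shared by the orthology, tandem-duplication,
introner-identity and intron-conservation stages.

Protein alignments use BLOSUM62 with affine gaps (open 10, extend 1): the
first residue of a gap costs the open penalty, each further residue the
extension penalty.  ``X`` is treated as scoring 0 against everything.  DNA
global identity uses EDNAFULL-like scoring (match +5, mismatch -4) with the
same gap costs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class AlignmentHit:
    """A scored pairwise hit (substitution-matrix units)."""

    query_id: str
    subject_id: str
    score: float
    identity: float
    length: int


def _blosum62_x0():
    m = substitution_matrices.load("BLOSUM62")
    m = m.copy()
    alphabet = m.alphabet
    xi = alphabet.index("X")
    for j in range(len(alphabet)):
        m[xi, j] = 0.0
        m[j, xi] = 0.0
    return m


@lru_cache(maxsize=None)
def protein_aligner(mode: str = "local", gap_open: int = 10, gap_extend: int = 1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _blosum62_x0()
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner


@lru_cache(maxsize=None)
def dna_aligner(mode: str = "global", gap_open: int = 10, gap_extend: int = 1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner


def _alignment_stats(alignment) -> tuple[int, int]:
    """(matches, aligned columns incl. gap columns) of a Bio.Align.Alignment."""
    a, b = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches, len(a)


def local_align(
    protein_a: str,
    protein_b: str,
    ids: tuple[str, str] = ("a", "b"),
    gap_open: int = 10,
    gap_extend: int = 1,
) -> AlignmentHit:
    """Optimal Smith-Waterman hit under BLOSUM62 affine gaps.

    Identity is computed over the aligned local region (gap columns
    included in the denominator).  A pair with no positive-scoring region
    yields score 0 and an empty alignment.
    """
    aligner = protein_aligner("local", gap_open, gap_extend)
    score = aligner.score(protein_a, protein_b)
    if score <= 0:
        return AlignmentHit(ids[0], ids[1], 0.0, 0.0, 0)
    alignment = aligner.align(protein_a, protein_b)[0]
    matches, length = _alignment_stats(alignment)
    return AlignmentHit(ids[0], ids[1], float(score), matches / length if length else 0.0, length)


def local_score(protein_a: str, protein_b: str, gap_open: int = 10, gap_extend: int = 1) -> float:
    """Score-only Smith-Waterman (no traceback); used for all-vs-all scans."""
    return float(protein_aligner("local", gap_open, gap_extend).score(protein_a, protein_b))


def global_align(
    protein_a: str,
    protein_b: str,
    gap_open: int = 10,
    gap_extend: int = 1,
) -> tuple[str, str, float]:
    """Optimal global (Needleman-Wunsch) alignment; returns the two aligned
    rows (with '-') and the score.  End gaps are penalized like internal
    gaps."""
    if not protein_a or not protein_b:
        # degenerate: all-gap alignment against the non-empty sequence
        return ("-" * len(protein_b) or protein_a, protein_b or "-" * len(protein_a), 0.0)
    aligner = protein_aligner("global", gap_open, gap_extend)
    alignment = aligner.align(protein_a, protein_b)[0]
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


def global_identity(a: str, b: str, dna: bool = False, gap_open: int = 10, gap_extend: int = 1) -> tuple[float, int]:
    """Global alignment identity = matches / alignment length, plus length."""
    if not a or not b:
        return 0.0, max(len(a), len(b))
    aligner = (dna_aligner if dna else protein_aligner)("global", gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    matches, length = _alignment_stats(alignment)
    return matches / length if length else 0.0, length


def alignment_identity(row_a: str, row_b: str) -> float:
    """Identity over the columns of two pre-aligned rows."""
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return matches / len(row_a) if row_a else 0.0
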