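"""Best-reciprocal-hit orthology, identity distributions, and synteny-block
chaining over gene ranks, with a dot-plot table export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignmentHit, local_align, local_score
from .io import GeneModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologPair:
    """A mutual best hit between the two proteomes."""

    gene_a: str
    gene_b: str
    score: float
    identity: float


@dataclass
class SyntenyBlock:
    """A collinear chain of ortholog anchors on one scaffold pair."""

    scaffold_a: str
    scaffold_b: str
    anchors: list[OrthologPair]
    direction: str  # ascending | descending

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def all_vs_all_hits(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    min_score: float = 300,
    gap_open: int = 10,
    gap_extend: int = 1,
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Score-only Smith-Waterman all-vs-all in both directions.

    Local alignment score is symmetric, so each pair is scored once.
    Returns (hits A->B, hits B->A), already filtered at ``score > min_score``
    (strict, matching the retention rule).
    """
    ab, ba = [], []
    items_b = sorted(proteins_b.items())
    for qa, seq_a in sorted(proteins_a.items()):
        for qb, seq_b in items_b:
            s = local_score(seq_a, seq_b, gap_open, gap_extend)
            if s > min_score:
                ab.append(AlignmentHit(qa, qb, s, 0.0, 0))
                ba.append(AlignmentHit(qb, qa, s, 0.0, 0))
    return ab, ba


def filter_hits(hits: list[AlignmentHit], min_score: float = 300) -> list[AlignmentHit]:
    """Retain hits with score strictly greater than ``min_score``."""
    return [h for h in hits if h.score > min_score]


def _best_subject(hits: list[AlignmentHit]) -> dict[str, str]:
    """Top-scoring subject per query; score ties resolved to the
    lexicographically smallest subject id."""
    best: dict[str, tuple[float, str]] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or h.score > cur[0] or (h.score == cur[0] and h.subject_id < cur[1]):
            best[h.query_id] = (h.score, h.subject_id)
    return {q: s for q, (_, s) in best.items()}


def best_reciprocal_hits(
    hits_ab: list[AlignmentHit],
    hits_ba: list[AlignmentHit],
    proteins_a: dict[str, str] | None = None,
    proteins_b: dict[str, str] | None = None,
) -> list[OrthologPair]:
    """Mutual best hits between the two filtered hit lists.

    (a, b) is a pair iff b is a's top subject and a is b's top subject
    (ties broken to the smaller id before checking reciprocity).  When the
    proteomes are supplied, pair identities are computed from the full
    local alignment of each retained pair.
    """
    best_ab = _best_subject(hits_ab)
    best_ba = _best_subject(hits_ba)
    score_of = {(h.query_id, h.subject_id): h.score for h in hits_ab}
    pairs = []
    for a, b in sorted(best_ab.items()):
        if best_ba.get(b) == a:
            identity = 0.0
            if proteins_a is not None and proteins_b is not None:
                identity = local_align(proteins_a[a], proteins_b[b]).identity
            pairs.append(OrthologPair(a, b, score_of[(a, b)], identity))
    return pairs


def synteny_blocks(
    pairs: list[OrthologPair],
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    min_anchors: int = 5,
    max_gap: int = 15,
) -> tuple[list[SyntenyBlock], pd.DataFrame, dict[str, float]]:
    """Chain ortholog anchors into collinear synteny blocks.

    Per (scaffoldA, scaffoldB) pair, anchors sorted by rankA are chained
    greedily while consecutive anchors differ by <= ``max_gap`` ranks in
    both genomes and rankB stays monotone; each chain fixes ascending or
    descending direction at its second anchor.  Chains with >=
    ``min_anchors`` anchors are blocks.  Returns (blocks, dot-plot table,
    metrics).
    """
    ga = {g.gene_id: g for g in genes_a}
    gb = {g.gene_id: g for g in genes_b}
    by_pair: dict[tuple[str, str], list[OrthologPair]] = {}
    for p in pairs:
        a, b = ga[p.gene_a], gb[p.gene_b]
        by_pair.setdefault((a.scaffold_id, b.scaffold_id), []).append(p)

    blocks: list[SyntenyBlock] = []
    for (sca, scb), anchors in sorted(by_pair.items()):
        anchors = sorted(anchors, key=lambda p: ga[p.gene_a].rank)
        chain: list[OrthologPair] = []
        direction = 0  # 0 unset, +1 ascending, -1 descending

        def flush():
            nonlocal chain, direction
            if len(chain) >= min_anchors:
                blocks.append(SyntenyBlock(sca, scb, chain,
                                           "descending" if direction < 0 else "ascending"))
            chain, direction = [], 0

        for p in anchors:
            if not chain:
                chain = [p]
                continue
            prev = chain[-1]
            d_a = ga[p.gene_a].rank - ga[prev.gene_a].rank
            d_b = gb[p.gene_b].rank - gb[prev.gene_b].rank
            step = (d_b > 0) - (d_b < 0)
            ok = d_a <= max_gap and abs(d_b) <= max_gap and d_b != 0
            if ok and direction == 0:
                direction = step
            elif ok and step != direction:
                ok = False
            if ok:
                chain.append(p)
            else:
                flush()
                chain = [p]
        flush()

    rows = []
    anchored = set()
    for i, b in enumerate(blocks, 1):
        for p in b.anchors:
            anchored.add((p.gene_a, p.gene_b))
            rows.append(dict(gene_a=p.gene_a, gene_b=p.gene_b,
                             rank_a=ga[p.gene_a].rank, rank_b=gb[p.gene_b].rank,
                             scaffold_a=b.scaffold_a, scaffold_b=b.scaffold_b,
                             block_id=f"SB{i:04d}"))
    for p in pairs:
        if (p.gene_a, p.gene_b) not in anchored:
            a, b = ga[p.gene_a], gb[p.gene_b]
            rows.append(dict(gene_a=p.gene_a, gene_b=p.gene_b, rank_a=a.rank,
                             rank_b=b.rank, scaffold_a=a.scaffold_id,
                             scaffold_b=b.scaffold_id, block_id=""))
    dotplot = pd.DataFrame(rows)

    genes_in_blocks = set()
    for b in blocks:
        for p in b.anchors:
            genes_in_blocks.add(("A", p.gene_a))
            genes_in_blocks.add(("B", p.gene_b))
    metrics = dict(
        n_blocks=float(len(blocks)),
        frac_orthologs_in_blocks=(sum(b.n_anchors for b in blocks) / len(pairs)) if pairs else 0.0,
        frac_genes_in_blocks=(len(genes_in_blocks) / (len(genes_a) + len(genes_b)))
        if (genes_a or genes_b) else 0.0,
    )
    return blocks, dotplot, metrics


def identity_distribution(pairs: list[OrthologPair]) -> tuple[dict[str, float], np.ndarray]:
    """Median/quartile summary plus the raw identity values (violin-ready)."""
    if not pairs:
        raise ValueError("identity_distribution: no ortholog pairs")
    values = np.array([p.identity for p in pairs])
    summary = dict(
        n=float(len(values)),
        median=float(np.median(values)),
        q1=float(np.percentile(values, 25)),
        q3=float(np.percentile(values, 75)),
        mean=float(values.mean()),
    )
    return summary, values


def ortholog_table(pairs: list[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(gene_a=p.gene_a, gene_b=p.gene_b, score=p.score,
              identity=round(p.identity, 4)) for p in pairs]
    )
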