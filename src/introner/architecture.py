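"""Genome-architecture statistics: gene-orientation shift rate, co-oriented
gene blocks, tandem-duplication clusters, and telomere-motif scanning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import revcomp
from .align import local_align, local_score
from .io import GeneModel, GenomeSeq

logger = logging.getLogger(__name__)

TELOMERE_MOTIFS = ("TTTAGGG", "TTTGGGG")


@dataclass(frozen=True)
class OrientationBlock:
    """A run of >= 5 same-strand genes tolerating interruptions of <= 2
    contiguous opposite-strand genes; starts and ends on block-orientation
    genes."""

    scaffold_id: str
    first_rank: int
    last_rank: int
    orientation: str
    n_genes: int
    n_interruption_genes: int

    @property
    def span(self) -> int:
        return self.last_rank - self.first_rank + 1


@dataclass(frozen=True)
class TandemCluster:
    """Co-localized run of near-identical paralogs (single-linkage at
    >= 95% identity / >= 90% coverage, <= 1 intervening gene)."""

    scaffold_id: str
    gene_ids: tuple[str, ...]
    first_rank: int
    last_rank: int


def _strand_runs(genes: list[GeneModel]) -> dict[str, list[str]]:
    """Per-scaffold strand strings ordered by rank."""
    per: dict[str, list[GeneModel]] = {}
    for g in genes:
        per.setdefault(g.scaffold_id, []).append(g)
    return {sc: [g.strand for g in sorted(ms, key=lambda g: g.rank)] for sc, ms in per.items()}


def orientation_change_rate(
    genes: list[GeneModel],
    window: int = 10,
    metric: str = "transitions",
) -> tuple[dict[str, float], float]:
    """Mean gene-orientation shift per non-overlapping window of genes.

    ``metric="transitions"`` (default) counts adjacent-pair strand changes
    inside each complete window (0..window-1); ``metric="minority"`` counts
    genes in the window's minority orientation.  Scaffolds with fewer than
    ``window`` genes contribute no window.  Returns (per-scaffold means,
    genome-wide mean over all windows).
    """
    if metric not in ("transitions", "minority"):
        raise ValueError(f"unknown metric {metric!r}")
    per_scaffold: dict[str, float] = {}
    all_counts: list[int] = []
    for scaffold, strands in sorted(_strand_runs(genes).items()):
        counts = []
        for w0 in range(0, len(strands) - window + 1, window):
            win = strands[w0 : w0 + window]
            if metric == "transitions":
                counts.append(sum(1 for a, b in zip(win, win[1:]) if a != b))
            else:
                plus = win.count("+")
                counts.append(min(plus, window - plus))
        if counts:
            per_scaffold[scaffold] = float(np.mean(counts))
            all_counts.extend(counts)
    return per_scaffold, float(np.mean(all_counts)) if all_counts else 0.0


def coorient_blocks(genes: list[GeneModel]) -> tuple[list[OrientationBlock], float]:
    """Maximal co-oriented gene blocks, greedily left to right.

    A block is >= 5 genes of one orientation with every interruption run of
    opposite-strand genes <= 2, trimmed to start and end on
    block-orientation genes.  Interruption genes count as inside blocks for
    the coverage fraction.  Returns (blocks, fraction of all genes inside
    blocks).
    """
    blocks: list[OrientationBlock] = []
    n_total = 0
    n_in_blocks = 0
    for scaffold, strands in sorted(_strand_runs(genes).items()):
        n = len(strands)
        n_total += n
        i = 0
        while i < n:
            o = strands[i]
            # grow: last index of an o-gene reachable without an opposite run > 2
            j = i
            last_o = i
            opp_run = 0
            while j < n:
                if strands[j] == o:
                    last_o = j
                    opp_run = 0
                else:
                    opp_run += 1
                    if opp_run > 2:
                        break
                j += 1
            n_o = sum(1 for s in strands[i : last_o + 1] if s == o)
            if n_o >= 5:
                blocks.append(
                    OrientationBlock(scaffold, i, last_o, o, n_o, last_o - i + 1 - n_o)
                )
                n_in_blocks += last_o - i + 1
                i = last_o + 1
            else:
                i += 1
    return blocks, (n_in_blocks / n_total) if n_total else 0.0


def tandem_duplication_clusters(
    proteins: dict[str, str],
    genes: list[GeneModel],
    min_identity: float = 0.95,
    min_cov: float = 0.90,
) -> list[TandemCluster]:
    """Tandemly duplicated gene clusters within one genome.

    Homolog pairs must share >= ``min_identity`` local-alignment identity
    over >= ``min_cov`` of the longest protein; single-linkage components
    over those edges are then split into co-localized runs where
    consecutive members are separated by at most one non-member gene.
    Only runs of >= 2 genes are reported.  Output is invariant to protein
    input order.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    ids = sorted(gid for gid in proteins if gid in gene_by_id)
    parent = {gid: gid for gid in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pa, pb = proteins[a], proteins[b]
            longest = max(len(pa), len(pb))
            # cheap length guard: identical-ish pairs have near-equal lengths
            if min(len(pa), len(pb)) < min_cov * longest:
                continue
            hit = local_align(pa, pb, ids=(a, b))
            if hit.identity >= min_identity and hit.length >= min_cov * longest:
                parent[find(a)] = find(b)

    components: dict[str, list[str]] = {}
    for gid in ids:
        components.setdefault(find(gid), []).append(gid)

    clusters: list[TandemCluster] = []
    for comp in components.values():
        if len(comp) < 2:
            continue
        members = sorted((gene_by_id[g] for g in comp), key=lambda g: (g.scaffold_id, g.rank))
        run: list[GeneModel] = []
        for g in members:
            if run and g.scaffold_id == run[-1].scaffold_id and g.rank - run[-1].rank <= 2:
                run.append(g)
            else:
                if len(run) >= 2:
                    clusters.append(TandemCluster(run[0].scaffold_id,
                                                  tuple(x.gene_id for x in run),
                                                  run[0].rank, run[-1].rank))
                run = [g]
        if len(run) >= 2:
            clusters.append(TandemCluster(run[0].scaffold_id,
                                          tuple(x.gene_id for x in run),
                                          run[0].rank, run[-1].rank))
    clusters.sort(key=lambda c: (c.scaffold_id, c.first_rank))
    return clusters


def telomere_scan(
    genomes: list[GenomeSeq],
    motifs: tuple[str, ...] = TELOMERE_MOTIFS,
    terminal_window: int = 200,
    min_copies: int = 3,
) -> dict[tuple[str, str], bool]:
    """Telomere-motif calls per scaffold end.

    An end is positive when >= ``min_copies`` tandem copies of the motifs
    (interleaved variants allowed, either strand) occur within the terminal
    window.  Keys are (scaffold_id, '5p'|'3p').
    """
    fwd = re.compile("(?:" + "|".join(motifs) + "){%d,}" % min_copies)
    rev = re.compile("(?:" + "|".join(revcomp(m) for m in motifs) + "){%d,}" % min_copies)
    calls = {}
    for g in genomes:
        head = g.sequence[:terminal_window]
        tail = g.sequence[-terminal_window:]
        calls[(g.scaffold_id, "5p")] = bool(fwd.search(head) or rev.search(head))
        calls[(g.scaffold_id, "3p")] = bool(fwd.search(tail) or rev.search(tail))
    return calls


def blocks_table(blocks: list[OrientationBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(scaffold=b.scaffold_id, first_rank=b.first_rank, last_rank=b.last_rank,
              orientation=b.orientation, n_genes=b.n_genes,
              n_interruptions=b.n_interruption_genes) for b in blocks]
    )
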