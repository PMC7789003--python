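"""Spliced-leader (SL) trans-splicing evidence: find SL-bearing reads, map
their junctions onto the genome, and assign them to genes.

The dinoflagellate spliced leader (DinoSL) is a 22-nt leader trans-spliced
onto mRNA 5' ends; mature transcripts carry a (usually truncated) suffix of
it, always ending in the 3' pentamer TCAAG.  The SL sequence itself is
configuration; only its length and 3' end are assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import revcomp
from .io import GeneModel, GenomeSeq

logger = logging.getLogger(__name__)

MIN_SL_SUFFIX = 5


@dataclass(frozen=True)
class SLCandidate:
    read_id: str
    sequence: str
    suffix_len: int  # length of the matched SL suffix at the read 5' end


@dataclass(frozen=True)
class SLJunction:
    read_id: str
    scaffold_id: str
    position: int  # genomic coordinate of the first transcribed base (1-based)
    strand: str
    suffix_len: int
    upstream_AG_ok: bool
    assigned_gene: str | None = None
    assignment_kind: str | None = None  # utr5 | first_exon | nearest


def find_sl_reads(reads: dict[str, str], sl_seq: str, k: int = 8) -> list[SLCandidate]:
    """Reads whose prefix is a suffix of the SL of length >= 5.

    A k-mer index over the SL's 3' 16-mer prefilters the reads; the longest
    SL suffix equal to the read prefix is recorded.  Matching suffixes
    necessarily end with the SL 3' pentamer.  Output order is sorted by
    read id (input-order invariant).
    """
    if len(sl_seq) < 16:
        raise ValueError("SL sequence shorter than its 16-nt 3' region")
    tail16 = sl_seq[-16:]
    kmers = {tail16[i : i + k] for i in range(len(tail16) - k + 1)}
    out = []
    for read_id in sorted(reads):
        seq = reads[read_id].upper()
        head = seq[: len(sl_seq)]
        if not any(head[i : i + k] in kmers for i in range(max(1, len(head) - k + 1))):
            # suffixes of 5..k-1 nt carry no full k-mer; test them directly
            if not any(seq.startswith(sl_seq[-L:]) for L in range(MIN_SL_SUFFIX, k)):
                continue
        best = 0
        for L in range(len(sl_seq), MIN_SL_SUFFIX - 1, -1):
            if seq.startswith(sl_seq[-L:]):
                best = L
                break
        if best >= MIN_SL_SUFFIX:
            out.append(SLCandidate(read_id, seq, best))
    return out


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i == -1:
            return hits
        hits.append(i)
        start = i + 1


def locate_sl_junction(
    candidate: SLCandidate,
    genomes: list[GenomeSeq],
    sl_seq: str,
    max_extension: int = 13,
) -> SLJunction | None:
    """Map the post-SL portion of a candidate read to the genome.

    The portion after the SL suffix must match the genome exactly and
    uniquely (ambiguous or unmappable candidates are dropped with a logged
    reason); the junction is the genomic coordinate of the first post-SL
    base.  The two read bases immediately preceding the junction must be
    the SL 3' "AG"; when they are not (e.g. sequencing error), the junction
    is shifted upstream by up to ``max_extension`` bases while the read
    prefix stays consistent with the SL, else the junction is flagged
    ``upstream_AG_ok=False``.
    """
    body = candidate.sequence[candidate.suffix_len :]
    if len(body) < 20:
        logger.info("read %s: post-SL portion too short to map", candidate.read_id)
        return None
    hits: list[tuple[str, str, int]] = []
    for g in genomes:
        for pos in _find_all(g.sequence, body):
            hits.append((g.scaffold_id, "+", pos + 1))
        for pos in _find_all(g.sequence, revcomp(body)):
            hits.append((g.scaffold_id, "-", pos + len(body)))
    if not hits:
        logger.info("read %s: post-SL portion unmappable, dropped", candidate.read_id)
        return None
    if len(hits) > 1:
        logger.info("read %s: post-SL portion maps to %d loci, dropped as ambiguous",
                    candidate.read_id, len(hits))
        return None
    scaffold, strand, position = hits[0]

    suffix_len = candidate.suffix_len
    ag_ok = candidate.sequence[suffix_len - 2 : suffix_len] == "AG"
    if not ag_ok:
        for shift in range(1, max_extension + 1):
            s = suffix_len - shift
            if s < MIN_SL_SUFFIX:
                break
            if candidate.sequence[:s] == sl_seq[-s:] and candidate.sequence[s - 2 : s] == "AG":
                suffix_len = s
                position = position - shift if strand == "+" else position + shift
                ag_ok = True
                break
    return SLJunction(candidate.read_id, scaffold, position, strand, suffix_len, ag_ok)


def assign_sl_to_gene(junction: SLJunction, genes: list[GeneModel]) -> SLJunction:
    """Attach a junction to a gene: 5' UTR overlap, then first coding exon
    overlap, then the nearest strand-consistent gene by distance to its
    start (ties to the smaller gene id)."""
    same = [g for g in genes
            if g.scaffold_id == junction.scaffold_id and g.strand == junction.strand]
    if not same:
        return junction
    pos = junction.position
    for g in same:
        if g.utr5 and g.utr5[0] <= pos <= g.utr5[1]:
            return SLJunction(**{**junction.__dict__, "assigned_gene": g.gene_id,
                                 "assignment_kind": "utr5"})
    for g in same:
        first = g.exons[0] if g.strand == "+" else g.exons[-1]
        if first[0] <= pos <= first[1]:
            return SLJunction(**{**junction.__dict__, "assigned_gene": g.gene_id,
                                 "assignment_kind": "first_exon"})

    def gene_start(g: GeneModel) -> int:
        return g.start if g.strand == "+" else g.end

    nearest = min(same, key=lambda g: (abs(gene_start(g) - pos), g.gene_id))
    return SLJunction(**{**junction.__dict__, "assigned_gene": nearest.gene_id,
                         "assignment_kind": "nearest"})


def build_sl_consensus(candidates: list[SLCandidate]) -> tuple[pd.DataFrame, str]:
    """Right-anchored base-frequency matrix over the SL-derived prefixes.

    Prefixes are 3'-aligned (the SL 3' end is the common anchor); the
    consensus string is the per-column majority base.
    """
    if not candidates:
        raise ValueError("no SL candidates")
    width = max(c.suffix_len for c in candidates)
    counts = np.zeros((4, width))
    bases = "ACGT"
    for c in candidates:
        prefix = c.sequence[: c.suffix_len].rjust(width, "N")
        for pos, b in enumerate(prefix):
            if b in bases:
                counts[bases.index(b), pos] += 1
    totals = counts.sum(axis=0)
    safe = np.where(totals == 0, 1.0, totals)
    freqs = counts / safe
    cols = [f"-{width - i}" for i in range(width)]
    matrix = pd.DataFrame(freqs, index=list(bases), columns=cols)
    consensus = "".join(
        bases[int(np.argmax(counts[:, i]))] if totals[i] > 0 else "N" for i in range(width)
    )
    return matrix, consensus


def junction_table(junctions: list[SLJunction]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(read_id=j.read_id, scaffold=j.scaffold_id, position=j.position,
              strand=j.strand, suffix_len=j.suffix_len, upstream_AG_ok=j.upstream_AG_ok,
              gene=j.assigned_gene or "", kind=j.assignment_kind or "")
         for j in junctions]
    )
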