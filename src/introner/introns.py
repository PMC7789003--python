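"""Validated intron catalog: junction filtering, splice-site classification,
splice-site frequency matrices, and per-gene intron typing.

An intron is *canonical* iff its sense-strand donor/acceptor dinucleotides
are GT..AG; every other intron is non-canonical (NCI).  GC-AG and GA-AG
donors form a separately reported subcategory that still counts as NCI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import gc_fraction, revcomp
from .io import GeneModel, GenomeSeq, JunctionRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
DINUCS = [a + b for a in BASES for b in BASES]


@dataclass
class Intron:
    """One junction-validated intron (coordinates 1-based inclusive)."""

    scaffold_id: str
    start: int
    end: int
    strand: str
    seq: str
    support: int
    host_gene: str | None = None
    phase: int | None = None

    @property
    def intron_id(self) -> str:
        return f"{self.scaffold_id}:{self.start}-{self.end}({self.strand})"

    @property
    def donor2(self) -> str:
        return self.seq[:2]

    @property
    def acceptor2(self) -> str:
        return self.seq[-2:]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def gc(self) -> float:
        return gc_fraction(self.seq)

    @property
    def klass(self) -> str:
        return "canonical" if (self.donor2, self.acceptor2) == ("GT", "AG") else "NCI"

    @property
    def site_cat(self) -> str:
        return classify_splice_sites(self)


def classify_splice_sites(intron: Intron) -> str:
    """Splice-site category: GT-AG, GC/GA-AG, or other."""
    d, a = intron.donor2, intron.acceptor2
    if (d, a) == ("GT", "AG"):
        return "GT-AG"
    if d in ("GC", "GA") and a == "AG":
        return "GC/GA-AG"
    return "other"


def _resolve_strand(plus_seq: str, junction: JunctionRecord, host: GeneModel | None) -> str:
    """Resolve '?' junction strands: splice dinucleotides first, then the
    host gene's strand, '+' as last resort."""
    if junction.strand in "+-":
        return junction.strand
    if plus_seq[:2] == "GT" and plus_seq[-2:] == "AG":
        return "+"
    if plus_seq[:2] == "CT" and plus_seq[-2:] == "AC":
        return "-"
    if host is not None:
        return host.strand
    return "+"


def extract_validated_introns(
    junctions: list[JunctionRecord],
    genomes: list[GenomeSeq],
    genes: list[GeneModel],
    min_support: int = 3,
    min_len: int = 40,
    max_len: int = 1000,
) -> list[Intron]:
    """Build the validated intron set from junction evidence.

    Duplicate junctions (same scaffold, start, end, strand) are merged with
    summed support before filtering; the support threshold is inclusive
    (``support >= min_support``) and the length window is closed
    [min_len, max_len].  Sense-strand sequence is the reverse complement of
    the plus-strand genomic slice for '-' junctions.  A host gene is
    assigned when the junction lies within a gene's span on the same
    strand; the phase is computed from the CDS when the junction coincides
    with an annotated exon boundary pair.
    """
    seqs = {g.scaffold_id: g.sequence for g in genomes}
    genes_by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_scaffold.setdefault(g.scaffold_id, []).append(g)

    # merge duplicates (strand '?' merges only with itself)
    merged: dict[tuple, int] = {}
    for j in junctions:
        key = (j.scaffold_id, j.start, j.end, j.strand)
        merged[key] = merged.get(key, 0) + j.support

    n_in = len(merged)
    introns: list[Intron] = []
    for (scaffold, start, end, strand), support in sorted(merged.items()):
        if scaffold not in seqs:
            logger.warning("junction %s:%d-%d on unknown scaffold, skipped", scaffold, start, end)
            continue
        if start < 1 or end > len(seqs[scaffold]):
            logger.warning("junction %s:%d-%d outside scaffold bounds, skipped", scaffold, start, end)
            continue
        if support < min_support:
            continue
        length = end - start + 1
        if length < min_len or length > max_len:
            continue
        plus_seq = seqs[scaffold][start - 1 : end]
        host = None
        for g in genes_by_scaffold.get(scaffold, []):
            if g.exons[0][0] <= start and end <= g.exons[-1][1]:
                if strand == "?" or g.strand == strand:
                    host = g
                    break
        resolved = _resolve_strand(plus_seq, JunctionRecord(scaffold, start, end, strand, support), host)
        seq = plus_seq if resolved == "+" else revcomp(plus_seq)
        phase = None
        if host is not None and host.strand == resolved:
            offset = host.cds_offset_of_intron(start, end)
            if offset is not None:
                phase = offset % 3
        introns.append(
            Intron(scaffold, start, end, resolved, seq, support,
                   host_gene=host.gene_id if host else None, phase=phase)
        )
    logger.info("validated introns: %d in, %d retained", n_in, len(introns))
    return introns


def splice_site_frequency(
    introns: list[Intron],
    genomes: list[GenomeSeq] | None = None,
    n_intronic: int = 10,
    n_flank: int = 5,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Donor/acceptor dinucleotide count table and positional base
    frequencies.

    Returns a 16x16 table (rows: donor dinucleotide, columns: acceptor) whose
    entries sum to the number of introns, plus base-frequency matrices for
    the first/last ``n_intronic`` intronic positions and ``n_flank`` flanking
    exonic positions on each side (keys: ``five_prime``, ``three_prime``).
    Flank positions beyond scaffold ends are padded with N and excluded from
    the frequency denominators; the matrices are directly renderable as
    sequence logos.
    """
    if not introns:
        raise ValueError("splice_site_frequency: empty intron list")
    table = pd.DataFrame(0, index=DINUCS, columns=DINUCS, dtype=int)
    for intr in introns:
        d, a = intr.donor2, intr.acceptor2
        if d in table.index and a in table.columns:
            table.loc[d, a] += 1

    seqs = {g.scaffold_id: g.sequence for g in genomes} if genomes else {}

    def window(intr: Intron, side: str) -> str:
        scaffold = seqs.get(intr.scaffold_id, "")
        if side == "five":
            if intr.strand == "+":
                flank = scaffold[max(0, intr.start - 1 - n_flank) : intr.start - 1] if scaffold else ""
                flank = "N" * (n_flank - len(flank)) + flank
            else:
                flank = scaffold[intr.end : intr.end + n_flank] if scaffold else ""
                flank = revcomp(flank)
                flank = "N" * (n_flank - len(flank)) + flank
            if not scaffold:
                flank = "N" * n_flank
            body = intr.seq[:n_intronic].ljust(n_intronic, "N")
            return flank + body
        else:
            if intr.strand == "+":
                flank = scaffold[intr.end : intr.end + n_flank] if scaffold else ""
                flank = flank + "N" * (n_flank - len(flank))
            else:
                flank = scaffold[max(0, intr.start - 1 - n_flank) : intr.start - 1] if scaffold else ""
                flank = revcomp(flank)
                flank = flank + "N" * (n_flank - len(flank))
            if not scaffold:
                flank = "N" * n_flank
            body = intr.seq[-n_intronic:].rjust(n_intronic, "N")
            return body + flank

    matrices = {}
    for key, side in (("five_prime", "five"), ("three_prime", "three")):
        width = n_flank + n_intronic
        counts = np.zeros((4, width))
        for intr in introns:
            for pos, base in enumerate(window(intr, side)):
                if base in BASES:
                    counts[BASES.index(base), pos] += 1
        totals = counts.sum(axis=0)
        totals[totals == 0] = 1.0
        freqs = counts / totals
        if key == "five_prime":
            cols = [f"E{-i}" for i in range(n_flank, 0, -1)] + [f"I{i}" for i in range(1, n_intronic + 1)]
        else:
            cols = [f"I{-i}" for i in range(n_intronic, 0, -1)] + [f"E{i}" for i in range(1, n_flank + 1)]
        matrices[key] = pd.DataFrame(freqs, index=list(BASES), columns=cols)
    return table, matrices


def gene_intron_typing(genes: list[GeneModel], introns: list[Intron]) -> dict[str, str]:
    """Partition genes into canonical-only / NCI-only / heterogeneous /
    intronless by the classes of their validated introns.  Introns without
    a host gene are excluded."""
    by_gene: dict[str, set[str]] = {}
    for intr in introns:
        if intr.host_gene is not None:
            by_gene.setdefault(intr.host_gene, set()).add(intr.klass)
    labels = {}
    for g in genes:
        classes = by_gene.get(g.gene_id)
        if not classes:
            labels[g.gene_id] = "intronless"
        elif classes == {"canonical"}:
            labels[g.gene_id] = "canonical-only"
        elif classes == {"NCI"}:
            labels[g.gene_id] = "NCI-only"
        else:
            labels[g.gene_id] = "heterogeneous"
    return labels


def catalog_table(introns: list[Intron]) -> pd.DataFrame:
    """Intron catalog as a tidy table (one row per intron)."""
    rows = [
        dict(
            intron_id=i.intron_id, scaffold=i.scaffold_id, start=i.start, end=i.end,
            strand=i.strand, length=i.length, support=i.support, donor2=i.donor2,
            acceptor2=i.acceptor2, klass=i.klass, site_cat=i.site_cat, gc=round(i.gc, 4),
            host_gene=i.host_gene if i.host_gene else "", phase="" if i.phase is None else i.phase,
        )
        for i in introns
    ]
    return pd.DataFrame(rows)
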