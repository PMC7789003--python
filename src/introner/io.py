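"""Readers/writers for genome FASTA, GFF3 gene models, and junction tables.

Coordinate convention: all intervals are 1-based inclusive internally (the
GFF3 convention).  BED-style 0-based half-open coordinates are accepted and
produced only at the boundary, via :func:`introner._utils.to_bed` /
:func:`introner._utils.from_bed`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._utils import DEFAULT_SL, from_bed

logger = logging.getLogger(__name__)

CODON_TABLE = 1  # standard code


@dataclass(frozen=True)
class GenomeSeq:
    """One scaffold: identifier plus uppercase DNA over {A,C,G,T,N}."""

    scaffold_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"scaffold {self.scaffold_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene: scaffold, strand, ordered exons, and rank along its scaffold.

    ``exons`` are 1-based inclusive genomic (start, end) pairs, ascending and
    non-overlapping regardless of strand.  ``rank`` is the 0-based index of
    the gene among all genes on its scaffold ordered by start coordinate.
    ``utr5`` is an optional (start, end) 5' UTR interval.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    rank: int = -1
    utr5: tuple[int, int] | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start {s} > end {e}")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")

    @property
    def start(self) -> int:
        first = self.exons[0][0]
        return min(first, self.utr5[0]) if self.utr5 else first

    @property
    def end(self) -> int:
        last = self.exons[-1][1]
        return max(last, self.utr5[1]) if self.utr5 else last

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Annotation-implied introns (first/last intronic base, inclusive)."""
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def cds_sequence(self, scaffold_seq: str) -> str:
        """Spliced coding sequence, 5'->3' on the coding strand."""
        parts = [scaffold_seq[s - 1 : e] for s, e in self.exons]
        cds = "".join(parts)
        if self.strand == "-":
            from ._utils import revcomp

            cds = revcomp(cds)
        return cds

    def protein(self, scaffold_seq: str) -> str:
        """Translated CDS, stop codon stripped."""
        prot = str(Seq(self.cds_sequence(scaffold_seq)).translate())
        return prot.rstrip("*")

    def cds_offset_of_intron(self, intron_start: int, intron_end: int) -> int | None:
        """Coding nucleotides upstream (in coding direction) of an intron.

        Returns None when the intron does not sit exactly between two exons
        of this gene.
        """
        for i, (istart, iend) in enumerate(self.introns):
            if (istart, iend) == (intron_start, intron_end):
                if self.strand == "+":
                    return sum(e - s + 1 for s, e in self.exons[: i + 1])
                return sum(e - s + 1 for s, e in self.exons[i + 1 :])
        return None


@dataclass(frozen=True)
class JunctionRecord:
    """One splice-junction observation: first/last intronic base + support."""

    scaffold_id: str
    start: int
    end: int
    strand: str
    support: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"junction {self.scaffold_id}:{self.start}-{self.end}: start > end")
        if self.support < 0:
            raise ValueError("negative junction support")
        if self.strand not in ("+", "-", "?"):
            raise ValueError(f"bad junction strand {self.strand!r}")


@dataclass
class PipelineConfig:
    """Resolved tunables for a pipeline run; serialized into every run log.

    Defaults mirror the per-module defaults; see docs/methods.md.
    """

    seed: int = 0
    min_support: int = 3
    min_intron_len: int = 40
    max_intron_len: int = 1000
    ir_min_len: int = 8
    ir_max_len: int = 20
    ir_end_window: int = 6
    ir_min_loop: int = 3
    dr_min_len: int = 3
    dr_max_len: int = 8
    dr_boundary_window: int = 8
    min_intron_identity: float = 0.30
    profile_flank: int = 5
    profile_pseudocount: float = 0.5
    n_superfamilies: int = 4
    orientation_window: int = 10
    tandem_min_identity: float = 0.95
    tandem_min_cov: float = 0.90
    telomere_window: int = 200
    telomere_min_copies: int = 3
    align_gap_open: int = 10
    align_gap_extend: int = 1
    min_align_score: int = 300
    synteny_min_anchors: int = 5
    synteny_max_gap: int = 15
    mask_window: int = 9
    mask_min_matches: int = 5
    mask_gap_margin: int = 5
    sl_seq: str = DEFAULT_SL
    sl_kmer: int = 8
    sl_max_extension: int = 13

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_genome(fasta_path) -> list[GenomeSeq]:
    """Load scaffolds from FASTA, uppercase-normalized."""
    out = []
    seen = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate scaffold id {rec.id}")
        seen.add(rec.id)
        out.append(GenomeSeq(rec.id, str(rec.seq).upper()))
    return out


def write_genome(genomes: list[GenomeSeq], fasta_path) -> None:
    recs = [SeqRecord(Seq(g.sequence), id=g.scaffold_id, description="") for g in genomes]
    SeqIO.write(recs, str(fasta_path), "fasta")


def assign_ranks(genes: list[GeneModel]) -> list[GeneModel]:
    """Assign per-scaffold ranks by ascending gene start (stable, in place)."""
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    for members in by_scaffold.values():
        members.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(members):
            g.rank = i
    return genes


def read_gene_models(gff3_path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/five_prime_UTR features into GeneModels.

    Genes without explicit exon children fall back to CDS children; ranks are
    assigned per scaffold by ascending start.
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
        if not exons:
            exons = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        if not exons:
            raise ValueError(f"gene {gene.id}: no exon or CDS features")
        exons = sorted(set(exons))
        utrs = [(f.start, f.end) for f in db.children(gene, featuretype="five_prime_UTR")]
        utr5 = utrs[0] if utrs else None
        genes.append(
            GeneModel(
                gene_id=gene.id,
                scaffold_id=gene.seqid,
                strand=gene.strand,
                exons=exons,
                utr5=utr5,
            )
        )
    return assign_ranks(genes)


def load_annotated_genome(fasta_path, gff3_path) -> tuple[list[GenomeSeq], list[GeneModel]]:
    """Load and cross-validate a genome FASTA and its GFF3 annotation.

    Every gene must reference an existing scaffold and lie within its bounds.
    """
    genomes = read_genome(fasta_path)
    lengths = {g.scaffold_id: len(g) for g in genomes}
    genes = read_gene_models(gff3_path)
    for g in genes:
        if g.scaffold_id not in lengths:
            raise ValueError(f"gene {g.gene_id}: unknown scaffold {g.scaffold_id}")
        if g.end > lengths[g.scaffold_id] or g.start < 1:
            raise ValueError(
                f"gene {g.gene_id}: coordinates {g.start}-{g.end} outside scaffold "
                f"{g.scaffold_id} (length {lengths[g.scaffold_id]})"
            )
    return genomes, genes


def write_gene_models(genes: list[GeneModel], gff3_path) -> None:
    """Emit gene/mRNA/exon/five_prime_UTR GFF3 (version 3 header)."""
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.scaffold_id, x.start)):
            cols = [g.scaffold_id, "introner", "gene", str(g.start), str(g.end), ".", g.strand, "."]
            fh.write("\t".join(cols + [f"ID={g.gene_id}"]) + "\n")
            mrna = f"{g.gene_id}.t1"
            cols[2] = "mRNA"
            fh.write("\t".join(cols + [f"ID={mrna};Parent={g.gene_id}"]) + "\n")
            if g.utr5:
                fh.write(
                    "\t".join(
                        [g.scaffold_id, "introner", "five_prime_UTR", str(g.utr5[0]),
                         str(g.utr5[1]), ".", g.strand, ".", f"Parent={mrna}"]
                    )
                    + "\n"
                )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    "\t".join(
                        [g.scaffold_id, "introner", "exon", str(s), str(e), ".", g.strand,
                         ".", f"ID={g.gene_id}.exon{i};Parent={mrna}"]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Junction TSV
# ---------------------------------------------------------------------------

def load_junctions(path, bed=False) -> list[JunctionRecord]:
    """Read a junction TSV: scaffold, start, end, strand, support.

    With ``bed=True`` the start/end columns are interpreted as 0-based
    half-open (BED-style) and converted to first/last intronic base.
    A header line starting with 'scaffold' is tolerated.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "scaffold":
                continue
            if len(parts) < 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 columns, got {len(parts)}")
            try:
                start, end, support = int(parts[1]), int(parts[2]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from exc
            if bed:
                start, end = from_bed(start, end)
            records.append(JunctionRecord(parts[0], start, end, parts[3], support))
    if not records:
        logger.warning("no junction records in %s", path)
    return records


def write_junctions(records: list[JunctionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tstrand\tsupport\n")
        for r in records:
            fh.write(f"{r.scaffold_id}\t{r.start}\t{r.end}\t{r.strand}\t{r.support}\n")


def read_fasta_dict(path) -> dict[str, str]:
    """FASTA as an id -> uppercase sequence mapping (proteins or reads)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta_dict(seqs: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()],
        str(path),
        "fasta",
    )
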