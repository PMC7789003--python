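"""Synthetic two-strain genome generator with complete truth tables.

The generator emulates a pair of diverged, compact, gene-dense strain
genomes of the kind sequenced for co-occurring syndinian parasites: short
intergenic spacers, long runs of co-oriented genes, telomere repeat motifs
at scaffold ends, introns planted in three classes (canonical GT-AG,
plain non-canonical, and introner elements with inverted-repeat arms and
direct repeats at the boundaries), syntenic ortholog pairs at a target
protein identity, tandem duplicates, junction read support, and
spliced-leader (SL) tagged reads.  Strain B is derived from strain A by
codon-level substitution (2:1 synonymous preference), strain-specific
intron insertion, and segmental inversions; every planted feature is
recorded so downstream detectors can be scored against truth.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._utils import DEFAULT_SL, revcomp
from .io import (GeneModel, GenomeSeq, JunctionRecord, write_genome,
                 write_gene_models, write_junctions, write_fasta_dict)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD.forward_table.items()):
    AA_TO_CODONS.setdefault(aa, []).append(codon)
STOP_CODONS = sorted(_STANDARD.stop_codons)
AMINO_ACIDS = sorted(AA_TO_CODONS)
_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "N": "ACGT"}
BASES = "ACGT"

TELOMERE = "TTTAGGG"
TELOMERE_VARIANT = "TTTGGGG"


@dataclass
class SimConfig:
    """All generator tunables; defaults are the package's study conditions.

    Class fractions follow the strain-A-like splice spectrum (about a third
    canonical GT-AG); the IE arm template is the A25-like "TTA[AG][AG]...G"
    motif.  See docs/methods.md for the rationale behind every default.
    """

    seed: int = 0
    n_scaffolds: int = 4
    genes_per_scaffold: int = 50
    fraction_spliced: float = 0.7
    mean_introns_per_spliced_gene: float = 3.0
    class_fractions: tuple[float, float, float] = (0.34, 0.36, 0.30)  # canonical, NCI-plain, IE
    n_families: int = 5
    ir_len_range: tuple[int, int] = (8, 20)
    dr_len_range: tuple[int, int] = (3, 5)
    family_motif_template: str = "TTARR"
    family_motif_end: str = "G"
    target_protein_identity: float = 0.5
    # strain-specific insertion probability per intron site and per unit of
    # protein divergence (1 - identity); the realized per-site probability is
    # intron_gain_rate * (1 - target_protein_identity), so duplicate genomes
    # have strictly identical intron positions
    intron_gain_rate: float = 0.2
    rearrangement_rate: float = 0.02  # expected inversions per gene
    junction_depth_mean: float = 20.0
    false_junction_rate: float = 0.05
    sl_seq: str = DEFAULT_SL
    read_error_rate: float = 0.0
    fraction_trans_spliced: float = 0.3
    n_sl_reads: int = 200
    protein_len_range: tuple[int, int] = (120, 300)
    utr_len_range: tuple[int, int] = (60, 120)
    intergenic_median: float = 800.0
    intergenic_sigma: float = 0.6
    orientation_flip_prob: float = 0.02
    n_tandem_pairs: int = 4
    identical_ie_groups: tuple[int, ...] = (3, 2)
    plant_telomeres: bool = True
    telomere_copies: int = 5

    def validate(self) -> None:
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if self.class_fractions[2] > 0 and self.n_families == 0:
            raise ValueError("IE fraction > 0 requires n_families > 0")
        if not (0 <= self.intron_gain_rate <= 1):
            raise ValueError("intron_gain_rate must be in [0, 1]")
        lo, hi = self.ir_len_range
        if not (8 <= lo <= hi <= 20):
            raise ValueError("IR length range must lie within 8-20")
        dlo, dhi = self.dr_len_range
        if not (3 <= dlo <= dhi <= 8):
            raise ValueError("DR length range must lie within 3-8")


@dataclass
class IntronTruth:
    """One planted intron instance in one strain."""

    strain: str
    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    cds_offset: int
    phase: int
    klass: str  # canonical | NCI-plain | IE
    family_id: str = ""
    arm5: str = ""
    arm3: str = ""
    arm5_offset: int = 0
    arm3_offset_from_end: int = 0
    dr_seq: str = ""
    seq: str = ""
    conserved: bool = True
    site_id: str = ""

    @property
    def intron_id(self) -> str:
        return f"{self.scaffold_id}:{self.start}-{self.end}({self.strand})"


@dataclass
class SLReadTruth:
    read_id: str
    strain: str
    gene_id: str
    scaffold_id: str
    position: int  # true junction: first transcribed genomic base
    strand: str
    suffix_len: int
    sequence: str


@dataclass
class TruthSet:
    config: SimConfig
    genomes: dict[str, list[GenomeSeq]]
    genes: dict[str, list[GeneModel]]
    proteins: dict[str, dict[str, str]]
    introns: dict[str, list[IntronTruth]]
    orthologs: list[tuple[str, str, float]]
    family_arms: dict[str, tuple[str, str]]
    trans_spliced: dict[str, list[str]]
    sl_reads: dict[str, list[SLReadTruth]]
    inversions: dict[str, list[tuple[str, int, int]]]  # strain -> (scaffold, first, last rank)

    def identical_ie_pairs_expected(self, strain: str) -> int:
        """C(m, 2) summed over groups of byte-identical planted IE sequences."""
        counts = Counter(t.seq for t in self.introns[strain] if t.klass == "IE")
        return sum(m * (m - 1) // 2 for m in counts.values() if m > 1)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _rand_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n)) if n > 0 else ""


def _expand_iupac(rng, template: str) -> str:
    return "".join(rng.choice(list(_IUPAC[c])) for c in template)


def _random_protein(rng, n: int) -> str:
    return "M" + "".join(rng.choice(AMINO_ACIDS, size=n - 1))


def _back_translate(rng, protein: str) -> str:
    return "".join(AA_TO_CODONS[aa][rng.integers(len(AA_TO_CODONS[aa]))] for aa in protein)


def _translate_ok(cds: str) -> bool:
    """No internal stop codons."""
    for i in range(0, len(cds) - 2, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return False
    return True


@dataclass
class _Family:
    family_id: str
    arm5: str
    arm3: str
    loop_len: int
    dr_len: int


@dataclass
class _Site:
    """An intron site in ancestral CDS coordinates."""

    site_id: str
    cds_offset: int
    conserved: bool
    strain: str = ""  # for strain-specific sites
    klass: str = ""
    family: _Family | None = None
    seq: str = ""
    arm5_offset: int = 0
    arm3_offset_from_end: int = 0
    dr_seq: str = ""


class _Generator:
    def __init__(self, config: SimConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)

    # -- families -----------------------------------------------------------
    def make_families(self) -> list[_Family]:
        cfg, rng = self.cfg, self.rng
        families, seen = [], set()
        while len(families) < cfg.n_families:
            arm_len = int(rng.integers(cfg.ir_len_range[0], cfg.ir_len_range[1] + 1))
            head = _expand_iupac(rng, cfg.family_motif_template)
            tail = cfg.family_motif_end
            mid = _rand_seq(rng, arm_len - len(head) - len(tail))
            arm5 = (head + mid + tail)[:arm_len]
            if arm5 in seen:
                continue
            seen.add(arm5)
            families.append(_Family(
                family_id=f"TRUTHFAM{len(families) + 1}",
                arm5=arm5, arm3=revcomp(arm5),
                loop_len=int(rng.integers(20, 46)),
                dr_len=int(rng.integers(cfg.dr_len_range[0], cfg.dr_len_range[1] + 1)),
            ))
        return families

    # -- intron sequences ---------------------------------------------------
    def _intron_length(self) -> int:
        raw = int(self.rng.lognormal(math.log(200), 0.5))
        return min(max(raw, 44), 900)

    def canonical_intron(self) -> str:
        return "GT" + _rand_seq(self.rng, self._intron_length() - 4) + "AG"

    def nci_intron(self) -> str:
        seq = list(_rand_seq(self.rng, self._intron_length()))
        while seq[0] + seq[1] == "GT":
            seq[0] = str(self.rng.choice(list(BASES)))
            seq[1] = str(self.rng.choice(list(BASES)))
        return "".join(seq)

    def ie_intron(self, family: _Family) -> tuple[str, int, int]:
        """Assemble pad5 + arm5 + loop + arm3 + pad3; never canonical, and the
        planted arms are not extendable into the loop or the pads."""
        rng = self.rng
        for _ in range(50):
            o5 = int(rng.integers(0, 4))
            o3 = int(rng.integers(0, 4))
            loop_len = family.loop_len + int(rng.integers(-3, 4))
            loop_len = max(loop_len, 44 - 2 * len(family.arm5) - o5 - o3, 5)
            loop = list(_rand_seq(rng, loop_len))
            while loop[-1] == revcomp(loop[0]):
                loop[-1] = str(rng.choice(list(BASES)))
            pad5 = list(_rand_seq(rng, o5))
            pad3 = list(_rand_seq(rng, o3))
            # pads must not extend the arm pair outward
            if o5 >= 1 and o3 >= 1 and pad5[-1] == revcomp(pad3[0]):
                pad3[0] = str(rng.choice([b for b in BASES if b != revcomp(pad5[-1])]))
            seq = "".join(pad5) + family.arm5 + "".join(loop) + family.arm3 + "".join(pad3)
            if not (seq[:2] == "GT" and seq[-2:] == "AG"):
                return seq, o5, o3
        raise RuntimeError("could not assemble a non-canonical IE intron")

    def sample_class(self) -> str:
        r = self.rng.random()
        c, n, _ = self.cfg.class_fractions
        if r < c:
            return "canonical"
        if r < c + n:
            return "NCI-plain"
        return "IE"

    # -- main ---------------------------------------------------------------
    def run(self) -> TruthSet:
        cfg, rng = self.cfg, self.rng
        families = self.make_families()
        n_genes = cfg.n_scaffolds * cfg.genes_per_scaffold

        # ancestral genes
        genes_anc = []
        for gi in range(n_genes):
            plen = int(rng.integers(*cfg.protein_len_range))
            protein = _random_protein(rng, plen)
            cds = _back_translate(rng, protein)
            spliced = rng.random() < cfg.fraction_spliced
            n_sites = 1 + int(rng.poisson(cfg.mean_introns_per_spliced_gene - 1)) if spliced else 0
            genes_anc.append(dict(idx=gi, cds=cds, n_sites=n_sites))

        # intron sites per gene, in ancestral CDS coordinates
        p_gain = min(1.0, cfg.intron_gain_rate * (1.0 - cfg.target_protein_identity))
        for g in genes_anc:
            cds_len = len(g["cds"])
            offsets = set()
            sites: list[_Site] = []
            for si in range(g["n_sites"]):
                conserved = rng.random() >= p_gain
                strains = ["AB"] if conserved else ["A", "B"]
                for strain in strains:
                    for _ in range(30):
                        off = int(rng.integers(12, cds_len - 12))
                        if all(abs(off - o) > 10 for o in offsets):
                            offsets.add(off)
                            break
                    else:
                        continue
                    klass = self.sample_class()
                    site = _Site(site_id=f"g{g['idx']}s{si}{strain}", cds_offset=off,
                                 conserved=conserved, strain="" if strain == "AB" else strain,
                                 klass=klass)
                    if klass == "IE":
                        fam = families[int(rng.integers(len(families)))]
                        site.family = fam
                        site.seq, site.arm5_offset, site.arm3_offset_from_end = self.ie_intron(fam)
                    elif klass == "canonical":
                        site.seq = self.canonical_intron()
                    else:
                        site.seq = self.nci_intron()
                    sites.append(site)
            g["sites"] = sorted(sites, key=lambda s: s.cds_offset)

        # DR forcing on the ancestral CDS for conserved IE sites
        for g in genes_anc:
            cds = list(g["cds"])
            for site in g["sites"]:
                if site.klass == "IE" and site.conserved:
                    self._force_dr(cds, site)
            g["cds"] = "".join(cds)

        # derive strain-B CDS by codon substitution
        q = 1.0 - cfg.target_protein_identity
        for g in genes_anc:
            g["cds_A"] = g["cds"]
            g["cds_B"] = self._mutate_cds(g["cds"], q)
            for strain in "AB":
                cds = list(g[f"cds_{strain}"])
                for site in g["sites"]:
                    if site.klass == "IE" and site.strain == strain:
                        self._force_dr(cds, site)
                g[f"cds_{strain}"] = "".join(cds)

        # planted identical-IE groups (strain-specific extras)
        extra_sites: dict[str, list[tuple[int, _Site]]] = {"A": [], "B": []}
        for strain in "AB":
            for k, m in enumerate(cfg.identical_ie_groups):
                fam = families[k % len(families)]
                seq, o5, o3 = self.ie_intron(fam)
                chosen = rng.choice(n_genes, size=m, replace=False)
                for j, gi in enumerate(sorted(int(x) for x in chosen)):
                    g = genes_anc[gi]
                    cds_len = len(g[f"cds_{strain}"])
                    taken = {s.cds_offset for s in g["sites"]}
                    off = None
                    for _ in range(50):
                        cand = int(rng.integers(12, cds_len - 12))
                        if all(abs(cand - o) > 10 for o in taken):
                            off = cand
                            break
                    if off is None:
                        continue
                    site = _Site(site_id=f"ident{strain}{k}c{j}", cds_offset=off,
                                 conserved=False, strain=strain, klass="IE", family=fam,
                                 seq=seq, arm5_offset=o5, arm3_offset_from_end=o3)
                    extra_sites[strain].append((gi, site))

        # layout: strand pattern, scaffold assignment, tandem duplicates
        strands = []
        s = "+" if rng.random() < 0.5 else "-"
        for _ in range(n_genes):
            if rng.random() < cfg.orientation_flip_prob:
                s = "+" if s == "-" else "-"
            strands.append(s)

        order_a = [[gi for gi in range(sc * cfg.genes_per_scaffold,
                                       (sc + 1) * cfg.genes_per_scaffold)]
                   for sc in range(cfg.n_scaffolds)]
        # strain-B order: copy + segmental inversions
        order_b = [list(sc) for sc in order_a]
        flip_b: dict[int, bool] = {}
        inversions: list[tuple[str, int, int]] = []
        for sc_idx, sc_genes in enumerate(order_b):
            n_inv = rng.poisson(cfg.rearrangement_rate * len(sc_genes))
            for _ in range(n_inv):
                i = int(rng.integers(0, len(sc_genes) - 1))
                j = int(rng.integers(i + 1, min(i + 16, len(sc_genes)) + 1))
                sc_genes[i:j] = sc_genes[i:j][::-1]
                for gi in sc_genes[i:j]:
                    flip_b[gi] = not flip_b.get(gi, False)
                inversions.append((f"B_sc{sc_idx + 1}", i, j - 1))

        tandem_templates = sorted(int(x) for x in
                                  rng.choice(n_genes, size=cfg.n_tandem_pairs, replace=False)) \
            if cfg.n_tandem_pairs else []

        genomes: dict[str, list[GenomeSeq]] = {}
        gene_models: dict[str, list[GeneModel]] = {}
        proteins: dict[str, dict[str, str]] = {}
        intron_truth: dict[str, list[IntronTruth]] = {}
        trans_flags = {gi: rng.random() < cfg.fraction_trans_spliced for gi in range(n_genes)}
        trans_spliced: dict[str, list[str]] = {"A": [], "B": []}

        for strain, order in (("A", order_a), ("B", order_b)):
            scaffolds, models, prots, truths = [], [], {}, []
            extras = {gi: [] for gi in range(n_genes)}
            for gi, site in extra_sites[strain]:
                extras[gi].append(site)
            for sc_idx, sc_genes in enumerate(order):
                sc_name = f"{strain}_sc{sc_idx + 1}"
                parts: list[str] = []
                pos = 0
                if cfg.plant_telomeres:
                    telo5 = "".join(revcomp(TELOMERE if rng.random() < 0.7 else TELOMERE_VARIANT)
                                    for _ in range(cfg.telomere_copies))
                    parts.append(telo5)
                    pos += len(telo5)
                for gi in sc_genes:
                    spacer = int(np.clip(rng.lognormal(math.log(cfg.intergenic_median),
                                                       cfg.intergenic_sigma), 200, 3000))
                    parts.append(_rand_seq(rng, spacer))
                    pos += spacer
                    strand = strands[gi]
                    if strain == "B" and flip_b.get(gi, False):
                        strand = "+" if strand == "-" else "-"
                    placed = self._place_gene(
                        genes_anc[gi], extras[gi], strain, sc_name, pos, strand,
                        gene_id=f"{strain}_g{gi:04d}",
                    )
                    parts.append(placed["segment"])
                    pos += len(placed["segment"])
                    models.append(placed["model"])
                    prots[placed["model"].gene_id] = placed["protein"]
                    truths.extend(placed["introns"])
                    if trans_flags[gi]:
                        trans_spliced[strain].append(placed["model"].gene_id)
                    if gi in tandem_templates:
                        spacer2 = int(np.clip(rng.lognormal(math.log(cfg.intergenic_median),
                                                            cfg.intergenic_sigma), 200, 3000))
                        parts.append(_rand_seq(rng, spacer2))
                        pos += spacer2
                        dup = self._place_duplicate(genes_anc[gi], strain, sc_name, pos, strand,
                                                    gene_id=f"{strain}_g{gi:04d}d")
                        parts.append(dup["segment"])
                        pos += len(dup["segment"])
                        models.append(dup["model"])
                        prots[dup["model"].gene_id] = dup["protein"]
                tail_spacer = int(np.clip(rng.lognormal(math.log(cfg.intergenic_median),
                                                        cfg.intergenic_sigma), 200, 3000))
                parts.append(_rand_seq(rng, tail_spacer))
                if cfg.plant_telomeres:
                    parts.append("".join(TELOMERE if rng.random() < 0.7 else TELOMERE_VARIANT
                                         for _ in range(cfg.telomere_copies)))
                scaffolds.append(GenomeSeq(sc_name, "".join(parts)))
            # ranks by start
            by_sc: dict[str, list[GeneModel]] = {}
            for m in models:
                by_sc.setdefault(m.scaffold_id, []).append(m)
            for ms in by_sc.values():
                ms.sort(key=lambda m: m.start)
                for r, m in enumerate(ms):
                    m.rank = r
            genomes[strain] = scaffolds
            gene_models[strain] = models
            proteins[strain] = prots
            intron_truth[strain] = truths

        orthologs = [(f"A_g{gi:04d}", f"B_g{gi:04d}", cfg.target_protein_identity)
                     for gi in range(n_genes)]
        truth = TruthSet(
            config=cfg, genomes=genomes, genes=gene_models, proteins=proteins,
            introns=intron_truth, orthologs=orthologs,
            family_arms={f.family_id: (f.arm5, f.arm3) for f in families},
            trans_spliced=trans_spliced, sl_reads={"A": [], "B": []},
            inversions={"B": inversions, "A": []},
        )
        return truth

    # -- pieces -------------------------------------------------------------
    def _mutate_cds(self, cds: str, q: float) -> str:
        rng = self.rng
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        aa_of = _STANDARD.forward_table
        for i in range(1, len(codons)):
            codon = codons[i]
            if codon in STOP_CODONS:
                continue
            aa = aa_of[codon]
            if rng.random() < q:  # nonsynonymous
                new_aa = str(rng.choice([a for a in AMINO_ACIDS if a != aa]))
                codons[i] = AA_TO_CODONS[new_aa][rng.integers(len(AA_TO_CODONS[new_aa]))]
            elif rng.random() < min(2 * q, 1.0):  # synonymous, 2:1 preference
                syn = AA_TO_CODONS[aa]
                codons[i] = syn[rng.integers(len(syn))]
        return "".join(codons)

    def _force_dr(self, cds: list[str], site: _Site) -> None:
        """Plant a target-site-duplication-style direct repeat: copy the
        exonic bases immediately upstream of the insertion point over the
        bases immediately downstream.  Skipped when it would create an
        internal stop codon."""
        fam = site.family
        dlen = fam.dr_len if fam else 3
        off = site.cds_offset
        if off - dlen < 3 or off + dlen > len(cds) - 3:
            return
        dr = "".join(cds[off - dlen : off])
        backup = cds[off : off + dlen]
        cds[off : off + dlen] = list(dr)
        if _translate_ok("".join(cds)):
            site.dr_seq = dr
        else:
            cds[off : off + dlen] = backup

    def _gene_sense(self, cds: str, sites: list[_Site], utr_len: int):
        """Assemble the sense-strand gene region and sense-coordinate
        features (0-based)."""
        pieces = []
        exon_bounds = []  # (sense_start, sense_end) of coding exons
        intron_bounds = []  # (sense_start, sense_end, site)
        prev = 0
        pos = utr_len
        for site in sites:
            pieces.append(cds[prev : site.cds_offset])
            exon_bounds.append((pos, pos + (site.cds_offset - prev) - 1))
            pos += site.cds_offset - prev
            pieces.append(site.seq)
            intron_bounds.append((pos, pos + len(site.seq) - 1, site))
            pos += len(site.seq)
            prev = site.cds_offset
        pieces.append(cds[prev:])
        exon_bounds.append((pos, pos + (len(cds) - prev) - 1))
        return "".join(pieces), exon_bounds, intron_bounds

    def _place_gene(self, g: dict, extras: list[_Site], strain: str, scaffold: str,
                    offset0: int, strand: str, gene_id: str) -> dict:
        cfg, rng = self.cfg, self.rng
        cds = g[f"cds_{strain}"]
        sites = [s for s in g["sites"] if s.strain in ("", strain)] + extras
        sites = sorted(sites, key=lambda s: s.cds_offset)
        utr_len = int(rng.integers(*cfg.utr_len_range))
        utr_seq = _rand_seq(rng, utr_len)
        body, exon_bounds, intron_bounds = self._gene_sense(cds, sites, utr_len)
        sense = utr_seq + body
        L = len(sense)

        def to_genomic(p_start: int, p_end: int) -> tuple[int, int]:
            # sense 0-based -> genomic 1-based inclusive (offset0 = 0-based
            # genomic offset of the segment)
            if strand == "+":
                return offset0 + p_start + 1, offset0 + p_end + 1
            return offset0 + (L - 1 - p_end) + 1, offset0 + (L - 1 - p_start) + 1

        exons = sorted(to_genomic(s, e) for s, e in exon_bounds)
        utr5 = to_genomic(0, utr_len - 1)
        model = GeneModel(gene_id, scaffold, strand, exons, utr5=(min(utr5), max(utr5)))
        segment = sense if strand == "+" else revcomp(sense)

        truths = []
        for s0, e0, site in intron_bounds:
            gs, ge = to_genomic(s0, e0)
            truths.append(IntronTruth(
                strain=strain, gene_id=gene_id, scaffold_id=scaffold, start=gs, end=ge,
                strand=strand, cds_offset=site.cds_offset, phase=site.cds_offset % 3,
                klass=site.klass,
                family_id=site.family.family_id if site.family else "",
                arm5=site.family.arm5 if site.family else "",
                arm3=site.family.arm3 if site.family else "",
                arm5_offset=site.arm5_offset, arm3_offset_from_end=site.arm3_offset_from_end,
                dr_seq=site.dr_seq, seq=site.seq, conserved=site.conserved,
                site_id=site.site_id,
            ))
        protein = str(_translate(cds))
        return dict(segment=segment, model=model, protein=protein, introns=truths)

    def _place_duplicate(self, g: dict, strain: str, scaffold: str, offset0: int,
                         strand: str, gene_id: str) -> dict:
        """An intronless near-identical copy of the gene's protein (tandem
        duplicate; ~2% amino-acid divergence)."""
        cds = self._mutate_cds(g[f"cds_{strain}"], 0.02)
        utr_len = int(self.rng.integers(*self.cfg.utr_len_range))
        sense = _rand_seq(self.rng, utr_len) + cds
        L = len(sense)
        if strand == "+":
            exons = [(offset0 + utr_len + 1, offset0 + L)]
            utr5 = (offset0 + 1, offset0 + utr_len)
        else:
            exons = [(offset0 + 1, offset0 + L - utr_len)]
            utr5 = (offset0 + L - utr_len + 1, offset0 + L)
        model = GeneModel(gene_id, scaffold, strand, exons, utr5=utr5)
        return dict(segment=sense if strand == "+" else revcomp(sense),
                    model=model, protein=str(_translate(cds)), introns=[])


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate()).rstrip("*")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_truth(config: SimConfig) -> TruthSet:
    """Generate the two-strain genome pair and its complete truth tables."""
    return _Generator(config).run()


def emit_genome_files(truth: TruthSet, outdir) -> dict[str, dict[str, Path]]:
    """Write per-strain FASTA + GFF3 (+ protein FASTA); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for strain in truth.genomes:
        fasta = outdir / f"strain_{strain}.fasta"
        gff3 = outdir / f"strain_{strain}.gff3"
        prot = outdir / f"strain_{strain}.proteins.fasta"
        write_genome(truth.genomes[strain], fasta)
        write_gene_models(truth.genes[strain], gff3)
        write_fasta_dict(truth.proteins[strain], prot)
        paths[strain] = dict(fasta=fasta, gff3=gff3, proteins=prot)
    return paths


def emit_junctions(
    truth: TruthSet,
    strain: str,
    depth_mean: float | None = None,
    false_rate: float | None = None,
    seed: int | None = None,
    path=None,
) -> list[JunctionRecord]:
    """Junction evidence for one strain: every true intron with sampled read
    support, plus low-support false junctions placed inside exons (never
    coinciding with a true splice site)."""
    cfg = truth.config
    depth_mean = cfg.junction_depth_mean if depth_mean is None else depth_mean
    false_rate = cfg.false_junction_rate if false_rate is None else false_rate
    rng = np.random.default_rng(cfg.seed + 1000 if seed is None else seed)
    records = []
    true_coords = set()
    for t in truth.introns[strain]:
        support = int(rng.poisson(depth_mean))
        records.append(JunctionRecord(t.scaffold_id, t.start, t.end, t.strand, support))
        true_coords.add((t.scaffold_id, t.start, t.end))
    n_false = int(round(false_rate * len(records)))
    genes = truth.genes[strain]
    lengths = {g.scaffold_id: len(g) for g in truth.genomes[strain]}
    made = 0
    while made < n_false and genes:
        g = genes[int(rng.integers(len(genes)))]
        ex = g.exons[int(rng.integers(len(g.exons)))]
        start = int(rng.integers(ex[0], ex[1] + 1))
        end = start + int(rng.integers(50, 201))
        if end > lengths[g.scaffold_id]:
            continue
        key = (g.scaffold_id, start, end)
        if key in true_coords or any(start == s or end == e
                                     for sc, s, e in true_coords if sc == g.scaffold_id):
            continue
        records.append(JunctionRecord(g.scaffold_id, start, end, g.strand,
                                      1 + int(rng.poisson(0.5))))
        made += 1
    if path is not None:
        write_junctions(records, path)
    return records


def emit_sl_reads(
    truth: TruthSet,
    strain: str,
    n_reads: int | None = None,
    error_rate: float | None = None,
    seed: int | None = None,
    path=None,
) -> dict[str, str]:
    """SL-tagged reads for one strain's trans-spliced genes.

    Each read is a sampled suffix (5-22 nt) of the SL followed by the
    transcript 5' sequence from the true junction (the gene's first
    transcribed base); the genomic part never crosses the first intron
    because the 5' UTR is at least as long.  Truth junctions are recorded
    on the TruthSet.
    """
    cfg = truth.config
    n_reads = cfg.n_sl_reads if n_reads is None else n_reads
    error_rate = cfg.read_error_rate if error_rate is None else error_rate
    rng = np.random.default_rng(cfg.seed + 2000 if seed is None else seed)
    sl = cfg.sl_seq
    gene_by_id = {g.gene_id: g for g in truth.genes[strain]}
    seqs = {g.scaffold_id: g.sequence for g in truth.genomes[strain]}
    flagged = truth.trans_spliced[strain]
    reads: dict[str, str] = {}
    truth.sl_reads[strain] = []
    if not flagged:
        if path is not None:
            write_fasta_dict(reads, path)
        return reads
    for ri in range(n_reads):
        gid = flagged[int(rng.integers(len(flagged)))]
        g = gene_by_id[gid]
        suffix_len = int(rng.integers(5, len(sl) + 1))
        body_len = 60
        if g.strand == "+":
            jpos = g.utr5[0]
            body = seqs[g.scaffold_id][jpos - 1 : jpos - 1 + body_len]
        else:
            jpos = g.utr5[1]
            body = revcomp(seqs[g.scaffold_id][jpos - body_len : jpos])
        seq = sl[-suffix_len:] + body
        if error_rate > 0:
            chars = list(seq)
            for i in range(len(chars)):
                if rng.random() < error_rate:
                    chars[i] = str(rng.choice([b for b in BASES if b != chars[i]]))
            seq = "".join(chars)
        read_id = f"{strain}_slread{ri:05d}"
        reads[read_id] = seq
        truth.sl_reads[strain].append(SLReadTruth(
            read_id, strain, gid, g.scaffold_id, jpos, g.strand, suffix_len, seq))
    if path is not None:
        write_fasta_dict(reads, path)
    return reads


def truth_intron_table(truth: TruthSet, strain: str) -> pd.DataFrame:
    rows = [dict(intron_id=t.intron_id, gene=t.gene_id, klass=t.klass,
                 family=t.family_id, conserved=t.conserved, phase=t.phase,
                 cds_offset=t.cds_offset, arm5=t.arm5, dr=t.dr_seq, length=len(t.seq))
            for t in truth.introns[strain]]
    return pd.DataFrame(rows)
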