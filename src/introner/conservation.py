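"""Conserved vs strain-specific intron positions between orthologous genes.

Each intron is mapped onto the global protein alignment of its ortholog
pair at the column of the last amino acid encoded (wholly or partially) by
the upstream exon, together with its phase (coding nucleotides of the
interrupted codon preceding the intron).  An intron is conserved when the
two orthologs carry introns at the same alignment column, in the same
phase, inside a conserved (unmasked) block of the alignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import alignment_identity, global_align
from .introns import Intron
from .io import GeneModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntronPlacement:
    gene_id: str
    column: int  # 0-based alignment column of the upstream-exon last residue
    phase: int
    intron_id: str
    klass: str
    in_conserved_block: bool = True


def global_align_proteins(prot_a: str, prot_b: str, gap_open: int = 10, gap_extend: int = 1):
    """Global affine-gap protein alignment; returns (row_a, row_b, score)."""
    return global_align(prot_a, prot_b, gap_open, gap_extend)


def conserved_block_mask(
    row_a: str,
    row_b: str,
    window: int = 9,
    min_matches: int = 5,
    gap_margin: int = 5,
) -> np.ndarray:
    """Boolean mask of alignment columns inside conserved blocks.

    A column is retained iff it is non-gap in both rows, lies strictly more
    than ``gap_margin`` columns from any gap column, and its centered window
    of ``window`` columns (truncated at the alignment ends) contains at
    least ``min_matches`` identities.
    """
    n = len(row_a)
    is_gap = np.array([a == "-" or b == "-" for a, b in zip(row_a, row_b)])
    is_match = np.array([a == b and a != "-" for a, b in zip(row_a, row_b)])
    mask = np.zeros(n, dtype=bool)
    gap_cols = np.flatnonzero(is_gap)
    half = window // 2
    for c in range(n):
        if is_gap[c]:
            continue
        if gap_cols.size and np.min(np.abs(gap_cols - c)) <= gap_margin:
            continue
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if int(is_match[lo:hi].sum()) >= min_matches:
            mask[c] = True
    return mask


def _residue_to_column(row: str) -> list[int]:
    """1-based residue index -> 0-based alignment column for one row."""
    cols = []
    for i, ch in enumerate(row):
        if ch != "-":
            cols.append(i)
    return cols


def map_intron_placements(
    gene: GeneModel,
    introns: list[Intron],
    alignment_row: str,
    mask: np.ndarray | None = None,
) -> list[IntronPlacement]:
    """Map a gene's introns to alignment columns.

    The placement column is that of the last residue encoded wholly or
    partially by the upstream exon: residue ceil(cds_offset / 3), where
    cds_offset is the number of coding nucleotides before the intron; the
    phase is cds_offset mod 3.  Introns outside the CDS (e.g. in the 5'
    UTR) are skipped with a warning.
    """
    res_cols = _residue_to_column(alignment_row)
    out = []
    for intr in introns:
        offset = gene.cds_offset_of_intron(intr.start, intr.end)
        if offset is None or offset <= 0:
            logger.warning("intron %s outside CDS of %s, skipped", intr.intron_id, gene.gene_id)
            continue
        residue = math.ceil(offset / 3)  # 1-based
        if residue > len(res_cols):
            logger.warning("intron %s beyond protein of %s, skipped", intr.intron_id, gene.gene_id)
            continue
        col = res_cols[residue - 1]
        out.append(IntronPlacement(
            gene.gene_id, col, offset % 3, intr.intron_id, intr.klass,
            in_conserved_block=bool(mask[col]) if mask is not None else True,
        ))
    return out


def conserved_introns(
    placements_a: list[IntronPlacement],
    placements_b: list[IntronPlacement],
    mask: np.ndarray,
) -> tuple[list[tuple[IntronPlacement, IntronPlacement]], list[IntronPlacement], list[IntronPlacement], dict]:
    """Split placements into conserved pairs and strain-specific sets.

    Conserved = same alignment column, same phase, column unmasked.
    Placements in masked columns are excluded from every set and from all
    denominators.  The composition dict reports the canonical/NCI split of
    conserved and specific placements.
    """
    pa = [p for p in placements_a if mask[p.column]]
    pb = [p for p in placements_b if mask[p.column]]
    index_b = {(p.column, p.phase): p for p in pb}
    conserved, specific_a = [], []
    used_b = set()
    for p in pa:
        q = index_b.get((p.column, p.phase))
        if q is not None:
            conserved.append((p, q))
            used_b.add((q.column, q.phase))
        else:
            specific_a.append(p)
    specific_b = [p for p in pb if (p.column, p.phase) not in used_b]

    def comp(placements):
        c = sum(1 for p in placements if p.klass == "canonical")
        return dict(canonical=c, nci=len(placements) - c)

    composition = dict(
        conserved=comp([p for p, _ in conserved] + [q for _, q in conserved]),
        specific_a=comp(specific_a),
        specific_b=comp(specific_b),
    )
    return conserved, specific_a, specific_b, composition


def pair_conservation(
    gene_a: GeneModel,
    gene_b: GeneModel,
    prot_a: str,
    prot_b: str,
    introns_a: list[Intron],
    introns_b: list[Intron],
    min_unmasked: int = 50,
    mask_params: dict | None = None,
) -> dict | None:
    """Full conservation analysis of one ortholog pair.

    Returns None when fewer than ``min_unmasked`` columns survive masking
    (guard against spurious 0/0 statistics on hyper-diverged pairs).
    """
    row_a, row_b, _ = global_align_proteins(prot_a, prot_b)
    mask = conserved_block_mask(row_a, row_b, **(mask_params or {}))
    if int(mask.sum()) < min_unmasked:
        return None
    pa = map_intron_placements(gene_a, introns_a, row_a, mask)
    pb = map_intron_placements(gene_b, introns_b, row_b, mask)
    conserved, spec_a, spec_b, composition = conserved_introns(pa, pb, mask)
    n_a = len(conserved) + len(spec_a)
    n_b = len(conserved) + len(spec_b)
    return dict(
        gene_a=gene_a.gene_id, gene_b=gene_b.gene_id,
        identity=alignment_identity(row_a, row_b),
        n_conserved=len(conserved), n_specific_a=len(spec_a), n_specific_b=len(spec_b),
        conserved_frac_a=len(conserved) / n_a if n_a else float("nan"),
        conserved_frac_b=len(conserved) / n_b if n_b else float("nan"),
        unmasked_columns=int(mask.sum()),
        composition=composition,
    )


def conservation_vs_identity(pair_results: list[dict], bin_width: float = 0.05) -> pd.DataFrame:
    """Mean conserved fraction binned by protein identity (bin width 5%).

    Empty bins are reported with NaN means.
    """
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    rows = []
    values = [(r["identity"], r["conserved_frac_a"]) for r in pair_results
              if r is not None and not math.isnan(r["conserved_frac_a"])]
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = [f for ident, f in values if lo <= ident < hi or (hi == 1.0 and ident == 1.0)]
        rows.append(dict(identity_lo=round(lo, 2), identity_hi=round(hi, 2),
                         n_pairs=len(in_bin),
                         mean_conserved_frac=float(np.mean(in_bin)) if in_bin else float("nan")))
    return pd.DataFrame(rows)
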