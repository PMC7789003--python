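"""Pipeline driver: run requested analysis stages in dependency order over
one or two annotated strain genomes, writing TSV/JSON reports.

Every run logs its fully resolved configuration and per-stage input/output
counts, and is byte-reproducible given the same inputs, config and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import architecture, conservation, elements, introns as intron_mod, orthology, sl as sl_mod
from .io import PipelineConfig, load_annotated_genome, load_junctions, read_fasta_dict

logger = logging.getLogger(__name__)

STAGES = ("introns", "introners", "architecture", "orthology", "conservation", "sl")


def _intron_stage(strain: dict, cfg: PipelineConfig, outdir: Path, label: str) -> dict:
    genomes, genes = strain["genomes"], strain["genes"]
    junctions = load_junctions(strain["junctions"])
    validated = intron_mod.extract_validated_introns(
        junctions, genomes, genes, cfg.min_support, cfg.min_intron_len, cfg.max_intron_len)
    strain["introns"] = validated
    intron_mod.catalog_table(validated).to_csv(outdir / f"{label}.introns.tsv", sep="\t", index=False)
    table, matrices = intron_mod.splice_site_frequency(validated, genomes)
    table.to_csv(outdir / f"{label}.splice_dinucs.tsv", sep="\t")
    for key, m in matrices.items():
        m.to_csv(outdir / f"{label}.splice_freq_{key}.tsv", sep="\t")
    typing = intron_mod.gene_intron_typing(genes, validated)
    counts = pd.Series(typing).value_counts().to_dict()
    n = len(validated)
    canon = sum(1 for i in validated if i.klass == "canonical")
    return dict(n_junctions=len(junctions), n_validated=n,
                frac_canonical=canon / n if n else 0.0, gene_typing=counts)


def _introner_stage(strain: dict, cfg: PipelineConfig, outdir: Path, label: str) -> dict:
    validated = strain["introns"]
    seqs = {g.scaffold_id: g.sequence for g in strain["genomes"]}
    irs, drs = {}, {}
    for intr in validated:
        irs[intr.intron_id] = elements.find_inverted_repeats(
            intr.seq, cfg.ir_min_len, cfg.ir_max_len, cfg.ir_end_window, cfg.ir_min_loop)
        sc = seqs[intr.scaffold_id]
        if intr.strand == "+":
            e5 = sc[max(0, intr.start - 1 - cfg.dr_boundary_window) : intr.start - 1]
            e3 = sc[intr.end : intr.end + cfg.dr_boundary_window]
        else:
            from ._utils import revcomp
            e5 = revcomp(sc[intr.end : intr.end + cfg.dr_boundary_window])
            e3 = revcomp(sc[max(0, intr.start - 1 - cfg.dr_boundary_window) : intr.start - 1])
        drs[intr.intron_id] = elements.find_direct_repeats(
            e5, intr.seq, e3, cfg.dr_min_len, cfg.dr_max_len, cfg.dr_boundary_window)
    candidates, flagged, counts = elements.call_introners(validated, irs, drs)
    families, singletons = elements.cluster_families(candidates, cfg.min_intron_identity)
    background = elements.catalog_background(validated)
    for fam in families:
        elements.build_family_profile(fam, background, cfg.profile_flank, cfg.profile_pseudocount)
    repeated = elements.scan_for_family_members(families, validated)
    pairs = elements.find_identical_ie_pairs(candidates)
    result = dict(n_candidates=len(candidates), n_canonical_with_ir=len(flagged),
                  n_families=len(families), n_singletons=len(singletons),
                  n_repeated_introns=len(repeated), n_identical_pairs=len(pairs),
                  call_counts=counts)
    if len(families) >= 2:
        k = min(cfg.n_superfamilies, len(families))
        _, newick = elements.cluster_superfamilies(families, k)
        (outdir / f"{label}.families.nwk").write_text(newick)
    elements.ie_table(candidates, families).to_csv(outdir / f"{label}.ies.tsv", sep="\t", index=False)
    pd.DataFrame(pairs, columns=["ie_1", "ie_2"]).to_csv(
        outdir / f"{label}.identical_pairs.tsv", sep="\t", index=False)
    strain["families"] = families
    strain["ies"] = candidates
    return result


def _architecture_stage(strain: dict, cfg: PipelineConfig, outdir: Path, label: str) -> dict:
    genes = strain["genes"]
    per_sc, mean_rate = architecture.orientation_change_rate(genes, cfg.orientation_window)
    blocks, frac = architecture.coorient_blocks(genes)
    architecture.blocks_table(blocks).to_csv(outdir / f"{label}.blocks.tsv", sep="\t", index=False)
    tandems = architecture.tandem_duplication_clusters(
        strain["proteins"], genes, cfg.tandem_min_identity, cfg.tandem_min_cov)
    telo = architecture.telomere_scan(strain["genomes"],
                                      terminal_window=cfg.telomere_window,
                                      min_copies=cfg.telomere_min_copies)
    return dict(orientation_shift=mean_rate, n_blocks=len(blocks),
                frac_genes_in_blocks=frac, n_tandem_clusters=len(tandems),
                n_tandem_genes=sum(len(t.gene_ids) for t in tandems),
                n_telomeric_ends=sum(telo.values()))


def run_pipeline(config: dict | str | Path, outdir=None) -> dict:
    """Execute the requested stages over the configured strain inputs.

    ``config`` is a dict (or path to a YAML file) with keys: ``stages`` (list
    drawn from introns/introners/architecture/orthology/conservation/sl),
    ``outdir``, ``params`` (PipelineConfig overrides) and per-strain input
    blocks ``strain_a``/``strain_b`` with ``fasta``, ``gff3`` and optionally
    ``junctions``, ``proteins``, ``reads`` paths.  Two-genome stages
    (orthology, conservation) require both strains.  Returns the JSON-ready
    summary, also written to ``summary.json``.
    """
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    stages = config.get("stages", list(STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid stages: {list(STAGES)}")
    outdir = Path(outdir or config.get("outdir", "introner_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(**config.get("params", {}))

    strains = {}
    for label in ("strain_a", "strain_b"):
        if label not in config:
            continue
        block = config[label]
        genomes, genes = load_annotated_genome(block["fasta"], block["gff3"])
        strains[label] = dict(genomes=genomes, genes=genes,
                              junctions=block.get("junctions"),
                              reads=block.get("reads"))
        strains[label]["proteins"] = (
            read_fasta_dict(block["proteins"]) if block.get("proteins")
            else {g.gene_id: g.protein({x.scaffold_id: x.sequence for x in genomes}[g.scaffold_id])
                  for g in genes})
    if not strains:
        raise ValueError("no strain inputs configured")

    summary = {"config": cfg.to_dict(), "stages": {}}
    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        try:
            if stage == "introns":
                summary["stages"][stage] = {
                    label: _intron_stage(s, cfg, outdir, label) for label, s in strains.items()
                    if s["junctions"]}
            elif stage == "introners":
                if not all("introns" in s for s in strains.values()):
                    raise RuntimeError("introners stage requires the introns stage")
                summary["stages"][stage] = {
                    label: _introner_stage(s, cfg, outdir, label) for label, s in strains.items()}
            elif stage == "architecture":
                summary["stages"][stage] = {
                    label: _architecture_stage(s, cfg, outdir, label)
                    for label, s in strains.items()}
            elif stage == "orthology":
                sa, sb = strains["strain_a"], strains["strain_b"]
                ab, ba = orthology.all_vs_all_hits(sa["proteins"], sb["proteins"],
                                                   cfg.min_align_score,
                                                   cfg.align_gap_open, cfg.align_gap_extend)
                pairs = orthology.best_reciprocal_hits(ab, ba, sa["proteins"], sb["proteins"])
                blocks, dotplot, metrics = orthology.synteny_blocks(
                    pairs, sa["genes"], sb["genes"], cfg.synteny_min_anchors, cfg.synteny_max_gap)
                stats, _ = orthology.identity_distribution(pairs)
                orthology.ortholog_table(pairs).to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
                dotplot.to_csv(outdir / "dotplot.tsv", sep="\t", index=False)
                strains["_pairs"] = pairs
                summary["stages"][stage] = dict(n_pairs=len(pairs), identity=stats, **metrics)
            elif stage == "conservation":
                pairs = strains.get("_pairs")
                if pairs is None:
                    raise RuntimeError("conservation stage requires the orthology stage")
                sa, sb = strains["strain_a"], strains["strain_b"]
                ia = {g: [] for g in sa["proteins"]}
                for i in sa["introns"]:
                    if i.host_gene:
                        ia.setdefault(i.host_gene, []).append(i)
                ib = {g: [] for g in sb["proteins"]}
                for i in sb["introns"]:
                    if i.host_gene:
                        ib.setdefault(i.host_gene, []).append(i)
                ga = {g.gene_id: g for g in sa["genes"]}
                gb = {g.gene_id: g for g in sb["genes"]}
                mask_params = dict(window=cfg.mask_window, min_matches=cfg.mask_min_matches,
                                   gap_margin=cfg.mask_gap_margin)
                results = [conservation.pair_conservation(
                    ga[p.gene_a], gb[p.gene_b], sa["proteins"][p.gene_a], sb["proteins"][p.gene_b],
                    ia.get(p.gene_a, []), ib.get(p.gene_b, []), mask_params=mask_params)
                    for p in pairs]
                results = [r for r in results if r is not None]
                trend = conservation.conservation_vs_identity(results)
                trend.to_csv(outdir / "conservation_trend.tsv", sep="\t", index=False)
                tot_c = sum(r["n_conserved"] for r in results)
                tot_a = sum(r["n_conserved"] + r["n_specific_a"] for r in results)
                summary["stages"][stage] = dict(
                    n_pairs_analyzed=len(results), total_conserved=tot_c,
                    conserved_fraction_a=tot_c / tot_a if tot_a else 0.0)
            elif stage == "sl":
                out = {}
                for label, s in strains.items():
                    if label.startswith("_") or not s.get("reads"):
                        continue
                    reads = read_fasta_dict(s["reads"])
                    cands = sl_mod.find_sl_reads(reads, cfg.sl_seq, cfg.sl_kmer)
                    junctions = [sl_mod.locate_sl_junction(c, s["genomes"], cfg.sl_seq,
                                                           cfg.sl_max_extension) for c in cands]
                    junctions = [sl_mod.assign_sl_to_gene(j, s["genes"])
                                 for j in junctions if j is not None]
                    sl_mod.junction_table(junctions).to_csv(
                        outdir / f"{label}.sl_junctions.tsv", sep="\t", index=False)
                    out[label] = dict(n_reads=len(reads), n_candidates=len(cands),
                                      n_junctions=len(junctions))
                summary["stages"][stage] = out
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    strains.pop("_pairs", None)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    return summary
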