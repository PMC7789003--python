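import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from introner.io import load_annotated_genome, load_junctions
from introner.simulate import (SimConfig, emit_genome_files, emit_junctions,
                               emit_sl_reads, simulate_truth)
from introner import introns as intron_mod


@pytest.fixture(scope="session")
def default_truth():
    """The default two-strain synthetic genome (2 x 200 genes, 5 IE families,
    30% IE introns), shared across the suite."""
    return simulate_truth(SimConfig(seed=7))


@pytest.fixture(scope="session")
def emitted(default_truth, tmp_path_factory):
    """Emitted FASTA/GFF3/junctions/reads for both strains, reloaded through
    the package's own readers."""
    outdir = tmp_path_factory.mktemp("sim")
    paths = emit_genome_files(default_truth, outdir)
    data = {}
    for strain in "AB":
        jpath = outdir / f"{strain}.junctions.tsv"
        emit_junctions(default_truth, strain, path=jpath)
        rpath = outdir / f"{strain}.sl_reads.fasta"
        emit_sl_reads(default_truth, strain, path=rpath)
        genomes, genes = load_annotated_genome(paths[strain]["fasta"], paths[strain]["gff3"])
        data[strain] = dict(genomes=genomes, genes=genes,
                            junctions=load_junctions(jpath),
                            paths=dict(paths[strain], junctions=jpath, reads=rpath))
    return data


@pytest.fixture(scope="session")
def catalog_a(default_truth, emitted):
    """Validated intron catalog of strain A."""
    d = emitted["A"]
    return intron_mod.extract_validated_introns(d["junctions"], d["genomes"], d["genes"])
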