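"""Shared fixtures: handcrafted toy genomes and session-scoped synthetic data."""

import pytest

from readthru import extraction, synthetic_data as sd
from readthru.extraction import StopContext

#: default rejection plan exercising every reachable filter
REJECT_PLAN = {
    "short-intergenic": 0.02,
    "length-not-multiple-of-3": 0.02,
    "no-valid-stop": 0.01,
    "internal-stop": 0.02,
    "non-ACGT": 0.02,
}


def make_context(
    downstream: str = "",
    stop: str = "TAA",
    gene_id: str = "g1",
    abundance: float | None = None,
    upstream: str | None = None,
    intergenic: int = 200,
) -> StopContext:
    """Build a StopContext, padding the downstream UTR to 97 nt with C
    (CCC is never a stop triplet)."""
    downstream = (downstream + "C" * 97)[:97]
    return StopContext(
        gene_id=gene_id,
        primary_stop=stop,
        upstream_cds=upstream or "ACG" * 10,
        downstream_utr=downstream,
        intergenic_3prime=intergenic,
        abundance=abundance,
    )


@pytest.fixture(scope="session")
def small_genome():
    """A 400-gene synthetic genome with planned filter failures, plus its
    extracted contexts."""
    cfg = sd.GenomeSimConfig(n_genes=400, seed=0, reject_plan=dict(REJECT_PLAN))
    genome, expression, truth = sd.build_genome(cfg)
    contexts, report = extraction.extract_stop_contexts(genome, expression)
    return {
        "config": cfg,
        "genome": genome,
        "expression": expression,
        "truth": truth,
        "contexts": contexts,
        "report": report,
    }


@pytest.fixture()
def toy_genome_files(tmp_path):
    """A two-contig, three-gene toy genome written to FASTA + GFF3."""
    # ctg1: plus-strand gene, CDS 1..9 = ATGAAATAA, then 200+ bp of space
    ctg1 = "ATGAAATAA" + "C" * 300
    # ctg2: minus-strand gene occupying the reverse complement of
    # ATGAAATGA placed at the far end, plus a CDS-less gene feature
    ctg2 = "G" * 300 + "TCATTTCAT"
    fasta = tmp_path / "toy.fasta"
    fasta.write_text(f">ctg1\n{ctg1}\n>ctg2\n{ctg2}\n")
    gff = tmp_path / "toy.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "ctg1\ttoy\tgene\t1\t9\t.\t+\t.\tID=gplus\n"
        "ctg1\ttoy\tmRNA\t1\t9\t.\t+\t.\tID=gplus.t1;Parent=gplus\n"
        "ctg1\ttoy\tCDS\t1\t9\t.\t+\t0\tID=gplus.c1;Parent=gplus.t1\n"
        "ctg2\ttoy\tgene\t301\t309\t.\t-\t.\tID=gminus\n"
        "ctg2\ttoy\tmRNA\t301\t309\t.\t-\t.\tID=gminus.t1;Parent=gminus\n"
        "ctg2\ttoy\tCDS\t301\t309\t.\t-\t0\tID=gminus.c1;Parent=gminus.t1\n"
        "ctg2\ttoy\tgene\t1\t50\t.\t+\t.\tID=gnocds\n"
    )
    return fasta, gff
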