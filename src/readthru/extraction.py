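"""Stop-codon context extraction with quality filters.

For every protein-coding gene we keep a 130-nt window centred on
termination: the last 10 codons of the CDS (30 nt), the primary stop
(positions +1..+3) and 97 nt of 3'-UTR (positions +4..+100). Genes are
retained only if they have >100 bp of 3' intergenic space, a CDS length
that is a multiple of 3, a single in-frame stop located terminally, and
a window made up exclusively of A, C, G and T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TGA", "TAG")

#: Rejection reasons in the precedence order used to attribute a single
#: reason per gene when several rules fail at once. The retained set is
#: independent of this order; only the bookkeeping needs a tie-break.
REJECTION_REASONS = (
    "short-intergenic",
    "length-not-multiple-of-3",
    "no-valid-stop",
    "internal-stop",
    "truncated-context",
    "non-ACGT",
)

UPSTREAM_NT = 30
DOWNSTREAM_NT = 97


@dataclass
class StopContext:
    """One gene's termination context.

    ``upstream_cds``: last 30 CDS nt before the stop. ``downstream_utr``:
    97 nt at positions +4..+100, the stop occupying +1..+3.
    """

    gene_id: str
    primary_stop: str
    upstream_cds: str
    downstream_utr: str
    intergenic_3prime: int
    abundance: float | None = None

    def __post_init__(self) -> None:
        if self.primary_stop not in STOP_CODONS:
            raise ValueError(f"{self.gene_id}: primary stop {self.primary_stop!r}")
        if len(self.upstream_cds) != UPSTREAM_NT:
            raise ValueError(f"{self.gene_id}: upstream length {len(self.upstream_cds)}")
        if len(self.downstream_utr) != DOWNSTREAM_NT:
            raise ValueError(f"{self.gene_id}: downstream length {len(self.downstream_utr)}")
        window = self.upstream_cds + self.primary_stop + self.downstream_utr
        if set(window) - set("ACGT"):
            raise ValueError(f"{self.gene_id}: non-ACGT characters in context")

    def site(self, pos: int) -> str:
        """Nucleotide at a stop-anchored site (-30..-1, +1..+100; no 0)."""
        if -UPSTREAM_NT <= pos <= -1:
            return self.upstream_cds[UPSTREAM_NT + pos]
        if 1 <= pos <= 3:
            return self.primary_stop[pos - 1]
        if 4 <= pos <= 3 + DOWNSTREAM_NT:
            return self.downstream_utr[pos - 4]
        raise IndexError(f"site {pos} outside context window")


@dataclass
class FilterReport:
    """Per-reason rejection counts; retained + sum(rejections) = input genes."""

    n_input: int = 0
    retained: int = 0
    rejections: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REJECTION_REASONS}
    )

    def check(self) -> None:
        assert self.retained + sum(self.rejections.values()) == self.n_input


def intergenic_3prime_distance(gene, genome) -> int:
    """Distance (bp) from the base after the gene's stop, in transcription
    direction, to the nearest boundary of any other annotated gene on
    either strand of the same contig; falls back to the contig end.
    """
    contig_len = len(genome.contigs[gene.contig])
    others = [g for g in genome.genes if g.contig == gene.contig and g.gene_id != gene.gene_id]
    if gene.strand == "+":
        stop_end = gene.span[1]  # first position after the stop
        dist = contig_len - stop_end
        for other in others:
            s, e = other.span
            if e <= stop_end:
                continue
            dist = min(dist, max(s - stop_end, 0))
    else:
        stop_start = gene.span[0]  # stop occupies the first bases of the span
        dist = stop_start
        for other in others:
            s, e = other.span
            if s >= stop_start:
                continue
            dist = min(dist, max(stop_start - e, 0))
    return dist


def _window_sequences(gene, genome) -> tuple[str, str] | None:
    """(upstream 30 nt of spliced CDS minus stop, downstream 97 genomic nt)
    or None if the downstream window runs off the contig."""
    contig_seq = genome.contigs[gene.contig]
    cds = gene.coding_sequence
    upstream = cds[-33:-3]
    if gene.strand == "+":
        stop_end = gene.span[1]
        if stop_end + DOWNSTREAM_NT > len(contig_seq):
            return None
        downstream = contig_seq[stop_end : stop_end + DOWNSTREAM_NT]
    else:
        stop_start = gene.span[0]
        if stop_start - DOWNSTREAM_NT < 0:
            return None
        downstream = str(
            Seq(contig_seq[stop_start - DOWNSTREAM_NT : stop_start]).reverse_complement()
        )
    return upstream, downstream


def extract_stop_contexts(
    genome,
    expression=None,
    min_intergenic: int = 100,
) -> tuple[list[StopContext], FilterReport]:
    """Apply the quality filters and build :class:`StopContext` records.

    Retention requires: 3' intergenic space strictly greater than
    ``min_intergenic``; CDS length a multiple of 3; terminal codon in
    {TAA, TGA, TAG}; no in-frame stop after the initiator other than the
    terminal one; the 130-nt window entirely on the contig and made of
    A/C/G/T only. Rejections are tallied in the returned
    :class:`FilterReport` (one reason per gene, fixed precedence).
    """
    contexts: list[StopContext] = []
    report = FilterReport(n_input=len(genome.genes))
    for gene in genome.genes:
        reason = _classify(gene, genome, min_intergenic)
        if reason is not None:
            report.rejections[reason] += 1
            continue
        upstream, downstream = _window_sequences(gene, genome)
        abundance = expression.get(gene.gene_id) if expression is not None else None
        contexts.append(
            StopContext(
                gene_id=gene.gene_id,
                primary_stop=gene.coding_sequence[-3:],
                upstream_cds=upstream,
                downstream_utr=downstream,
                intergenic_3prime=intergenic_3prime_distance(gene, genome),
                abundance=abundance,
            )
        )
        report.retained += 1
    report.check()
    return contexts, report


def _classify(gene, genome, min_intergenic: int) -> str | None:
    """Rejection reason for ``gene`` or None if retained."""
    if intergenic_3prime_distance(gene, genome) <= min_intergenic:
        return "short-intergenic"
    cds = gene.coding_sequence
    if len(cds) % 3 != 0 or len(cds) < 36:  # need 10 codons + stop + initiator
        return "length-not-multiple-of-3"
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] not in STOP_CODONS:
        return "no-valid-stop"
    if any(c in STOP_CODONS for c in codons[1:-1]):
        return "internal-stop"
    pair = _window_sequences(gene, genome)
    if pair is None:
        return "truncated-context"
    upstream, downstream = pair
    if set(upstream + cds[-3:] + downstream) - set("ACGT"):
        return "non-ACGT"
    return None


def partition_heg_leg(
    contexts: list[StopContext], min_genes: int = 400
) -> tuple[list[StopContext], list[StopContext]]:
    """Split contexts into highly/lowly expressed gene sets.

    HEG = top quartile by protein abundance, LEG = bottom quartile; both
    of size floor(n/4). Ties are broken by descending abundance then
    ascending gene id. Fewer than ``min_genes`` contexts with abundance
    refuses with ValueError (species-inclusion threshold).
    """
    scored = [c for c in contexts if c.abundance is not None]
    if len(scored) < min_genes:
        raise ValueError(
            f"only {len(scored)} genes with abundance; need >= {min_genes}"
        )
    if len({c.abundance for c in scored}) == 1:
        logger.warning("partition_heg_leg: all abundances equal; id-ordered split")
    ranked = sorted(scored, key=lambda c: (-c.abundance, c.gene_id))
    q = len(ranked) // 4
    return ranked[:q], ranked[len(ranked) - q :]
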