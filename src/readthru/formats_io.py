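"""Readers and writers for the standard formats the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`GenomeData` (contigs + gene models), :class:`ExpressionTable`
(per-gene protein abundance in ppm), phylogenies (dendropy trees) and
aligned three-taxon ortholog records.

Coordinate convention: internal coordinates are 0-based half-open;
GFF3's 1-based inclusive coordinates are converted at the parse
boundary, and converted back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .triplet_substitutions import TripletAlignment

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
STOP_CODONS = ("TAA", "TGA", "TAG")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ConsistencyError(ValueError):
    """Raised when cross-file references do not resolve (e.g. a CDS on a
    contig absent from the FASTA)."""


@dataclass
class GeneModel:
    """A protein-coding gene reduced to its CDS.

    ``cds_parts`` are 0-based half-open intervals in contig coordinates,
    sorted by start and non-overlapping. ``coding_sequence`` is the
    spliced, strand-oriented CDS including the terminal stop codon (for
    minus-strand genes it is the reverse complement of the concatenated
    contig slices).
    """

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    cds_parts: list[tuple[int, int]]
    coding_sequence: str

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent (min start, max end) of the CDS."""
        return self.cds_parts[0][0], self.cds_parts[-1][1]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        parts = sorted(self.cds_parts)
        for (s0, e0), (s1, e1) in zip(parts, parts[1:]):
            if e0 > s1:
                raise ValueError(f"overlapping CDS parts in {self.gene_id}")
        self.cds_parts = parts
        total = sum(e - s for s, e in parts)
        if total != len(self.coding_sequence):
            raise ValueError(
                f"{self.gene_id}: CDS length {len(self.coding_sequence)} != "
                f"sum of interval lengths {total}"
            )


@dataclass
class GenomeData:
    """A genome: contig sequences plus gene models referencing them."""

    contigs: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.contigs = {k: v.upper() for k, v in self.contigs.items()}
        for name, seq in self.contigs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name}: ambiguity codes other than N not "
                    f"accepted: {sorted(bad)}"
                )
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ConsistencyError(
                    f"gene {g.gene_id} references missing contig {g.contig}"
                )

    def genes_by_contig(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.contig, []).append(g)
        return out


def _spliced_cds(contig_seq: str, parts: Sequence[tuple[int, int]], strand: str) -> str:
    chunks = [contig_seq[s:e] for s, e in sorted(parts)]
    seq = "".join(chunks)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def read_genome(fasta_path: str | Path, gff3_path: str | Path) -> GenomeData:
    """Parse a genome FASTA plus GFF3 annotation into :class:`GenomeData`.

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open. Minus-strand coding sequences are reverse complemented and
    exon-ordered 5'->3'. Where a gene has several annotated transcripts
    the longest CDS is taken (ties broken by lexicographically smallest
    transcript id). Genes lacking CDS features are skipped with a logged
    count.
    """
    fasta_path, gff3_path = Path(fasta_path), Path(gff3_path)
    try:
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    except Exception as exc:  # Bio raises assorted ValueErrors
        raise FormatError(f"malformed FASTA {fasta_path}: {exc}") from exc
    if not contigs:
        raise FormatError(f"no records in FASTA {fasta_path}")

    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise FormatError(f"malformed GFF3 {gff3_path}: {exc}") from exc

    genes: list[GeneModel] = []
    n_skipped = 0
    for gene in db.features_of_type("gene"):
        # Collect candidate transcripts; tolerate CDS attached directly
        # to the gene (no mRNA level).
        candidates: dict[str, list] = {}
        for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
            cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
            if cds:
                candidates[mrna.id] = cds
        direct = list(db.children(gene, featuretype="CDS", level=1, order_by="start"))
        if direct:
            candidates.setdefault(gene.id, direct)
        if not candidates:
            n_skipped += 1
            continue
        # Longest CDS; tie-break lexicographically smallest transcript id.
        best_id = min(
            candidates,
            key=lambda t: (-sum(f.end - f.start + 1 for f in candidates[t]), t),
        )
        cds_feats = candidates[best_id]
        contig_id = cds_feats[0].seqid
        if contig_id not in contigs:
            raise ConsistencyError(
                f"gene {gene.id}: CDS references unknown contig {contig_id}"
            )
        strand = cds_feats[0].strand
        if strand not in "+-":
            raise FormatError(f"gene {gene.id}: CDS without strand")
        parts = [(f.start - 1, f.end) for f in cds_feats]  # to 0-based half-open
        coding = _spliced_cds(contigs[contig_id], parts, strand)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=contig_id,
                strand=strand,
                cds_parts=parts,
                coding_sequence=coding,
            )
        )
    if n_skipped:
        logger.info("read_genome: skipped %d genes lacking CDS features", n_skipped)
    return GenomeData(contigs=contigs, genes=genes)


def write_genome(genome: GenomeData, fasta_path: str | Path, gff3_path: str | Path) -> None:
    """Write ``genome`` back to FASTA + GFF3 (gene/mRNA/CDS hierarchy)."""
    with open(fasta_path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            start, end = g.span
            row = [g.contig, "readthru", ".", str(start + 1), str(end), ".", g.strand, "."]
            fh.write("\t".join(row[:2] + ["gene"] + row[3:] + [f"ID={g.gene_id}"]) + "\n")
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                "\t".join(row[:2] + ["mRNA"] + row[3:] + [f"ID={mrna_id};Parent={g.gene_id}"])
                + "\n"
            )
            for i, (s, e) in enumerate(g.cds_parts):
                fh.write(
                    "\t".join(
                        [
                            g.contig,
                            "readthru",
                            "CDS",
                            str(s + 1),
                            str(e),
                            ".",
                            g.strand,
                            "0",
                            f"ID={g.gene_id}.cds{i};Parent={mrna_id}",
                        ]
                    )
                    + "\n"
                )


class ExpressionTable(dict):
    """Mapping gene-id -> protein abundance (ppm, non-negative)."""


def read_expression(tsv_path: str | Path) -> ExpressionTable:
    """Read a two-column (gene id, abundance) TSV; header row optional.

    Duplicate ids and non-numeric abundances raise :class:`FormatError`.
    """
    table = ExpressionTable()
    with open(tsv_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{tsv_path}:{lineno}: expected 2 columns")
            gene_id, val = fields[0], fields[1]
            try:
                abundance = float(val)
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise FormatError(
                    f"{tsv_path}:{lineno}: non-numeric abundance {val!r}"
                ) from None
            if abundance < 0:
                raise FormatError(f"{tsv_path}:{lineno}: negative abundance")
            if gene_id in table:
                raise FormatError(f"{tsv_path}:{lineno}: duplicate gene id {gene_id}")
            table[gene_id] = abundance
    if not table:
        logger.warning("read_expression: %s is empty", tsv_path)
    return table


def read_tree(
    path: str | Path, default_branch_length: float | None = None
) -> dendropy.Tree:
    """Read a rooted phylogeny from Newick or NEXUS.

    Tips must carry unique labels. Edges missing a length raise unless
    ``default_branch_length`` is given, in which case it is substituted
    (logged). Polytomies are allowed.
    """
    path = Path(path)
    tree = None
    last_exc: Exception | None = None
    for schema in ("nexus", "newick") if path.suffix.lower() in {".nex", ".nexus"} else ("newick", "nexus"):
        try:
            tree = dendropy.Tree.get(path=str(path), schema=schema)
            break
        except Exception as exc:
            last_exc = exc
    if tree is None:
        raise FormatError(f"could not parse tree {path}: {last_exc}")

    labels = [t.label for t in tree.taxon_namespace]
    if any(lbl is None or lbl == "" for lbl in labels):
        raise FormatError(f"{path}: unlabeled tip")
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate tip label")
    n_defaulted = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            if default_branch_length is None:
                raise FormatError(f"{path}: edge missing branch length")
            edge.length = default_branch_length
            n_defaulted += 1
        elif edge.length < 0:
            raise FormatError(f"{path}: negative branch length")
    if n_defaulted:
        logger.info("read_tree: defaulted %d branch lengths to %s", n_defaulted, default_branch_length)
    return tree


def read_triplets(
    aligned_fasta_paths: Sequence[str | Path],
    role_map: Mapping[str, str],
) -> list[TripletAlignment]:
    """Read aligned three-taxon ortholog files.

    Each file must hold exactly three equal-length aligned records; the
    gap character is ``-``. ``role_map`` maps a header token (the first
    whitespace-separated word of the record id) to one of ``ingroup1``,
    ``ingroup2`` or ``outgroup``. Case is preserved: coding sequence is
    expected uppercase and 3'-UTR lowercase (soft-masking convention),
    which is how the stop codon is located downstream.
    """
    roles_needed = {"ingroup1", "ingroup2", "outgroup"}
    triplets: list[TripletAlignment] = []
    for p in aligned_fasta_paths:
        records = list(SeqIO.parse(str(p), "fasta"))
        if len(records) != 3:
            raise FormatError(f"{p}: expected 3 records, found {len(records)}")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise FormatError(f"{p}: aligned records of unequal length")
        seqs: dict[str, str] = {}
        for rec in records:
            token = rec.id.split()[0]
            role = role_map.get(token)
            if role is None:
                raise FormatError(f"{p}: header token {token!r} not in role map")
            if role in seqs:
                raise FormatError(f"{p}: role {role} assigned twice")
            seqs[role] = str(rec.seq)
        if set(seqs) != roles_needed:
            raise FormatError(f"{p}: roles {sorted(seqs)} != {sorted(roles_needed)}")
        triplets.append(TripletAlignment(seqs=seqs, name=Path(p).stem))
    return triplets
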