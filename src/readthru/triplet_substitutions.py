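"""Parsimony substitution profiling on three-taxon ortholog alignments.

Two sister ingroup species plus one outgroup allow ancestral bases to be
fixed wherever the outgroup base matches at least one ingroup; ingroup
bases that then differ from the ancestor count as lineage substitutions.
Per-site substitution frequencies over a window spanning ten codons
upstream of the stop to ten "codons" downstream quantify how selective
constraint decays with distance from the termination site.

Alignments follow the soft-masking convention: coding sequence (through
the terminal stop) uppercase, 3'-UTR lowercase, gaps ``-``. The stop
codon is located as the last three uppercase characters of each row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TGA", "TAG")
ROLES = ("ingroup1", "ingroup2", "outgroup")
GAP = "-"

#: Window sites around the stop: -30..-1 upstream CDS nucleotides,
#: +1..+3 the stop itself, +4..+33 the first ten downstream "codons".
WINDOW_SITES = tuple(range(-30, 0)) + tuple(range(1, 34))


@dataclass
class TripletAlignment:
    """An aligned ingroup1/ingroup2/outgroup ortholog triplet."""

    seqs: dict[str, str]
    name: str = ""
    shared_stop: str | None = None  # set by filter_triplet on pass
    stop_column: int | None = None  # alignment column of the stop's first base

    def __post_init__(self) -> None:
        if set(self.seqs) != set(ROLES):
            raise ValueError(f"triplet roles must be {ROLES}, got {sorted(self.seqs)}")
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise ValueError("aligned records of unequal length")

    def __len__(self) -> int:
        return len(self.seqs["ingroup1"])


def _ungapped_cds(aligned: str) -> str:
    """Ungapped uppercase (CDS) portion of one aligned row."""
    return "".join(c for c in aligned if c.isupper() and c != GAP)


def _stop_first_base_column(aligned: str) -> int | None:
    """Alignment column holding the first base of the terminal stop codon."""
    upper_cols = [i for i, c in enumerate(aligned) if c.isupper() and c != GAP]
    if len(upper_cols) < 3:
        return None
    return upper_cols[-3]


def filter_triplet(triplet: TripletAlignment, gap_free_codons: int = 10) -> str:
    """Quality-filter one triplet; returns ``"pass"`` or a rejection reason.

    A triplet passes iff, for every row: the ungapped CDS length is a
    multiple of 3, it carries no premature in-frame stop, and terminates
    in TAA/TGA/TAG; additionally all three stops must be identical, the
    stop codons must occupy the same alignment columns, and no gap may
    occur within ``gap_free_codons`` codons (30 columns) upstream or
    downstream of the stop. On pass, ``shared_stop`` and ``stop_column``
    are filled in.
    """
    stops = []
    stop_cols = []
    for role in ROLES:
        aligned = triplet.seqs[role]
        cds = _ungapped_cds(aligned)
        if len(cds) % 3 != 0 or len(cds) < 6:
            return "length-not-multiple-of-3"
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons[-1] not in STOP_CODONS:
            return "no-valid-stop"
        if any(c in STOP_CODONS for c in codons[:-1]):
            return "premature-stop"
        stops.append(codons[-1])
        stop_cols.append(_stop_first_base_column(aligned))
    if len(set(stops)) != 1:
        return "stop-disagreement"
    if len(set(stop_cols)) != 1 or stop_cols[0] is None:
        return "stop-misaligned"
    col = stop_cols[0]
    w = 30
    lo, hi = col - w, col + 3 + w
    if lo < 0 or hi > len(triplet):
        return "window-out-of-alignment"
    for role in ROLES:
        if GAP in triplet.seqs[role][lo:hi]:
            return "gap-near-stop"
    triplet.shared_stop = stops[0]
    triplet.stop_column = col
    return "pass"


def infer_ancestor(column: tuple[str, str, str]) -> str | None:
    """Outgroup-parsimony ancestral base for one (in1, in2, out) column.

    The ancestor of the ingroup pair is the outgroup base when it matches
    at least one ingroup; otherwise the site is unresolved (``None``).
    Columns containing gaps or non-ACGT characters are unresolved.
    """
    in1, in2, out = (b.upper() for b in column)
    if any(b not in "ACGT" for b in (in1, in2, out)):
        return None
    if out == in1 or out == in2:
        return out
    return None


def _site_to_column(site: int, stop_column: int) -> int:
    """Map a window site (-30..-1, +1..+33; no site 0) to an alignment column."""
    if site < 0:
        return stop_column + site
    return stop_column + site - 1


@dataclass
class SubstitutionProfile:
    """Per-site substitution frequencies per stop class.

    ``table`` columns: stop_class, site, numerator (substitutions summed
    over both ingroup lineages), denominator (2 x genes resolved at that
    site), frequency. ``valid_genes`` counts passing triplets per class.
    """

    table: pd.DataFrame
    valid_genes: dict[str, int] = field(default_factory=dict)


def substitution_profile(
    triplets: list[TripletAlignment], window_codons: int = 10
) -> SubstitutionProfile:
    """Build per-site substitution frequency profiles around the stop.

    Only triplets for which :func:`filter_triplet` passes contribute.
    For each window site, substitutions are counted on both ingroup
    lineages against the parsimony ancestor; sites with an unresolved
    ancestor (or any gap) are excluded from numerator and denominator at
    that site. Frequency = count / (2 x resolved genes of that class),
    i.e. a per-lineage rate.
    """
    sites = tuple(s for s in WINDOW_SITES if abs(s) <= 3 * window_codons or (0 < s <= 3 + 3 * window_codons))
    num: dict[str, dict[int, int]] = {s: {site: 0 for site in sites} for s in STOP_CODONS}
    den: dict[str, dict[int, int]] = {s: {site: 0 for site in sites} for s in STOP_CODONS}
    valid: dict[str, int] = {s: 0 for s in STOP_CODONS}

    for trip in triplets:
        if trip.shared_stop is None:
            if filter_triplet(trip) != "pass":
                continue
        stop = trip.shared_stop
        assert trip.stop_column is not None
        valid[stop] += 1
        s1, s2, so = (trip.seqs[r] for r in ROLES)
        for site in sites:
            col = _site_to_column(site, trip.stop_column)
            if col < 0 or col >= len(trip):
                continue
            column = (s1[col], s2[col], so[col])
            anc = infer_ancestor(column)
            if anc is None:
                continue
            den[stop][site] += 2
            num[stop][site] += (column[0].upper() != anc) + (column[1].upper() != anc)

    rows = []
    for stop in STOP_CODONS:
        if valid[stop] == 0:
            logger.warning("substitution_profile: no valid %s-terminating genes", stop)
            continue
        for site in sites:
            d = den[stop][site]
            rows.append(
                {
                    "stop_class": stop,
                    "site": site,
                    "numerator": num[stop][site],
                    "denominator": d,
                    "frequency": num[stop][site] / d if d else float("nan"),
                }
            )
    table = pd.DataFrame(rows, columns=["stop_class", "site", "numerator", "denominator", "frequency"])
    return SubstitutionProfile(table=table, valid_genes={k: v for k, v in valid.items() if v})
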