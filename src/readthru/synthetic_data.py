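"""Synthetic inputs with recorded ground truth.

Three generators emulate the statistical structure of the pipeline's
real inputs so that every stage can be validated against known truth
without downloads:

* :func:`build_genome` — a genome of single-gene contigs with
  Markov-structured 97-nt 3'-UTRs, expression-linked stop-codon choice
  (a logistic link from log protein abundance to P(TAA)), optional
  injected ASC excess at one codon position, and a per-gene plan of
  which extraction filter (if any) the gene is built to fail.
* :func:`build_triplets` — three-taxon ortholog alignments evolved from
  a common ancestor under Jukes-Cantor with a per-site rate profile
  that mimics the reduced substitution rate near the stop.
* :func:`build_comparative` — a pure-birth phylogeny with log(N_e)
  evolving as Brownian motion and a response trait built as
  a + b log(N_e) + phylogenetic noise with known signal lambda.

The matching ``generate_*`` functions write the standard file formats
(FASTA/GFF3/TSV/Newick) plus a truth table. Same seed, byte-identical
outputs.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath
from scipy import integrate, stats

from .extraction import REJECTION_REASONS
from .formats_io import GeneModel, GenomeData, write_genome
from .triplet_substitutions import TripletAlignment

NUCLEOTIDES = "ACGT"
STOP_CODONS = ("TAA", "TGA", "TAG")
_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in STOP_CODONS
)
_COMP = str.maketrans("ACGTN", "TGCAN")
UTR_LEN = 97
N_TRIPLETS = UTR_LEN // 3


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# --------------------------------------------------------------------------
# genome generator
# --------------------------------------------------------------------------

@dataclass
class GenomeSimConfig:
    """Study conditions for one synthetic genome.

    ``stop_probs`` are baseline (TAA, TGA, TAG) probabilities at mean
    expression; ``expression_link`` is the logistic coefficient tying
    P(TAA) to standardised log abundance (positive favours TAA in
    highly expressed genes). ``asc_inject`` = (codon position 1..6,
    excess probability): with that probability the UTR triplet at the
    position is overwritten by a uniformly drawn stop codon.
    ``reject_plan`` maps extraction rejection reasons to the per-gene
    probability of building a gene that fails that (single) filter.
    """

    n_genes: int = 1000
    gc: float = 0.5
    stop_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    expression_link: float = 0.5
    asc_inject: tuple[int, float] | None = None
    transition_matrix: np.ndarray | None = None
    intergenic_range: tuple[int, int] = (150, 400)
    cds_codons_range: tuple[int, int] = (50, 200)
    minus_strand_prob: float = 0.5
    reject_plan: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not math.isclose(sum(self.stop_probs), 1.0, abs_tol=1e-9):
            raise ValueError("stop_probs must sum to 1")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.asc_inject is not None:
            pos, e = self.asc_inject
            if not (1 <= pos <= 6 and 0 <= e <= 1):
                raise ValueError("asc_inject must be (position 1..6, prob)")
        if self.intergenic_range[0] <= max(100, UTR_LEN):
            raise ValueError("intergenic_range must start above the filter threshold")
        bad = set(self.reject_plan) - set(REJECTION_REASONS)
        if bad:
            raise ValueError(f"unknown rejection reasons {bad}")
        if sum(self.reject_plan.values()) >= 1:
            raise ValueError("rejection probabilities must sum below 1")

    def chain(self) -> tuple[np.ndarray, np.ndarray]:
        """(transition matrix, initial distribution) of the UTR chain."""
        if self.transition_matrix is not None:
            T = np.asarray(self.transition_matrix, dtype=float)
            if T.shape != (4, 4) or not np.allclose(T.sum(axis=1), 1.0):
                raise ValueError("transition matrix must be 4x4 row-stochastic")
        else:
            at = (1 - self.gc) / 2
            gcp = self.gc / 2
            row = np.array([at, gcp, gcp, at])  # A C G T
            T = np.tile(row, (4, 1))
        # stationary distribution as the initial marginal
        w, v = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(w - 1)))
        init = np.real(v[:, i])
        init = np.abs(init) / np.abs(init).sum()
        return T, init


def _sample_markov(T: np.ndarray, init: np.ndarray, length: int, rng: np.random.Generator) -> str:
    cum_t = np.cumsum(T, axis=1)
    cum_i = np.cumsum(init)
    out = np.empty(length, dtype=np.int8)
    state = int(np.searchsorted(cum_i, rng.random(), side="right"))
    state = min(state, 3)
    out[0] = state
    u = rng.random(length)
    for j in range(1, length):
        state = int(np.searchsorted(cum_t[state], u[j], side="right"))
        state = min(state, 3)
        out[j] = state
    return "".join(NUCLEOTIDES[i] for i in out)


def _p_taa(z: float, config: GenomeSimConfig) -> float:
    p0 = config.stop_probs[0]
    if p0 <= 0 or p0 >= 1:  # degenerate: link has nothing to shift
        return p0
    logit = math.log(p0 / (1 - p0)) + config.expression_link * z
    return 1 / (1 + math.exp(-logit))


def _draw_stop(z: float, config: GenomeSimConfig, rng: np.random.Generator) -> str:
    p_taa = _p_taa(z, config)
    if rng.random() < p_taa:
        return "TAA"
    _, p_tga, p_tag = config.stop_probs
    if p_tga + p_tag == 0:
        return "TAA"
    return "TGA" if rng.random() < p_tga / (p_tga + p_tag) else "TAG"


def build_genome(config: GenomeSimConfig):
    """Build a synthetic genome in memory.

    Returns (GenomeData, expression dict, truth DataFrame). Each gene
    sits on its own contig; the truth table records the planned filter
    fate, the primary stop, any-ASC positions post-injection, the first
    ASC, the 3' intergenic distance and the strand.
    """
    rng = np.random.default_rng(config.seed)
    T, init = config.chain()
    fates = list(config.reject_plan)
    fate_probs = [config.reject_plan[f] for f in fates]
    p_retained = 1 - sum(fate_probs)

    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    expression: dict[str, float] = {}
    truth_rows = []

    for i in range(config.n_genes):
        gid = f"g{i:05d}"
        u = rng.random()
        fate = "retained"
        acc = p_retained
        for f, pf in zip(fates, fate_probs):
            if u < acc + pf and u >= acc:
                fate = f
                break
            acc += pf

        z = float(rng.standard_normal())
        abundance = math.exp(z)
        stop = _draw_stop(z, config, rng)

        n_codons = int(rng.integers(config.cds_codons_range[0], config.cds_codons_range[1] + 1))
        internal = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
        cds = "ATG" + "".join(_NONSTOP_CODONS[j] for j in internal) + stop

        if fate == "internal-stop":
            k = int(rng.integers(1, n_codons - 1))
            cds = cds[: 3 * k] + STOP_CODONS[int(rng.integers(3))] + cds[3 * k + 3 :]
        elif fate == "no-valid-stop":
            cds = cds[:-3] + _NONSTOP_CODONS[int(rng.integers(len(_NONSTOP_CODONS)))]
        elif fate == "length-not-multiple-of-3":
            extra = "".join(NUCLEOTIDES[int(b)] for b in rng.integers(0, 4, size=int(rng.integers(1, 3))))
            cds = cds + extra

        if fate == "short-intergenic":
            d = int(rng.integers(0, 101))
        else:
            d = int(rng.integers(config.intergenic_range[0], config.intergenic_range[1] + 1))
        downstream = _sample_markov(T, init, d, rng) if d else ""

        asc_positions: list[int] = []
        first_asc: int | None = None
        if d >= UTR_LEN:
            utr = downstream[:UTR_LEN]
            if config.asc_inject is not None:
                pos, excess = config.asc_inject
                if rng.random() < excess:
                    injected = STOP_CODONS[int(rng.integers(3))]
                    utr = utr[: 3 * (pos - 1)] + injected + utr[3 * pos :]
            if fate == "non-ACGT":
                j = int(rng.integers(0, UTR_LEN))
                utr = utr[:j] + "N" + utr[j + 1 :]
            downstream = utr + downstream[UTR_LEN:]
            asc_positions = [
                n for n in range(1, 7) if utr[3 * (n - 1) : 3 * n] in STOP_CODONS
            ]
            first_asc = min(asc_positions) if asc_positions else None

        pad = "".join(NUCLEOTIDES[int(b)] for b in rng.integers(0, 4, size=20))
        plus_sense = pad + cds + downstream
        strand = "-" if rng.random() < config.minus_strand_prob else "+"
        contig_id = f"ctg_{gid}"
        if strand == "+":
            contigs[contig_id] = plus_sense
            cds_start = len(pad)
            parts = [(cds_start, cds_start + len(cds))]
        else:
            contigs[contig_id] = _revcomp(plus_sense)
            lc = len(plus_sense)
            parts = [(lc - len(pad) - len(cds), lc - len(pad))]
        genes.append(
            GeneModel(
                gene_id=gid,
                contig=contig_id,
                strand=strand,
                cds_parts=parts,
                coding_sequence=cds,
            )
        )
        expression[gid] = abundance
        truth_rows.append(
            {
                "gene_id": gid,
                "fate": fate,
                "stop": stop if fate not in ("no-valid-stop", "length-not-multiple-of-3") else "",
                "abundance": abundance,
                "asc_positions": ",".join(map(str, asc_positions)),
                "first_asc": first_asc if first_asc is not None else 0,
                "intergenic": d,
                "strand": strand,
            }
        )

    genome = GenomeData(contigs=contigs, genes=genes)
    truth = pd.DataFrame(truth_rows)
    return genome, expression, truth


def generate_genome(config: GenomeSimConfig, out_dir: str | Path):
    """Write a synthetic genome (FASTA, GFF3, expression TSV, truth TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, expression, truth = build_genome(config)
    fasta, gff3 = out / "genome.fasta", out / "genes.gff3"
    write_genome(genome, fasta, gff3)
    expr = out / "expression.tsv"
    with open(expr, "w") as fh:
        fh.write("gene_id\tabundance\n")
        for gid, ab in expression.items():
            fh.write(f"{gid}\t{ab:.10g}\n")
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return fasta, gff3, expr, truth_path


# ---- analytic expectations under the genome generator --------------------

def markov_position_marginals(T: np.ndarray, init: np.ndarray, length: int = UTR_LEN) -> np.ndarray:
    m = np.empty((length, 4))
    m[0] = init
    for t in range(1, length):
        m[t] = m[t - 1] @ T
    return m


def markov_stop_prob(T: np.ndarray, init: np.ndarray, position: int) -> float:
    """P(stop triplet at codon ``position``) under the chain (exact)."""
    m = markov_position_marginals(T, init, 3 * position)
    start = 3 * (position - 1)
    total = 0.0
    for s in STOP_CODONS:
        i1, i2, i3 = (_BASE_INDEX[b] for b in s)
        total += m[start][i1] * T[i1, i2] * T[i2, i3]
    return total


def expected_any_asc(config: GenomeSimConfig, position: int) -> float:
    """P(any ASC at a codon position), injection included."""
    T, init = config.chain()
    p = markov_stop_prob(T, init, position)
    if config.asc_inject is not None and config.asc_inject[0] == position:
        e = config.asc_inject[1]
        p = e + (1 - e) * p
    return p


def expected_p_hat(config: GenomeSimConfig) -> float:
    """Expected pooled in-frame stop-triplet frequency over the 32 UTR triplets."""
    return float(np.mean([expected_any_asc(config, n) for n in range(1, N_TRIPLETS + 1)]))


def expected_first_asc(config: GenomeSimConfig, position: int) -> float:
    """P(first ASC at a position); exact when the chain rows are identical
    (i.i.d. bases), otherwise an independence approximation."""
    prob = expected_any_asc(config, position)
    for j in range(1, position):
        prob *= 1 - expected_any_asc(config, j)
    return prob


def expected_pes(config: GenomeSimConfig, position: int) -> float:
    """Expected first-ASC PES at a position against the analytic geometric
    null with p estimated from the injected data (large-n limit)."""
    p_hat = expected_p_hat(config)
    null = p_hat * (1 - p_hat) ** (position - 1)
    return expected_first_asc(config, position) / null - 1


def _truncated_mean_p_taa(config: GenomeSimConfig, lo: float, hi: float) -> float:
    """E[P(TAA|z)] for z ~ N(0,1) truncated to (lo, hi)."""
    num, _ = integrate.quad(lambda z: _p_taa(z, config) * stats.norm.pdf(z), lo, hi)
    den = stats.norm.cdf(hi) - stats.norm.cdf(lo)
    return num / den


def expected_taa_disparity(config: GenomeSimConfig) -> float:
    """Expected HEG/LEG TAA frequency ratio (top vs bottom abundance quartile)."""
    q = stats.norm.ppf(0.75)
    return _truncated_mean_p_taa(config, q, 8.0) / _truncated_mean_p_taa(config, -8.0, -q)


def expected_taa_enrichment_score(config: GenomeSimConfig) -> float:
    """Expected TAA enrichment score under the generator conditions."""
    primary = _truncated_mean_p_taa(config, -8.0, 8.0)
    T, init = config.chain()
    usages = []
    for pos in range(1, 7):
        m = markov_position_marginals(T, init, 3 * pos)
        start = 3 * (pos - 1)
        probs = {}
        for s in STOP_CODONS:
            i1, i2, i3 = (_BASE_INDEX[b] for b in s)
            probs[s] = m[start][i1] * T[i1, i2] * T[i2, i3]
        total = sum(probs.values())
        taa = probs["TAA"]
        if config.asc_inject is not None and config.asc_inject[0] == pos:
            e = config.asc_inject[1]
            taa = e / 3 + (1 - e) * taa
            total = e + (1 - e) * total
        usages.append(taa / total)
    mean_down = float(np.mean(usages))
    return (primary - mean_down) / mean_down


# --------------------------------------------------------------------------
# ortholog triplet generator
# --------------------------------------------------------------------------

def default_rate_profile() -> dict[int, float]:
    """V-shaped per-site rate multipliers: constraint strongest at the stop,
    relieved with distance on both sides; stop positions frozen."""
    prof: dict[int, float] = {}
    for site in range(-30, 0):
        prof[site] = 0.3 + (-site - 1) * (1.0 / 29)
    for site in (1, 2, 3):
        prof[site] = 0.0
    for site in range(4, 34):
        prof[site] = 0.3 + (site - 4) * (1.0 / 29)
    return prof


@dataclass
class TripletSimConfig:
    """Study conditions for ortholog-triplet simulation.

    Branch lengths are expected substitutions per site at rate
    multiplier 1; the outgroup length spans root to outgroup tip. Sites
    outside the profiled window evolve at multiplier 1.
    """

    n_genes: int = 500
    branch_lengths: tuple[float, float, float] = (0.05, 0.05, 0.10)
    rate_profile: dict[int, float] = field(default_factory=default_rate_profile)
    stop_codon: str = "TAA"
    cds_codons: int = 12
    utr_len: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.branch_lengths):
            raise ValueError("branch lengths must be >= 0")
        if any(r < 0 for r in self.rate_profile.values()):
            raise ValueError("rate multipliers must be >= 0")
        if self.stop_codon not in STOP_CODONS:
            raise ValueError(f"stop_codon must be one of {STOP_CODONS}")
        if self.cds_codons < 12:
            raise ValueError("need >= 12 codons (10 upstream of the stop)")
        if self.utr_len < 34:
            raise ValueError("need >= 34 nt of UTR (10 downstream codons + margin)")


def _site_of_position(pos: int, stop_first: int) -> int | None:
    """Window site of alignment position ``pos`` (stop first base at
    ``stop_first``), or None outside the window."""
    if stop_first - 30 <= pos < stop_first:
        return pos - stop_first
    if stop_first <= pos < stop_first + 3:
        return pos - stop_first + 1
    if stop_first + 3 <= pos < stop_first + 33:
        return pos - stop_first + 1
    return None


def _evolve(seq_idx: np.ndarray, rates: np.ndarray, t: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Jukes-Cantor evolution: per-site Poisson(t * rate) events, each
    replacing the base by one of the other three. Returns (sequence,
    per-site event counts)."""
    events = rng.poisson(t * rates)
    out = seq_idx.copy()
    for pos in np.nonzero(events)[0]:
        for _ in range(events[pos]):
            out[pos] = (out[pos] + 1 + rng.integers(3)) % 4
    return out, events


def build_triplets(config: TripletSimConfig):
    """Simulate aligned ortholog triplets; returns (triplets, truth table).

    Truth rows: gene, site (window coordinates), substitution events per
    lineage. Alignments are gapless, CDS uppercase / UTR lowercase.
    """
    rng = np.random.default_rng(config.seed)
    cds_len = 3 * config.cds_codons
    total_len = cds_len + config.utr_len
    stop_first = cds_len - 3

    rates = np.ones(total_len)
    for pos in range(total_len):
        site = _site_of_position(pos, stop_first)
        if site is not None:
            rates[pos] = config.rate_profile.get(site, 1.0)

    triplets: list[TripletAlignment] = []
    truth_rows = []
    t1, t2, to = config.branch_lengths
    for g in range(config.n_genes):
        internal = rng.integers(0, len(_NONSTOP_CODONS), size=config.cds_codons - 2)
        root = "ATG" + "".join(_NONSTOP_CODONS[j] for j in internal) + config.stop_codon
        root += "".join(NUCLEOTIDES[int(b)] for b in rng.integers(0, 4, size=config.utr_len))
        root_idx = np.fromiter((_BASE_INDEX[b] for b in root), dtype=np.int64)

        in1, ev1 = _evolve(root_idx, rates, t1, rng)
        in2, ev2 = _evolve(root_idx, rates, t2, rng)
        out, evo = _evolve(root_idx, rates, to, rng)

        seqs = {}
        for role, idx in (("ingroup1", in1), ("ingroup2", in2), ("outgroup", out)):
            s = "".join(NUCLEOTIDES[i] for i in idx)
            seqs[role] = s[:cds_len] + s[cds_len:].lower()
        triplets.append(TripletAlignment(seqs=seqs, name=f"orth{g:05d}"))
        for pos in range(total_len):
            site = _site_of_position(pos, stop_first)
            if site is None:
                continue
            if ev1[pos] or ev2[pos] or evo[pos]:
                truth_rows.append(
                    {
                        "gene": f"orth{g:05d}",
                        "site": site,
                        "events_in1": int(ev1[pos]),
                        "events_in2": int(ev2[pos]),
                        "events_out": int(evo[pos]),
                    }
                )
    truth = pd.DataFrame(truth_rows, columns=["gene", "site", "events_in1", "events_in2", "events_out"])
    return triplets, truth


def generate_triplets(config: TripletSimConfig, out_dir: str | Path):
    """Write aligned FASTA files (one per gene), a role map and the truth table."""
    out = Path(out_dir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    triplets, truth = build_triplets(config)
    paths = []
    for trip in triplets:
        p = out / "alignments" / f"{trip.name}.fasta"
        with open(p, "w") as fh:
            for role in ("ingroup1", "ingroup2", "outgroup"):
                fh.write(f">{role}_{trip.name}\n{trip.seqs[role]}\n")
        paths.append(p)
    roles = out / "roles.tsv"
    with open(roles, "w") as fh:
        fh.write("token\trole\n")
        for trip in triplets:
            for role in ("ingroup1", "ingroup2", "outgroup"):
                fh.write(f"{role}_{trip.name}\t{role}\n")
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return paths, roles, truth_path


# --------------------------------------------------------------------------
# comparative generator
# --------------------------------------------------------------------------

@dataclass
class ComparativeSimConfig:
    """Study conditions for the comparative simulation.

    ``trait_model``: response = a + b * log(N_e) + noise, where the
    noise is multivariate normal with covariance sigma2 * V(lambda_true)
    (V the Brownian matrix of the pure-birth tree). log(N_e) itself
    evolves as Brownian motion with rate ``sigma2_x`` from root value
    ``log_ne_root``.
    """

    n_species: int = 50
    birth_rate: float = 1.0
    a: float = 0.0
    b: float = 1.0
    lambda_true: float = 1.0
    sigma2: float = 0.25
    sigma2_x: float = 1.0
    log_ne_root: float = 14.0
    q_unicell: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species too small for regression (need >= 3)")
        if not 0 <= self.lambda_true <= 1:
            raise ValueError("lambda_true must be in [0, 1]")


def build_comparative(config: ComparativeSimConfig):
    """Simulate (tree, traits DataFrame, truth dict)."""
    from .comparative import _lambda_cov, brownian_cov  # local import avoids cycle

    pyrng = random.Random(config.seed)
    rng = np.random.default_rng(config.seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_species,
        rng=pyrng,
    )
    # The process stops at the n-th speciation, leaving newborn sister
    # tips with zero-length branches; run the clock forward by one
    # waiting time so the present sits strictly between events.
    t_extra = float(rng.exponential(1.0 / (config.n_species * config.birth_rate)))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + t_extra
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i:03d}"
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    V = brownian_cov(tree, tips)
    jitter = 1e-10 * np.eye(len(tips))
    Lx = np.linalg.cholesky(config.sigma2_x * V + jitter)
    log_ne = config.log_ne_root + Lx @ rng.standard_normal(len(tips))
    Vl = _lambda_cov(V, config.lambda_true)
    Le = np.linalg.cholesky(config.sigma2 * Vl + jitter)
    noise = Le @ rng.standard_normal(len(tips))
    response = config.a + config.b * log_ne + noise
    cellularity = (rng.random(len(tips)) < config.q_unicell).astype(int)

    traits = pd.DataFrame(
        {
            "species": tips,
            "log_ne": log_ne,
            "ne": np.exp(log_ne),
            "cellularity": cellularity,
            "taa_enrichment": response,
        }
    ).set_index("species", drop=False)
    truth = {
        "a": config.a,
        "b": config.b,
        "lambda_true": config.lambda_true,
        "sigma2": config.sigma2,
    }
    return tree, traits, truth


def generate_comparative(config: ComparativeSimConfig, out_dir: str | Path):
    """Write tree.nwk, traits.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, traits, truth = build_comparative(config)
    tree_path = out / "tree.nwk"
    tree.write(path=str(tree_path), schema="newick", suppress_rooting=True)
    traits_path = out / "traits.tsv"
    traits.to_csv(traits_path, sep="\t", index=False)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return tree_path, traits_path, truth_path
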