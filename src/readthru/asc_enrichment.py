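"""Additional stop codon (ASC) enrichment in 3'-UTRs.

An in-frame stop triplet shortly downstream of the primary stop acts as
a fail-safe terminator when read-through occurs. This module scores ASC
occurrence at the first six in-frame "codon" positions of the 3'-UTR
(+1 at UTR nt 1-3, ..., +6 at nt 16-18) and tests it against two null
models:

* a **dinucleotide-controlled null**: 10,000 Monte-Carlo 3'-UTR
  simulants from a first-order Markov chain fitted to the observed UTR
  dinucleotide frequencies (compared on the *any-ASC* statistic);
* the **analytic degrading-frequency null** (first-ASC geometric law):
  P(first ASC at position n) = p (1 - p)^(n-1), with p the pooled
  in-frame stop-triplet frequency across the UTR (compared on the
  *first-ASC* statistic).

Per position, enrichment is quantified by the positional enrichment
score PES = (observed - expected) / expected and tested by a 1-df
chi-square; a genome is called enriched when any position shows a raw
excess with p < 0.05/6 (Bonferroni over the six positions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .extraction import StopContext

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TGA", "TAG")
NUCLEOTIDES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}
N_POSITIONS = 6
UTR_LEN = 97
N_TRIPLETS = UTR_LEN // 3  # 32 in-frame UTR triplets

#: stop triplets as base-index tuples, for vectorized counting
_STOP_IDX = [tuple(_BASE_INDEX[b] for b in s) for s in STOP_CODONS]


def detect_ascs(utr: str | StopContext) -> tuple[set[int], int | None]:
    """ASC positions within codon positions +1..+6 of one 3'-UTR.

    Position n holds a stop iff utr[3(n-1):3n] is TAA/TGA/TAG. Returns
    (set of positions with any stop, first such position or None).
    """
    seq = utr.downstream_utr if isinstance(utr, StopContext) else utr
    if len(seq) < 3 * N_POSITIONS:
        raise ValueError(f"UTR shorter than {3 * N_POSITIONS} nt")
    positions = {
        n for n in range(1, N_POSITIONS + 1) if seq[3 * (n - 1) : 3 * n] in STOP_CODONS
    }
    return positions, min(positions) if positions else None


@dataclass
class AscProfile:
    """Observed any-ASC and first-ASC counts per codon position +1..+6."""

    any_count: dict[int, int]
    first_count: dict[int, int]
    n_genes: int

    def __post_init__(self) -> None:
        assert sum(self.first_count.values()) <= self.n_genes
        for n in range(1, N_POSITIONS + 1):
            assert self.first_count[n] <= self.any_count[n]


def asc_profile(contexts: list[StopContext]) -> AscProfile:
    """Tally ASC occurrence over a gene set."""
    any_count = {n: 0 for n in range(1, N_POSITIONS + 1)}
    first_count = {n: 0 for n in range(1, N_POSITIONS + 1)}
    for c in contexts:
        positions, first = detect_ascs(c)
        for n in positions:
            any_count[n] += 1
        if first is not None:
            first_count[first] += 1
    return AscProfile(any_count=any_count, first_count=first_count, n_genes=len(contexts))


def estimate_p_hat(contexts: list[StopContext]) -> float:
    """Pooled in-frame stop-triplet frequency across the whole 97-nt UTR
    (32 triplets per gene) — the ``p`` of the geometric first-ASC null."""
    if not contexts:
        raise ValueError("estimate_p_hat: empty input")
    n_stop = 0
    n_total = 0
    for c in contexts:
        seq = c.downstream_utr
        for i in range(N_TRIPLETS):
            n_total += 1
            if seq[3 * i : 3 * i + 3] in STOP_CODONS:
                n_stop += 1
    return n_stop / n_total


@dataclass
class AscNullModel:
    """Per-position expected ASC frequency under one null model.

    ``kind`` is ``adachi-cavalcanti`` (analytic, first-ASC) or
    ``dinucleotide-sim`` (Monte-Carlo, any-ASC).
    """

    kind: str
    expected_freq: dict[int, float]
    p_hat: float | None = None
    n_sim: int | None = None
    seed: int | None = None


def ac_null(p: float, positions: int = N_POSITIONS) -> AscNullModel:
    """Analytic first-ASC null: P(first ASC at n) = p (1-p)^(n-1)."""
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    freq = {n: p * (1 - p) ** (n - 1) for n in range(1, positions + 1)}
    return AscNullModel(kind="adachi-cavalcanti", expected_freq=freq, p_hat=p)


def fit_markov(contexts: list[StopContext]) -> tuple[np.ndarray, np.ndarray]:
    """First-order Markov chain fitted to the observed 97-nt UTRs.

    Returns (transition matrix T[4,4], initial distribution = empirical
    marginal of the first UTR base, position +4). Rows for source states
    never observed fall back to uniform so simulation cannot deadlock;
    observed rows are exactly empirical.
    """
    if not contexts:
        raise ValueError("fit_markov: empty input")
    trans = np.zeros((4, 4))
    init = np.zeros(4)
    for c in contexts:
        idx = np.fromiter((_BASE_INDEX[b] for b in c.downstream_utr), dtype=np.int64)
        init[idx[0]] += 1
        np.add.at(trans, (idx[:-1], idx[1:]), 1)
    # observed rows stay exactly empirical; source states never seen get a
    # uniform row so the simulation cannot deadlock
    row_sums = trans.sum(axis=1, keepdims=True)
    unseen = row_sums[:, 0] == 0
    trans[unseen] = 0.25
    row_sums[row_sums == 0] = 1.0
    trans /= row_sums
    if init.sum() == 0:
        raise ValueError("no UTR sequences")
    init /= init.sum()
    return trans, init


def simulate_markov(
    trans: np.ndarray,
    init: np.ndarray,
    n_seq: int,
    length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized simulation of ``n_seq`` sequences (as base indices)."""
    cum_t = np.cumsum(trans, axis=1)
    cum_i = np.cumsum(init)
    out = np.empty((n_seq, length), dtype=np.int8)
    u = rng.random(n_seq)
    state = np.searchsorted(cum_i, u, side="right").astype(np.int8)
    np.clip(state, 0, 3, out=state)
    out[:, 0] = state
    for j in range(1, length):
        u = rng.random(n_seq)
        rows = cum_t[state]  # (n_seq, 4)
        state = (rows < u[:, None]).sum(axis=1).astype(np.int8)
        np.clip(state, 0, 3, out=state)
        out[:, j] = state
    return out


def any_asc_counts(seq_idx: np.ndarray, positions: int = N_POSITIONS) -> np.ndarray:
    """Per-position counts of sequences holding a stop triplet, from an
    (n_seq, length) base-index matrix."""
    counts = np.zeros(positions, dtype=np.int64)
    for n in range(positions):
        b1 = seq_idx[:, 3 * n]
        b2 = seq_idx[:, 3 * n + 1]
        b3 = seq_idx[:, 3 * n + 2]
        is_stop = np.zeros(len(seq_idx), dtype=bool)
        for i1, i2, i3 in _STOP_IDX:
            is_stop |= (b1 == i1) & (b2 == i2) & (b3 == i3)
        counts[n] = int(is_stop.sum())
    return counts


def dinucleotide_null(
    contexts: list[StopContext],
    n_sim: int = 10_000,
    seed: int | None = None,
) -> AscNullModel:
    """Dinucleotide-controlled Monte-Carlo null (any-ASC statistic).

    Fits a first-order Markov chain to the real UTRs (capturing
    nucleotide and dinucleotide preferences), simulates ``n_sim``
    97-nt UTRs, and reports the fraction of simulants with a stop
    triplet at each codon position. ``seed`` is mandatory so a run is
    reproducible bit-for-bit.
    """
    if seed is None:
        raise ValueError("dinucleotide_null: seed is mandatory")
    trans, init = fit_markov(contexts)
    rng = np.random.default_rng(seed)
    sims = simulate_markov(trans, init, n_sim, UTR_LEN, rng)
    counts = any_asc_counts(sims)
    freq = {n + 1: counts[n] / n_sim for n in range(N_POSITIONS)}
    return AscNullModel(kind="dinucleotide-sim", expected_freq=freq, n_sim=n_sim, seed=seed)


@dataclass
class PositionalEnrichment:
    """Observed vs expected ASC occurrence per codon position.

    ``pes`` is the positional enrichment score (obs - exp) / exp; the
    chi-square is 1-df Pearson on [observed, n - observed] against the
    null split.
    """

    observed: dict[int, int]
    expected: dict[int, float]
    pes: dict[int, float]
    p_value: dict[int, float]
    direction: dict[int, str]
    n_genes: int
    null_kind: str
    statistic: str  # "first-asc" or "any-asc"


def positional_enrichment(profile: AscProfile, null: AscNullModel) -> PositionalEnrichment:
    """Score observed ASC counts against a null model.

    The statistic is matched to the null: the analytic geometric null
    uses first-ASC counts, the dinucleotide simulation null any-ASC
    counts.
    """
    if null.kind == "adachi-cavalcanti":
        observed = profile.first_count
        statistic = "first-asc"
    elif null.kind == "dinucleotide-sim":
        observed = profile.any_count
        statistic = "any-asc"
    else:
        raise ValueError(f"unknown null kind {null.kind!r}")
    n = profile.n_genes
    pes: dict[int, float] = {}
    pval: dict[int, float] = {}
    expected: dict[int, float] = {}
    direction: dict[int, str] = {}
    for pos in sorted(null.expected_freq):
        exp = null.expected_freq[pos] * n
        obs = observed[pos]
        if exp == 0:
            if obs > 0:
                raise ValueError(f"position +{pos}: expected 0 with observed {obs} (degenerate null)")
            pes[pos], pval[pos] = 0.0, 1.0
            expected[pos], direction[pos] = 0.0, "enriched"
            continue
        expected[pos] = exp
        pes[pos] = (obs - exp) / exp
        chi2 = (obs - exp) ** 2 / exp + (obs - exp) ** 2 / (n - exp) if exp < n else 0.0
        pval[pos] = float(stats.chi2.sf(chi2, df=1)) if exp < n else 1.0
        direction[pos] = "enriched" if obs >= exp else "depleted"
    return PositionalEnrichment(
        observed=dict(observed),
        expected=expected,
        pes=pes,
        p_value=pval,
        direction=direction,
        n_genes=n,
        null_kind=null.kind,
        statistic=statistic,
    )


@dataclass
class GenomeAscCall:
    """Genome-level enrichment verdict plus the mean-PES score."""

    enriched: bool
    enrichment_score: float
    alpha_per_test: float
    significant_positions: list[int] = field(default_factory=list)


def genome_call(
    enrichment: PositionalEnrichment, alpha: float = 0.05, m: int = N_POSITIONS
) -> GenomeAscCall:
    """Call a genome ASC-enriched if any position shows a raw excess with
    chi-square p below the Bonferroni threshold alpha/m; the genome score
    is the mean PES across positions."""
    positions = sorted(enrichment.pes)
    if len(positions) != m:
        raise ValueError(f"expected {m} positions, got {len(positions)}")
    threshold = alpha / m
    sig = [
        pos
        for pos in positions
        if enrichment.observed[pos] > enrichment.expected[pos]
        and enrichment.p_value[pos] < threshold
    ]
    score = float(np.mean([enrichment.pes[p] for p in positions]))
    return GenomeAscCall(
        enriched=bool(sig),
        enrichment_score=score,
        alpha_per_test=threshold,
        significant_positions=sig,
    )


def chance_probability(alpha: float = 0.05, m: int = N_POSITIONS) -> tuple[float, float, float]:
    """Family-wise chance machinery for the genome call.

    Returns (per-test threshold alpha/m, probability a genome shows no
    significant position by chance (1 - alpha/m)^m, and its complement).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    prob_none = (1 - threshold) ** m
    return threshold, prob_none, 1 - prob_none


def group_binomial(k_enriched: int, n_genomes: int, p0: float, tail: str = "greater") -> float:
    """Exact binomial tail probability for k enriched genomes out of n.

    ``tail`` is ``greater``, ``less`` or ``two-sided`` (two-sided sums
    outcome probabilities <= P(k)).
    """
    if not 0 <= k_enriched <= n_genomes:
        raise ValueError("k must be within [0, n]")
    alt = {"greater": "greater", "less": "less", "two-sided": "two-sided"}[tail]
    return float(stats.binomtest(k_enriched, n_genomes, p0, alternative=alt).pvalue)
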