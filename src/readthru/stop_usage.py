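"""Primary stop-codon usage statistics.

TAA is the least leaky of the three stops; if translational
read-through is under selection, highly expressed genes (HEGs) should
prefer TAA over TGA/TAG relative to lowly expressed genes (LEGs), and
termination-context nucleotides (e.g. +4G) should be enriched in HEGs.
This module computes per-set stop frequencies, the standardized
frequency difference SFD = (HEG freq - LEG freq) / LEG freq, and
per-site nucleotide enrichment of HEGs against a genome-wide null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .extraction import StopContext

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TGA", "TAG")
NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass
class StopFrequencies:
    freq: dict[str, float]
    n: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("empty gene set")
        assert abs(sum(self.freq.values()) - 1.0) < 1e-12


@dataclass
class SfdResult:
    """Per-stop standardized frequency difference between HEGs and LEGs."""

    sfd: dict[str, float]
    heg_freq: StopFrequencies
    leg_freq: StopFrequencies


def stop_frequencies(contexts: list[StopContext]) -> StopFrequencies:
    """Proportion of genes terminating in each of TAA/TGA/TAG."""
    if not contexts:
        raise ValueError("stop_frequencies: empty input")
    n = len(contexts)
    counts = {s: 0 for s in STOP_CODONS}
    for c in contexts:
        counts[c.primary_stop] += 1
    return StopFrequencies(freq={s: counts[s] / n for s in STOP_CODONS}, n=n)


def sfd(heg_contexts: list[StopContext], leg_contexts: list[StopContext]) -> SfdResult:
    """Standardized frequency difference (HEG - LEG) / LEG per stop codon.

    A stop absent from both sets gets SFD 0 (logged); absent from LEGs
    only gets +inf.
    """
    heg = stop_frequencies(heg_contexts)
    leg = stop_frequencies(leg_contexts)
    out: dict[str, float] = {}
    for s in STOP_CODONS:
        h, l = heg.freq[s], leg.freq[s]
        if l == 0:
            if h == 0:
                logger.info("sfd: %s absent from both sets; SFD set to 0", s)
                out[s] = 0.0
            else:
                out[s] = math.inf
        else:
            out[s] = (h - l) / l
    return SfdResult(sfd=out, heg_freq=heg, leg_freq=leg)


def site_nucleotide_enrichment(
    heg_contexts: list[StopContext],
    all_contexts: list[StopContext],
    window: tuple[int, int] = (-30, 100),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-site, per-nucleotide chi-square enrichment of HEGs vs all genes.

    For each stop-anchored site in ``window`` (stop at +1..+3, first UTR
    base +4) and each nucleotide X, the HEG count of X is compared with
    the expectation under the genome-wide frequency of X at that site
    (all genes regardless of expression) by a 1-df Pearson chi-square on
    [count, n - count] — without continuity correction. Significance is
    flagged at p < ``alpha`` before any multiple-testing correction.

    Callers wanting the per-stop-class panels should pre-filter both
    context lists to one primary-stop class.

    Returns a tidy DataFrame: site, nucleotide, observed, expected,
    chi2, p_value, direction, significant. Upstream sites (< 0) carry
    direction as computed but are interpretable only as context, since
    amino-acid-level selection confounds the coding side.
    """
    lo, hi = window
    if lo < -30 or hi > 100 or lo > hi:
        raise ValueError(f"window {window} outside [-30, 100]")
    if not heg_contexts or not all_contexts:
        raise ValueError("empty context set")
    n_heg = len(heg_contexts)
    n_all = len(all_contexts)
    sites = [s for s in range(lo, hi + 1) if s != 0]
    rows = []
    for site in sites:
        heg_counts = {b: 0 for b in NUCLEOTIDES}
        all_counts = {b: 0 for b in NUCLEOTIDES}
        for c in heg_contexts:
            heg_counts[c.site(site)] += 1
        for c in all_contexts:
            all_counts[c.site(site)] += 1
        for base in NUCLEOTIDES:
            f_all = all_counts[base] / n_all
            obs = heg_counts[base]
            exp = f_all * n_heg
            if exp == 0 and obs > 0:
                logger.warning(
                    "site %+d %s: zero global frequency with observed %d; "
                    "expected floored at 0.5 counts",
                    site, base, obs,
                )
                exp = 0.5
            if exp == 0 or exp == n_heg:
                chi2, p = 0.0, 1.0
            else:
                chi2 = (obs - exp) ** 2 / exp + (obs - exp) ** 2 / (n_heg - exp)
                p = float(stats.chi2.sf(chi2, df=1))
            rows.append(
                {
                    "site": site,
                    "nucleotide": base,
                    "observed": obs,
                    "expected": exp,
                    "chi2": chi2,
                    "p_value": p,
                    "direction": "enriched" if obs >= exp else "depleted",
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)
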