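"""Cross-species comparative machinery.

Per-genome enrichment scores (TAA enrichment, TAA disparity), effective
population size from nucleotide diversity and mutation rate
(N_e = pi / 4 mu), and phylogenetic generalized least squares with
Pagel's lambda estimated by maximum likelihood. The lambda transform
scales the off-diagonal entries of the Brownian-motion covariance
matrix implied by the tree: lambda = 0 treats species as independent
points (ordinary least squares), lambda = 1 is pure Brownian evolution
on the tree. Exact combinatorial tests (binomial, Fisher's exact,
rank tests) back the cross-genome group claims.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .asc_enrichment import N_POSITIONS, STOP_CODONS
from .extraction import StopContext
from .stop_usage import stop_frequencies

logger = logging.getLogger(__name__)


def taa_enrichment_score(contexts: list[StopContext]) -> float:
    """TAA enrichment at the primary stop relative to downstream triplets.

    Usage = TAA / (TAA + TGA + TAG) among stop triplets at a position.
    The score is (primary usage - mean downstream usage) / mean
    downstream usage, the downstream mean being the unweighted average
    over codon positions +1..+6 (positions with no stop triplet at all
    are dropped from the mean with a warning).
    """
    if not contexts:
        raise ValueError("taa_enrichment_score: empty input")
    primary = stop_frequencies(contexts)
    primary_usage = primary.freq["TAA"]  # freqs already sum to 1 over the 3 stops

    usages = []
    for pos in range(1, N_POSITIONS + 1):
        counts = {s: 0 for s in STOP_CODONS}
        for c in contexts:
            triplet = c.downstream_utr[3 * (pos - 1) : 3 * pos]
            if triplet in counts:
                counts[triplet] += 1
        total = sum(counts.values())
        if total == 0:
            logger.warning("taa_enrichment_score: no stop triplets at +%d; dropped", pos)
            continue
        usages.append(counts["TAA"] / total)
    if not usages:
        raise ValueError("no downstream position with a stop triplet")
    mean_down = float(np.mean(usages))
    return (primary_usage - mean_down) / mean_down


def taa_disparity(heg_contexts: list[StopContext], leg_contexts: list[StopContext]) -> float:
    """TAA primary-stop frequency in HEGs divided by that in LEGs."""
    heg = stop_frequencies(heg_contexts).freq["TAA"]
    leg = stop_frequencies(leg_contexts).freq["TAA"]
    if leg == 0:
        raise ValueError("taa_disparity: LEG TAA frequency is zero")
    return heg / leg


def estimate_ne(pi: float, mu: float) -> float:
    """Effective population size N_e = pi / (4 mu)."""
    if pi <= 0 or mu <= 0:
        raise ValueError("pi and mu must be positive")
    return pi / (4 * mu)


def brownian_cov(tree: dendropy.Tree, tips: list[str]) -> np.ndarray:
    """Brownian-motion covariance matrix implied by the phylogeny.

    V[i, j] is the root-to-MRCA path length shared by tips i and j;
    the diagonal is root-to-tip depth.
    """
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in tips if t not in taxa]
    if missing:
        raise ValueError(f"tips not in tree: {missing}")
    # root distance per node
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[node] = (depth[parent] if parent is not None else 0.0) + (
            edge if parent is not None else 0.0
        )
    n = len(tips)
    V = np.zeros((n, n))
    pdm = tree.phylogenetic_distance_matrix()
    for i, a in enumerate(tips):
        leaf_a = tree.find_node_with_taxon_label(a)
        V[i, i] = depth[leaf_a]
        for j in range(i + 1, n):
            mrca = pdm.mrca(taxa[a], taxa[tips[j]])
            V[i, j] = V[j, i] = depth[mrca]
    return V


@dataclass
class PglsFit:
    """A fitted PGLS model.

    ``params``/``bse``/``tvalues``/``pvalues`` are indexed by design
    column (intercept first). ``lam`` is Pagel's lambda; the LR tests
    compare the ML lambda against the bounds 0 and 1 (1-df chi-square).
    Adjusted r-squared uses the usual small-sample correction and may be
    negative when the model underperforms the intercept-only null.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    lam: float
    loglik: float
    r2: float
    r2_adj: float
    lr_lambda0: tuple[float, float]
    lr_lambda1: tuple[float, float]
    nobs: int
    df_resid: int
    sigma2: float


def _lambda_cov(V: np.ndarray, lam: float) -> np.ndarray:
    Vl = lam * V
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def _gls(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS estimates via Cholesky whitening; returns (beta, rss, logdetV, XtViX_inv, rss0)."""
    L = np.linalg.cholesky(V)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("singular design")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    XtViX_inv = np.linalg.inv(Xw.T @ Xw)
    # intercept-only whitened fit for r-squared
    ones_w = solve_triangular(L, np.ones_like(y), lower=True)
    c = float(ones_w @ yw) / float(ones_w @ ones_w)
    r0 = yw - c * ones_w
    rss0 = float(r0 @ r0)
    return beta, rss, logdet, XtViX_inv, rss0


def _profile_loglik(y, X, V, lam, reml=False) -> float:
    n, k = X.shape
    Vl = _lambda_cov(V, lam)
    beta, rss, logdet, XtViX_inv, _ = _gls(y, X, Vl)
    if not reml:
        s2 = rss / n
        return -0.5 * (n * math.log(2 * math.pi * s2) + logdet + n)
    s2 = rss / (n - k)
    sign, logdet_x = np.linalg.slogdet(np.linalg.inv(XtViX_inv))
    return -0.5 * ((n - k) * math.log(2 * math.pi * s2) + logdet + logdet_x + (n - k))


def pgls_fit(
    y: pd.Series,
    X: pd.DataFrame,
    tree: dendropy.Tree,
    lam: float | str = "ML",
    reml: bool = False,
    add_intercept: bool = True,
) -> PglsFit:
    """Phylogenetic GLS with Pagel's lambda.

    ``y`` and ``X`` must share an index of species names matching the
    tree's tip labels. ``lam`` is either a fixed value in [0, 1] or
    ``"ML"``: profile likelihood maximised over a 0.01 grid followed by
    bounded refinement to 1e-6. With ``lam=0`` the fit reduces to
    ordinary least squares. Coefficient p-values use a t distribution
    with n - k residual degrees of freedom (k including the intercept).
    """
    tips = list(y.index)
    if list(X.index) != tips:
        raise ValueError("y and X must share the same species index")
    Xd = X.copy()
    if add_intercept:
        Xd.insert(0, "intercept", 1.0)
    names = list(Xd.columns)
    Xm = Xd.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    n, k = Xm.shape
    if n <= k:
        raise ValueError("need more species than parameters")
    # collinearity check with named columns
    if np.linalg.matrix_rank(Xm) < k:
        bad = [
            names[j]
            for j in range(Xm.shape[1])
            if np.linalg.matrix_rank(np.delete(Xm, j, axis=1)) == np.linalg.matrix_rank(Xm)
        ]
        raise ValueError(f"singular design matrix; collinear columns include {bad}")
    V = brownian_cov(tree, tips)
    if not np.allclose(np.diag(V), V[0, 0], rtol=1e-6):
        logger.warning("pgls_fit: tree is not ultrametric; lambda transform applied regardless")

    def nll(l: float) -> float:
        return -_profile_loglik(yv, Xm, V, l, reml=reml)

    if lam == "ML":
        grid = np.linspace(0.0, 1.0, 101)
        vals = [nll(l) for l in grid]
        i = int(np.argmin(vals))
        lo, hi = max(0.0, grid[i] - 0.01), min(1.0, grid[i] + 0.01)
        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6})
        lam_hat = float(res.x) if res.fun <= vals[i] else float(grid[i])
    else:
        lam_hat = float(lam)
        if not 0 <= lam_hat <= 1:
            raise ValueError("lambda must be in [0, 1]")

    Vl = _lambda_cov(V, lam_hat)
    beta, rss, logdet, XtViX_inv, rss0 = _gls(yv, Xm, Vl)
    df_resid = n - k
    sigma2 = rss / df_resid
    bse = np.sqrt(np.diag(XtViX_inv) * sigma2)
    tvals = beta / bse
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    r2 = 1.0 - rss / rss0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    ll_hat = _profile_loglik(yv, Xm, V, lam_hat, reml=reml)
    ll0 = _profile_loglik(yv, Xm, V, 0.0, reml=reml)
    ll1 = _profile_loglik(yv, Xm, V, 1.0, reml=reml)
    lr0 = max(0.0, 2 * (ll_hat - ll0))
    lr1 = max(0.0, 2 * (ll_hat - ll1))
    return PglsFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        lam=lam_hat,
        loglik=float(ll_hat),
        r2=float(r2),
        r2_adj=float(r2_adj),
        lr_lambda0=(float(lr0), float(stats.chi2.sf(lr0, 1))),
        lr_lambda1=(float(lr1), float(stats.chi2.sf(lr1, 1))),
        nobs=n,
        df_resid=df_resid,
        sigma2=float(sigma2),
    )


def fisher_exact_2x2(table, tail: str = "two-sided") -> float:
    """Exact hypergeometric p for a 2x2 table; two-sided sums all tables
    with fixed margins whose probability does not exceed the observed."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 integer table")
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[tail]
    return float(stats.fisher_exact(t, alternative=alt)[1])


def rank_tests(a, b, kind: str) -> tuple[float, float]:
    """Wilcoxon signed-rank (paired) or Spearman rank correlation.

    Returns (statistic, p-value); exact small-sample or normal
    approximation p per scipy's defaults.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if kind == "wilcoxon":
        if np.all(a - b == 0):
            raise ValueError("wilcoxon: all differences zero")
        res = stats.wilcoxon(a, b)
        return float(res.statistic), float(res.pvalue)
    if kind == "spearman":
        res = stats.spearmanr(a, b)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown rank test {kind!r}")


@dataclass
class SpeciesTraits:
    """One species' comparative variables."""

    species: str
    pi: float | None = None
    mu: float | None = None
    ne: float | None = None
    cellularity: int | None = None  # 1 unicellular, 0 multicellular
    gc: float | None = None
    median_gene_length: float | None = None
    median_3prime_intergenic: float | None = None
    taa_enrichment: float | None = None
    asc_enrichment: float | None = None
    taa_disparity: float | None = None

    def __post_init__(self) -> None:
        if self.ne is None and self.pi is not None and self.mu is not None:
            self.ne = estimate_ne(self.pi, self.mu)
        if self.gc is not None and not 0 <= self.gc <= 1:
            raise ValueError(f"{self.species}: gc outside [0, 1]")


def read_traits(tsv_path) -> pd.DataFrame:
    """Read a species trait table (TSV with a ``species`` column)."""
    df = pd.read_csv(tsv_path, sep="\t")
    if "species" not in df.columns:
        raise ValueError("traits table needs a 'species' column")
    if df["species"].duplicated().any():
        raise ValueError("duplicate species in traits table")
    if {"pi", "mu"} <= set(df.columns) and "ne" not in df.columns:
        df["ne"] = df["pi"] / (4 * df["mu"])
    return df.set_index("species", drop=False)


def parse_formula(formula: str) -> tuple[str, list[str]]:
    """Parse ``response ~ term (+ term)*`` into (response, terms)."""
    if "~" not in formula:
        raise ValueError("formula must contain '~'")
    lhs, rhs = formula.split("~", 1)
    response = lhs.strip()
    terms = [t.strip() for t in rhs.split("+") if t.strip()]
    if not response or not terms:
        raise ValueError(f"malformed formula {formula!r}")
    return response, terms
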