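"""One-sided Fisher's exact enrichment of a gene list against an ontology.

For each testable term a 2x2 table is formed from the input list, the term's
(propagated) annotation set and a gene universe, and the upper-tail
hypergeometric p-value, a hypergeometric-moment Z-score, the sample odds
ratio with a Woolf 95% CI (Haldane–Anscombe corrected when any cell is zero)
and a Benjamini–Hochberg FDR are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .knowledgebase import Ontology

logger = logging.getLogger("xgrkit")


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table for one term: overlap k, term size K, input size n, universe N.

    Cells: a = k (input ∩ term), b = K − k, c = n − k, d = N − K − n + k.
    """

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise EnrichmentError(f"invalid table: k={self.k}, K={self.K}, n={self.n}")
        if self.d < 0 or self.K > self.N or self.n > self.N:
            raise EnrichmentError(
                f"invalid table: K={self.K}, n={self.n}, N={self.N}, k={self.k}"
            )

    @property
    def a(self) -> int:
        return self.k

    @property
    def b(self) -> int:
        return self.K - self.k

    @property
    def c(self) -> int:
        return self.n - self.k

    @property
    def d(self) -> int:
        return self.N - self.K - self.n + self.k


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    zscore: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    fdr: float
    members: list[str]


def fisher_one_sided(t: ContingencyTable) -> float:
    """Upper-tail (enrichment-direction) hypergeometric p-value.

    p = Σ_{j=k}^{min(K,n)} C(K,j) C(N−K,n−j) / C(N,n); equals 1.0 at k = 0.
    """
    p = float(stats.hypergeom.sf(t.k - 1, t.N, t.K, t.n))
    return min(p, 1.0)


def hypergeom_zscore(t: ContingencyTable) -> float:
    """Standardize the overlap against exact hypergeometric null moments.

    z = (k − μ)/σ with μ = nK/N and σ² = nK(N−K)(N−n)/(N²(N−1)); degenerate
    tables (σ = 0, e.g. K = N) return 0 by convention.
    """
    if t.N < 2:
        return 0.0
    mu = t.n * t.K / t.N
    var = t.n * t.K * (t.N - t.K) * (t.N - t.n) / (t.N**2 * (t.N - 1))
    if var <= 0.0:
        return 0.0
    return (t.k - mu) / math.sqrt(var)


def odds_ratio_ci(
    t: ContingencyTable, level: float = 0.95
) -> tuple[float, float, float]:
    """Sample odds ratio with a Woolf logit confidence interval.

    When any cell is zero, 0.5 is added to all four cells (Haldane–Anscombe)
    before both the OR and the interval are computed.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return orr, orr * math.exp(-z * se), orr * math.exp(z * se)


def bh_fdr(pvalues: Sequence[float], n_tests: int | None = None) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.  ``n_tests`` overrides m
    (>= len(pvalues)) so the correction can span terms that were filtered out
    before testing.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise EnrichmentError("p-values must lie in [0, 1]")
    m = len(p) if n_tests is None else int(n_tests)
    if m < len(p):
        raise EnrichmentError("n_tests must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out.tolist()


def make_universe(
    input_genes: Iterable[str],
    ont: Ontology,
    mode: str = "annotated",
    custom_universe: Iterable[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Define the background gene universe and restrict the input to it.

    mode 'annotated' (default): every gene with at least one propagated
    annotation.  mode 'custom': the caller-supplied gene list.  Input genes
    outside the universe are dropped (count logged); an empty filtered input
    is an error.
    """
    input_set = set(input_genes)
    if mode == "annotated":
        universe = ont.annotated_genes()
    elif mode == "custom":
        if custom_universe is None:
            raise EnrichmentError("universe mode 'custom' requires a gene list")
        universe = set(custom_universe)
    else:
        raise EnrichmentError(f"unknown universe mode {mode!r}")
    filtered = input_set & universe
    dropped = len(input_set) - len(filtered)
    if dropped:
        logger.info("universe filter: dropped %d/%d input genes outside universe",
                    dropped, len(input_set))
    if not filtered:
        raise EnrichmentError("no input genes in universe")
    return universe, filtered


def run_enrichment(
    input_genes: Iterable[str],
    ont: Ontology,
    min_term: int = 10,
    max_term: int = 2000,
    min_overlap: int = 3,
    universe_mode: str = "annotated",
    custom_universe: Iterable[str] | None = None,
    fdr_scope: str = "tested",
) -> list[EnrichmentResult]:
    """Test every eligible ontology term for enrichment in the input list.

    A term is eligible when its propagated annotation set, restricted to the
    universe, has size in [min_term, max_term]; it is tested only when the
    overlap k with the (universe-filtered) input reaches min_overlap.  FDR is
    computed across tested terms by default; ``fdr_scope='eligible'`` corrects
    over all size-eligible terms instead.  Results are sorted by
    (fdr, pvalue, -zscore, term_id).
    """
    universe, inp = make_universe(input_genes, ont, universe_mode, custom_universe)
    N, n = len(universe), len(inp)
    rows: list[EnrichmentResult] = []
    n_eligible = 0
    for term_id in sorted(ont.terms):
        term_genes = ont.propagated.get(term_id, set()) & universe
        K = len(term_genes)
        if not (min_term <= K <= max_term):
            continue
        n_eligible += 1
        members = sorted(term_genes & inp)
        k = len(members)
        if k < min_overlap:
            continue
        t = ContingencyTable(k=k, K=K, n=n, N=N)
        orr, lo, hi = odds_ratio_ci(t)
        rows.append(EnrichmentResult(
            term_id=term_id,
            term_name=ont.terms[term_id][0],
            k=k, K=K, n=n, N=N,
            zscore=hypergeom_zscore(t),
            odds_ratio=orr, ci_low=lo, ci_high=hi,
            pvalue=fisher_one_sided(t),
            fdr=1.0,
            members=members,
        ))
    if not rows:
        logger.info("enrichment: no testable terms "
                    "(eligible terms: %d, min_overlap: %d)", n_eligible, min_overlap)
        return []
    if fdr_scope == "tested":
        m = None
    elif fdr_scope == "eligible":
        m = n_eligible
    else:
        raise EnrichmentError(f"unknown fdr scope {fdr_scope!r}")
    qs = bh_fdr([r.pvalue for r in rows], n_tests=m)
    for r, q in zip(rows, qs):
        r.fdr = q
    rows.sort(key=lambda r: (r.fdr, r.pvalue, -r.zscore, r.term_id))
    return rows
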