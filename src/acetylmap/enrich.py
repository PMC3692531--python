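"""Exact enrichment statistics: hypergeometric/Fisher tests, Pearson
chi-squared, Benjamini-Hochberg FDR, and the category- and TE-family
enrichment procedures built on them.

All tests are one-sided in the direction of enrichment (upper tail).  The
hypergeometric upper tail is computed by log-space summation of the exact
pmf, so p-values remain accurate far into the tail (1e-300 territory) where
naive summation underflows.  The one-sided Fisher exact test on the 2x2
table [[a, b], [c, d]] is mathematically identical to the hypergeometric
upper tail with k=a, n=a+b, K=a+c, N=a+b+c+d; both routes are exposed and
their agreement is enforced by the test-suite.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2 as chi2_dist

from .model import CategoryMap, TEFeature


@dataclass
class EnrichmentResult:
    """One category's contingency configuration and test outcome.

    k: selected features in the category; n: selected features total;
    K: category size in the universe; N: universe size.
    """

    category: str
    k: int
    n: int
    K: int
    N: int
    method: str
    p: float
    q: float = float("nan")
    significant: bool = False
    sample: str = ""

    def __post_init__(self) -> None:
        _check_counts(self.k, self.n, self.K, self.N)


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(
            f"invalid hypergeometric configuration k={k}, n={n}, K={K}, N={N}"
        )


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The probability of selecting at least k category members when drawing n
    features without replacement from a universe of N containing K members.
    Computed as a log-space sum of exact pmf terms.
    """
    _check_counts(k, n, K, N)
    if k == 0:
        return 1.0
    xs = np.arange(k, min(n, K) + 1)
    if xs.size == 0:
        return 0.0
    log_pmf = (
        gammaln(K + 1) - gammaln(xs + 1) - gammaln(K - xs + 1)
        + gammaln(N - K + 1) - gammaln(n - xs + 1) - gammaln(N - K - n + xs + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Equals ``hypergeom_upper_tail(a, a + b, a + c, a + b + c + d)``.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b + c + d == 0:
        import warnings

        warnings.warn("all-zero contingency table; p = 1")
        return 1.0
    return hypergeom_upper_tail(a, a + b, a + c, a + b + c + d)


def pearson_chi2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-squared statistic and p (1 df, no continuity correction).

    statistic = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("chi-squared undefined with a zero margin")
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    return float(stat), float(chi2_dist.sf(stat, df=1))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q(i) = min_{j >= i} p(j) * m / j over the ascending-sorted p's, capped
    at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def category_enrichment(
    selected_genes: Iterable[str],
    category_map: CategoryMap,
    method: str = "hypergeometric",
    fdr_cutoff: float = 0.05,
    sample: str = "",
) -> list[EnrichmentResult]:
    """Test every category for over-representation among the selected genes.

    Per category: k = |selected ∩ category|, n = |selected|, K = category
    size, N = universe size.  ``method`` is ``hypergeometric`` (exact upper
    tail) or ``chi2`` (Pearson's test on the induced 2x2 table, the procedure
    commonly used for GO term lists).  q-values are BH-adjusted across the
    categories tested; ``significant`` means q < fdr_cutoff.

    Selected genes outside the mapped universe are dropped with a warning
    only if the map claims full coverage; with a partial map (universe_size >
    mapped genes) unmapped selections legitimately count toward n.
    """
    if method not in ("hypergeometric", "chi2"):
        raise ValueError(f"unknown method {method!r}")
    selected = set(selected_genes)
    if not selected:
        import warnings

        warnings.warn("empty selection; no enrichment computed")
        return []
    N = category_map.universe_size
    if len(selected) > N:
        raise ValueError("selection larger than the universe")
    n = len(selected)
    results: list[EnrichmentResult] = []
    for category, K in sorted(category_map.category_sizes().items()):
        members = category_map.genes_in(category)
        k = len(selected & members)
        if method == "hypergeometric":
            p = hypergeom_upper_tail(k, n, K, N)
        else:
            table = [[k, n - k], [K - k, N - n - K + k]]
            _stat, p = pearson_chi2(table)
        results.append(
            EnrichmentResult(
                category=category, k=k, n=n, K=K, N=N, method=method, p=p,
                sample=sample,
            )
        )
    qs = bh_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
        # chi2 is two-sided; significance is only called in the direction of
        # over-representation (k/n above the universe fraction K/N)
        r.significant = bool(q < fdr_cutoff and r.k * r.N >= r.n * r.K)
    return results


def te_family_enrichment(
    marked_tes: Mapping[str, Iterable[TEFeature]],
    all_tes: Sequence[TEFeature],
    small_count_threshold: int = 100,
    p_cutoff: float = 0.01,
    families: Optional[Sequence[str]] = None,
) -> list[EnrichmentResult]:
    """Per-family, per-sample TE enrichment among marked TE copies.

    For family F and sample s: k = marked copies of F, n = total marked
    copies in s across ALL families, K = genome-wide copies of F, N =
    genome-wide TE copies.  The exact test is the hypergeometric upper tail;
    when k falls below ``small_count_threshold`` it is recorded as a Fisher
    exact test instead — numerically identical, the label preserves which
    procedure a small count would historically have been run through.
    Significance is called at p < p_cutoff (no FDR step here).
    """
    universe_counts: dict[str, int] = {}
    for te in all_tes:
        universe_counts[te.family] = universe_counts.get(te.family, 0) + 1
    N = len(all_tes)
    if families is None:
        families = sorted(universe_counts)
    results: list[EnrichmentResult] = []
    for sample, marked in marked_tes.items():
        marked = list(marked)
        n = len(marked)
        marked_counts: dict[str, int] = {}
        for te in marked:
            marked_counts[te.family] = marked_counts.get(te.family, 0) + 1
        for fam in marked_counts:
            if fam not in universe_counts:
                raise ValueError(
                    f"family {fam!r} marked in {sample} but absent from the universe"
                )
        for fam in families:
            K = universe_counts.get(fam, 0)
            k = marked_counts.get(fam, 0)
            method = "fisher_greater" if k < small_count_threshold else "hypergeometric"
            p = hypergeom_upper_tail(k, n, K, N) if n else 1.0
            r = EnrichmentResult(
                category=fam, k=k, n=n, K=K, N=N, method=method, p=p, sample=sample
            )
            r.q = r.p  # no multiplicity correction in the TE procedure
            r.significant = bool(p < p_cutoff)
            results.append(r)
    return results
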