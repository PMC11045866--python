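"""Small-sample nonparametric statistics implemented from first principles.

The quantification endpoints of the pipeline (metabolite differences,
penetrability fractions, growth rates, taxon-phenotype correlations) rest on
group sizes of 4-10, where asymptotic p-values are unreliable.  This module
provides exact null distributions where feasible:

* Mann-Whitney U with the exact p-value obtained by dynamic-programming
  enumeration of the rank-configuration null (no ties, n1+n2 <= 30);
* Wilcoxon signed-rank with exact enumeration of all 2^n sign assignments;
* Spearman correlation with an exact permutation p for small n;
* Benjamini-Hochberg step-up adjustment.

All tests are two-sided; exact two-sided p = min(1, 2 * min(lower tail,
upper tail)), matching standard exact-test software output for these
statistics.  Ties (mid-ranks) or larger samples fall back to the normal /
t approximation, flagged via ``exact=False`` on the result.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "CorrelationResult",
    "mann_whitney_exact",
    "wilcoxon_signed_rank_exact",
    "spearman",
    "bh_adjust",
    "correlate_taxa_vs_phenotype",
    "mann_whitney_u_counts",
]

# exact-enumeration bounds (memory/time limited DP; beyond these the
# normal approximation is both fast and accurate)
_MW_EXACT_MAX_N = 30
_WILCOXON_EXACT_MAX_N = 25
_SPEARMAN_EXACT_MAX_N = 9


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool
    n1: int
    n2: int
    tie_corrected: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "spearman"
    exact: bool = False
    p_adjusted: float | None = None
    label: str | None = None


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def mann_whitney_u_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of rank configurations per U value under the MW null.

    Entry ``c[u]`` is the number of ways to choose which ``n1`` of the
    ``n1+n2`` ranks belong to the first sample such that its Mann-Whitney
    statistic equals ``u``.  Computed by the classic dynamic programme over
    ranks; the counts sum to C(n1+n2, n1).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    cached = _mw_counts_cache.get((n1, n2))
    if cached is not None:
        return cached
    nmax = n1 * n2
    # f[k, u]: subsets of size k of the first i ranks with statistic u
    f = np.zeros((n1 + 1, nmax + 1), dtype=float)
    f[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):
        for k in range(min(i, n1), 0, -1):
            # taking rank i as the k-th member adds (i - k) to U
            shift = i - k
            if shift == 0:
                f[k, :] += f[k - 1, :]
            elif shift <= nmax:
                f[k, shift:] += f[k - 1, : nmax + 1 - shift]
    counts = f[n1]
    counts.setflags(write=False)
    _mw_counts_cache[(n1, n2)] = counts
    return counts


_mw_counts_cache: dict[tuple[int, int], np.ndarray] = {}


def mann_whitney_exact(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test; exact enumeration when the sample permits.

    The statistic reported is U = min(U1, U2).  With no ties and
    n1 + n2 <= 30 the two-sided p-value is exact (2 x the smaller tail of
    the enumerated null, capped at 1); otherwise the normal approximation
    with tie correction and continuity correction is used.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is implemented")
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    n1, n2 = len(xa), len(ya)
    pooled = np.concatenate([xa, ya])
    ranks = _sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if not has_ties and n1 + n2 <= _MW_EXACT_MAX_N:
        counts = mann_whitney_u_counts(n1, n2)
        total = counts.sum()
        uo = int(round(u))
        lower = counts[: uo + 1].sum() / total
        # null is symmetric about n1*n2/2; upper tail of min-U equals lower
        p = min(1.0, 2.0 * lower)
        return TestResult(u, p, "mann-whitney", True, n1, n2, False)

    # normal approximation with tie correction
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        # all observations identical
        return TestResult(u, 1.0, "mann-whitney", False, n1, n2, True)
    # u = min(u1, u2) <= mu, so the lower tail is the smaller one
    z = (u - mu + 0.5) / math.sqrt(sigma2)  # continuity correction
    p = min(1.0, 2.0 * _sps.norm.cdf(z))
    return TestResult(u, p, "mann-whitney", False, n1, n2, has_ties)


def _signed_rank_counts(n: int) -> np.ndarray:
    """Counts of sign assignments per W+ value; generating function of
    prod_i (1 + z^i) over ranks 1..n."""
    wmax = n * (n + 1) // 2
    c = np.zeros(wmax + 1, dtype=float)
    c[0] = 1.0
    for i in range(1, n + 1):
        c[i:] += c[: wmax + 1 - i]
    return c


def wilcoxon_signed_rank_exact(pre, post) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test on pre vs post values.

    Zero differences are dropped.  Exact two-sided p by enumeration of the
    2^n equiprobable sign assignments when |differences| are tie-free and
    n <= 25; otherwise normal approximation with tie correction.
    """
    pa = _as_1d(pre, "pre")
    qa = _as_1d(post, "post")
    if len(pa) != len(qa):
        raise ValueError("pre and post must be paired (equal length)")
    d = qa - pa
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon-signed-rank", False, len(pa), len(pa), False)
    absd = np.abs(d)
    ranks = _sps.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    _, tie_counts = np.unique(absd, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    wmax = n * (n + 1) / 2.0

    if not has_ties and n <= _WILCOXON_EXACT_MAX_N:
        counts = _signed_rank_counts(n)
        total = counts.sum()  # == 2^n
        wo = int(round(w_plus))
        lower = counts[: wo + 1].sum() / total
        upper = counts[wo:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return TestResult(w_plus, p, "wilcoxon-signed-rank", True, n, n, False)

    mu = wmax / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if sigma2 <= 0:
        return TestResult(w_plus, 1.0, "wilcoxon-signed-rank", False, n, n, True)
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * _sps.norm.sf(abs(z)))
    return TestResult(w_plus, p, "wilcoxon-signed-rank", False, n, n, has_ties)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with an exact permutation p for small n.

    rho is the Pearson correlation of mid-ranks.  For n <= 9 the two-sided
    p-value enumerates all n! permutations of one margin; above that the
    usual t approximation with n-2 degrees of freedom is used.  Constant
    input yields an undefined (NaN) correlation.
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    n = len(xa)
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return CorrelationResult(float("nan"), float("nan"), n, exact=False)
    rx = _sps.rankdata(xa)
    ry = _sps.rankdata(ya)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= _SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(itertools.permutations(ry)))
        rx_c = rx - rx.mean()
        p_c = perms - ry.mean()
        denom = math.sqrt((rx_c**2).sum() * (ry - ry.mean()
                                             ).dot(ry - ry.mean()))
        rhos = p_c.dot(rx_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return CorrelationResult(rho, p, n, exact=True)

    if abs(rho) >= 1.0:
        return CorrelationResult(rho, 0.0, n, exact=False)
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = float(2 * _sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho, min(1.0, p), n, exact=False)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def correlate_taxa_vs_phenotype(
    composition,
    phenotype,
    top_n: int = 30,
    ranking=None,
) -> list[CorrelationResult]:
    """Screen taxa for association with a per-sample phenotype.

    Parameters
    ----------
    composition : CompositionTable or pandas.DataFrame
        Per-sample taxon values to correlate (CLR or relative abundance),
        samples x taxa.
    phenotype : mapping or pandas.Series
        One real value per sample (e.g. mucus growth rate).
    top_n : int
        Number of taxa, ranked by mean abundance, entering the screen.
    ranking : optional DataFrame
        Table whose column means define the "most abundant" ordering;
        defaults to ``composition`` itself (pass relative abundances here
        when correlating CLR values).

    Returns Spearman results with BH-adjusted p-values across the screen.
    """
    import pandas as pd

    values = getattr(composition, "values_frame", None)
    frame = values if values is not None else pd.DataFrame(composition)
    pheno = pd.Series(phenotype)
    missing = [s for s in frame.index if s not in pheno.index]
    if missing:
        raise ValueError(f"phenotype missing for samples: {missing}")
    pheno = pheno.loc[frame.index]

    rank_frame = frame if ranking is None else pd.DataFrame(ranking)
    order = rank_frame.mean(axis=0).sort_values(ascending=False)
    if len(order) < top_n:
        import warnings

        warnings.warn(
            f"only {len(order)} taxa available; using all", stacklevel=2
        )
    chosen = list(order.index[:top_n])

    results = []
    for taxon in chosen:
        r = spearman(frame[taxon].to_numpy(), pheno.to_numpy())
        results.append(
            CorrelationResult(r.rho, r.p_value, r.n, exact=r.exact, label=taxon)
        )
    finite = [r for r in results if np.isfinite(r.p_value)]
    if finite:
        adj = bh_adjust([r.p_value for r in finite])
        adj_map = {id(r): a for r, a in zip(finite, adj)}
        results = [
            CorrelationResult(
                r.rho, r.p_value, r.n, exact=r.exact,
                p_adjusted=adj_map.get(id(r)), label=r.label,
            )
            for r in results
        ]
    return results
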