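"""Nonparametric comparison battery with exact small-sample behaviour.

Small bioarchaeological assemblages (n of 3–16 per group) sit outside the
comfort zone of asymptotic rank tests, so the group comparisons here use
full permutation enumeration whenever the sample is small enough:

* rank-sum (Mann–Whitney): exact over all C(n, n_a) group assignments,
* signed-rank with Pratt zero handling: exact over all 2^m sign patterns
  (zero differences are ranked with the rest, then discarded),
* Spearman rho: exact over all n! pairings for tiny n,
* Kruskal–Wallis: tie-corrected H with either the χ² approximation or a
  Monte-Carlo permutation p-value.

Ties are handled with mid-ranks everywhere and the enumeration runs on the
tied rank vector itself, so tied data need no special casing.  All p-values
are two-sided, computed as the doubled smaller tail probability (capped at
1) — the convention of the classical exact-test implementations.
Enumeration switches to the normal approximation above a combined n of 20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as _ss

EXACT_LIMIT = 20


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple
    exact: bool

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0 <= self.p_value <= 1 + 1e-12:
            raise ValueError(f"p={self.p_value} outside [0, 1]")


def _doubled_tail(cdf_le: float, cdf_ge: float) -> float:
    return min(1.0, 2.0 * min(cdf_le, cdf_ge))


def _int_ranks(values) -> np.ndarray:
    """Mid-ranks doubled to exact integers (mid-ranks are multiples of ½)."""
    r = _ss.rankdata(values) * 2.0
    ri = np.rint(r).astype(np.int64)
    assert np.allclose(r, ri)
    return ri


# ---------------------------------------------------------------------------
# Kruskal–Wallis

def kruskal_wallis(groups, method: str = "asymptotic",
                   n_resamples: int = 20000,
                   seed: Optional[int] = None) -> TestResult:
    """Tie-corrected H test across ≥2 groups.

    ``method='permutation'`` estimates the p-value by Monte-Carlo
    reshuffling of the pooled rank vector (seeded); ``'asymptotic'`` uses
    the χ² approximation.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    ns = tuple(len(g) for g in groups)
    if np.ptp(np.concatenate(groups)) == 0:
        return TestResult(0.0, 1.0, "kruskal-wallis", ns, True)
    h0, p_asym = _ss.kruskal(*groups)
    if method == "asymptotic":
        return TestResult(float(h0), float(p_asym), "kruskal-wallis (chi2)",
                          ns, False)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(groups)
    ranks = _ss.rankdata(pooled)
    n = len(pooled)
    sizes = np.array(ns)
    ends = np.cumsum(sizes)
    starts = ends - sizes
    tie_term = _tie_correction(pooled, n)
    # H depends only on per-group rank sums; permute the (fixed) rank vector
    idx = np.argsort(rng.random((n_resamples, n)), axis=1)
    perm_ranks = ranks[idx]
    hs = np.zeros(n_resamples)
    for s, e, ng in zip(starts, ends, sizes):
        hs += perm_ranks[:, s:e].sum(axis=1) ** 2 / ng
    hs = (12.0 / (n * (n + 1)) * hs - 3 * (n + 1)) / tie_term
    p = float(np.mean(hs >= h0 - 1e-12))
    return TestResult(float(h0), p, "kruskal-wallis (permutation)", ns, False)


def _tie_correction(pooled, n) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)


# ---------------------------------------------------------------------------
# rank-sum (Mann–Whitney / Wilcoxon two-sample)

def wilcoxon_rank_sum_exact(a, b,
                            exact_limit: int = EXACT_LIMIT) -> TestResult:
    """Two-sample rank-sum test, exact by enumeration for n_a+n_b ≤ limit.

    The statistic reported is the rank sum W of the first sample.  The
    exact null enumerates every C(n, n_a) assignment of the tied rank
    vector; larger samples fall back to the tie-corrected normal
    approximation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    n, na = len(a) + len(b), len(a)
    ranks2 = _int_ranks(np.concatenate([a, b]))  # doubled integer ranks
    w0 = int(ranks2[:na].sum())
    if n <= exact_limit:
        dist = _subset_sum_counts(ranks2, na)
        total = sum(dist.values())
        le = sum(c for s, c in dist.items() if s <= w0) / total
        ge = sum(c for s, c in dist.items() if s >= w0) / total
        return TestResult(w0 / 2.0, _doubled_tail(le, ge),
                          "rank-sum (exact)", (na, n - na), True)
    res = _ss.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic")
    return TestResult(w0 / 2.0, float(res.pvalue),
                      "rank-sum (normal approx)", (na, n - na), False)


def _subset_sum_counts(weights, k) -> dict:
    """counts[s] = number of k-subsets of ``weights`` with sum s."""
    dp = {(0, 0): 1}
    for w in weights:
        w = int(w)
        nxt = dict(dp)
        for (cnt, s), c in dp.items():
            if cnt < k:
                key = (cnt + 1, s + w)
                nxt[key] = nxt.get(key, 0) + c
        dp = nxt
    return {s: c for (cnt, s), c in dp.items() if cnt == k}


# ---------------------------------------------------------------------------
# signed-rank with Pratt zeros

def wilcoxon_signed_rank_pratt_exact(paired_a, paired_b,
                                     exact_limit: int = EXACT_LIMIT
                                     ) -> TestResult:
    """Paired signed-rank test with Pratt handling of zero differences.

    Zeros are ranked together with the non-zero differences and then
    dropped, which keeps the remaining ranks honest when many pairs tie.
    Exact enumeration over the 2^m sign patterns of the non-zero ranks for
    m ≤ limit, else the Pratt-corrected normal approximation.
    """
    a = np.asarray(paired_a, float)
    b = np.asarray(paired_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if len(d) < 3:
        raise ValueError("need at least 3 pairs")
    ranks2 = _int_ranks(np.abs(d))
    nz = d != 0
    r = ranks2[nz]
    if r.size == 0:
        return TestResult(0.0, 1.0, "signed-rank Pratt (degenerate)",
                          (len(d),), True)
    w0 = int(r[d[nz] > 0].sum())
    if r.size <= exact_limit:
        dist = _signed_sum_counts(r)
        total = sum(dist.values())
        le = sum(c for s, c in dist.items() if s <= w0) / total
        ge = sum(c for s, c in dist.items() if s >= w0) / total
        return TestResult(w0 / 2.0, _doubled_tail(le, ge),
                          "signed-rank Pratt (exact)", (len(d),), True)
    res = _ss.wilcoxon(a, b, zero_method="pratt", correction=False,
                       alternative="two-sided", method="approx")
    return TestResult(w0 / 2.0, float(res.pvalue),
                      "signed-rank Pratt (normal approx)", (len(d),), False)


def _signed_sum_counts(weights) -> dict:
    """counts[s] = number of sign patterns with positive-rank sum s."""
    dp = {0: 1}
    for w in weights:
        w = int(w)
        nxt = {}
        for s, c in dp.items():
            nxt[s] = nxt.get(s, 0) + c
            nxt[s + w] = nxt.get(s + w, 0) + c
        dp = nxt
    return dp


# ---------------------------------------------------------------------------
# Spearman

def spearman(x, y, exact_limit: int = 9) -> TestResult:
    """Spearman rho on mid-ranks; exact permutation p for n ≤ limit.

    The exact null permutes one rank vector against the other and counts
    |rho| at least as extreme; beyond the limit the t approximation is
    used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    rx = _ss.rankdata(x)
    ry = _ss.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("rho undefined for a constant sample")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n <= exact_limit:
        from itertools import permutations
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pyc = perms - perms.mean(axis=1, keepdims=True)
        rhos = (pyc @ rxc) / np.sqrt((pyc ** 2).sum(axis=1) * (rxc ** 2).sum())
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return TestResult(rho, p, "spearman (exact)", (n,), True)
    t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho ** 2))
    p = float(2 * _ss.t.sf(abs(t), n - 2))
    return TestResult(rho, min(1.0, p), "spearman (t approx)", (n,), False)
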