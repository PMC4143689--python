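"""Overlap analysis between top-SNP lists of two subgroups.

Under the null hypothesis that the truly associated SNPs are the same in
both subgroups (e.g. younger and older individuals), finding completely
disjoint top lists would be surprising.  The chance of that is quantified
in three steps: (1) invert the Benjamini-Hochberg inequality
p_k <= (k/m) q* at the k-th smallest permutation p-value to estimate the
false discovery rate of each group's selection; (2) convert to expected
true positives, TP = round((1 - FDR) * k); (3) compute the hypergeometric
probability that t2 draws from T truly associated SNPs avoid all t1 found
by the other group, C(T - t1, t2) / C(T, t2).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .scan import ScanTable

__all__ = ["OverlapAnalysis", "bh_fdr_at_k", "expected_tp",
           "p_zero_overlap", "first_overlap", "compare_subgroups"]


def bh_fdr_at_k(pvalues: np.ndarray, k: int, m: int) -> float:
    """Implied FDR of selecting the k smallest of m permutation p-values.

    Inverts p_k <= (k/m) q* at the k-th ranked p-value: q_hat = p_k * m / k,
    capped at 1.  ``pvalues`` must be sorted ascending and cover at least
    the first k tests (the untested remainder of the m tests may be
    omitted).
    """
    p = np.asarray(pvalues, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > p.size:
        raise ValueError(f"k={k} exceeds the {p.size} supplied p-values")
    if np.any(np.diff(p) < 0):
        raise ValueError("p-values must be sorted ascending")
    return min(1.0, float(p[k - 1]) * m / k)


def expected_tp(k: int, fdr: float) -> int:
    """Expected true positives among k selections, round half away from 0."""
    if not 0.0 <= fdr <= 1.0:
        raise ValueError("fdr must be in [0, 1]")
    return int(math.floor((1.0 - fdr) * k + 0.5))


def p_zero_overlap(T: int, t1: int, t2: int) -> float:
    """Probability that two TP sets drawn from T true SNPs are disjoint.

    Hypergeometric P(X = 0) with population T, t1 marked successes and t2
    draws: C(T - t1, t2) / C(T, t2), evaluated through log-gamma so large
    T does not overflow.  Symmetric in (t1, t2); returns 0 when t1 + t2
    exceeds T (pigeonhole).
    """
    if min(T, t1, t2) < 0 or t1 > T or t2 > T:
        raise ValueError("need 0 <= t1, t2 <= T")
    if t1 + t2 > T:
        return 0.0
    if t1 == 0 or t2 == 0:
        return 1.0

    def logc(n: int, r: int) -> float:
        return float(gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1))

    return float(np.exp(logc(T - t1, t2) - logc(T, t2)))


def first_overlap(
    ids_a: list[str], ids_b: list[str]
) -> tuple[int, int] | None:
    """Ranks (1-based) of the first SNP shared by two ranked lists.

    Scans the joint rank frontier: at step r the top-r of both lists are
    compared, so the returned pair minimizes max(rank_a, rank_b).  Returns
    None when the lists share nothing.
    """
    pos_a = {s: i + 1 for i, s in enumerate(ids_a)}
    pos_b = {s: i + 1 for i, s in enumerate(ids_b)}
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    best: tuple[int, int] | None = None
    for r in range(max(len(ids_a), len(ids_b))):
        for ids, seen, other_seen in (
            (ids_a, seen_a, seen_b),
            (ids_b, seen_b, seen_a),
        ):
            if r < len(ids):
                s = ids[r]
                seen.add(s)
                if s in other_seen:
                    cand = (pos_a[s], pos_b[s])
                    if best is None or max(cand) < max(best):
                        best = cand
        if best is not None and max(best) <= r + 1:
            return best
    return best


@dataclass
class OverlapAnalysis:
    """FDR-based expected-TP accounting and the zero-overlap probability."""

    m: int                      # total number of tests (SNPs scanned)
    alpha: float                # p-value cutoff defining each selection
    k1: int                     # selected SNP count, group 1
    k2: int                     # selected SNP count, group 2
    fdr1: float
    fdr2: float
    tp1: int
    tp2: int
    T: int                      # assumed number of truly associated SNPs
    p_no_overlap: float
    first_overlap_ranks: tuple[int, int] | None = None


def compare_subgroups(
    t_young: ScanTable,
    t_old: ScanTable,
    T: int,
    alpha: float = 1e-4,
    m: int | None = None,
    top_k: int | None = None,
) -> OverlapAnalysis:
    """Full overlap analysis of two subgroup scans over the same SNPs.

    Selections are the SNPs with permutation p-value <= ``alpha`` in each
    group; ``m`` defaults to the number of SNPs scanned.  ``top_k`` limits
    the ranked lists used for the first-overlap search.  A group with an
    empty selection contributes zero expected TPs (its FDR is undefined
    and reported as NaN).
    """
    a_ids = t_young.ranked()["snp_id"].tolist()
    b_ids = t_old.ranked()["snp_id"].tolist()
    if set(t_young.rows["snp_id"]) != set(t_old.rows["snp_id"]):
        raise ValueError("the two scans cover different SNP universes")
    if top_k is not None:
        a_ids, b_ids = a_ids[:top_k], b_ids[:top_k]
    fo = first_overlap(a_ids, b_ids)

    if m is None:
        m = len(t_young.rows)

    def group_stats(t: ScanTable) -> tuple[int, float, int]:
        p = np.sort(
            t.rows["p_perm"].dropna().to_numpy(dtype=float), kind="stable"
        )
        k = int(np.sum(p <= alpha))
        if k == 0:
            return 0, float("nan"), 0
        fdr = bh_fdr_at_k(p, k, m)
        return k, fdr, expected_tp(k, fdr)

    k1, fdr1, tp1 = group_stats(t_young)
    k2, fdr2, tp2 = group_stats(t_old)
    return OverlapAnalysis(
        m=m, alpha=alpha, k1=k1, k2=k2, fdr1=fdr1, fdr2=fdr2,
        tp1=tp1, tp2=tp2, T=T,
        p_no_overlap=p_zero_overlap(T, tp1, tp2),
        first_overlap_ranks=fo,
    )
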