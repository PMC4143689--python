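"""Dichotomization of a continuous covariate by exact 1-D two-means.

In one dimension the 2-means optimum is separable at a breakpoint of the
sorted values, so instead of running Lloyd iterations from random starts we
enumerate every breakpoint between consecutive distinct values and take the
within-cluster sum of squares minimizer.  The result is deterministic and
exactly optimal.  The reported cutoff is the largest value of the lower
cluster, so the labelling rule is "value > cutoff -> 1" (an age cutoff of
55 labels the over-55 group 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Dichotomy", "two_means_dichotomize"]


@dataclass
class Dichotomy:
    """A binary split of a continuous covariate."""

    cutoff: float
    labels: np.ndarray
    rule: str = "value > cutoff -> 1"
    wss: float = float("nan")


def two_means_dichotomize(v: np.ndarray) -> Dichotomy:
    """Split ``v`` into two groups by exact 1-D 2-means clustering.

    Returns per-sample labels in {0, 1} (1 = upper cluster) and the cutoff
    in covariate units.  Requires at least two distinct finite values.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if np.isnan(v).any():
        raise ValueError("missing values must be removed before clustering")
    s = np.sort(v)
    n = s.size
    if n < 2 or s[0] == s[-1]:
        raise ValueError("degenerate-environment: need >= 2 distinct values")

    # prefix sums give each candidate split's WSS in O(1)
    c1 = np.concatenate([[0.0], np.cumsum(s)])
    c2 = np.concatenate([[0.0], np.cumsum(s**2)])
    ks = np.arange(1, n)  # lower cluster = s[:k]
    valid = s[ks - 1] != s[ks]
    lo = c2[ks] - c1[ks] ** 2 / ks
    hi = (c2[n] - c2[ks]) - (c1[n] - c1[ks]) ** 2 / (n - ks)
    wss = np.where(valid, lo + hi, np.inf)
    k = int(ks[np.argmin(wss)])
    cutoff = float(s[k - 1])
    labels = (v > cutoff).astype(int)
    return Dichotomy(cutoff=cutoff, labels=labels, wss=float(np.min(wss)))
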