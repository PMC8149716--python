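"""Jenks natural-breaks classification by exact Fisher-Jenks dynamic programming.

The one-dimensional "natural breaks" problem asks for the partition of a
sorted value multiset into k contiguous classes minimizing the total
within-class sum of squared deviations (SSD).  Its quality is reported as
the goodness-of-variance fit, gvf = 1 - SSD_within / SSD_total.

The optimum never splits tied values, so the DP runs over the *unique*
sorted values weighted by their multiplicities — ties are kept together by
construction and the result is exact for the full multiset.  The interval
SSD cost satisfies the quadrangle inequality, so each DP layer is computed
with divide-and-conquer monotone minimization in O(u log u) for u unique
values; populations beyond ``max_sample`` are reduced by a seeded uniform
subsample, recorded in the result.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["ClassBreaks", "jenks_breaks"]


@dataclasses.dataclass(frozen=True)
class ClassBreaks:
    """Fitted natural breaks: interior break values and fit diagnostics.

    ``breaks`` holds the k-1 interior boundaries, each the maximum data
    value of its (lower) class, strictly ascending.  ``gvf`` is the
    goodness-of-variance fit in [0, 1]; ``sample_size`` the number of values
    the fit actually used.
    """

    k: int
    breaks: tuple[float, ...]
    gvf: float
    sample_size: int

    def __post_init__(self) -> None:
        if len(self.breaks) != self.k - 1:
            raise ValueError("need exactly k-1 interior breaks")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly ascending")


def _interval_ssd(prefix_w, prefix_s, prefix_q, i, j):
    """Weighted SSD of unique-value interval [i, j) from prefix sums."""
    w = prefix_w[j] - prefix_w[i]
    s = prefix_s[j] - prefix_s[i]
    q = prefix_q[j] - prefix_q[i]
    return q - s * s / w


def _dp_layer(prev, pw, ps, pq, m):
    """One Fisher-Jenks DP layer via divide-and-conquer minimization.

    ``prev[i]`` is the optimal cost of splitting the first i unique values
    into m-1 classes; returns (cost, argmin) arrays over right endpoints j,
    exploiting that the optimal split index is nondecreasing in j.
    """
    u = len(pw) - 1
    cur = np.full(u + 1, np.inf)
    arg = np.zeros(u + 1, dtype=np.int64)
    # valid right endpoints j = m..u; split i in [m-1, j-1]
    stack = [(m, u, m - 1, u - 1)]
    while stack:
        jlo, jhi, ilo, ihi = stack.pop()
        if jlo > jhi:
            continue
        j = (jlo + jhi) // 2
        cand = np.arange(ilo, min(ihi, j - 1) + 1)
        costs = prev[cand] + _interval_ssd(pw, ps, pq, cand, j)
        b = int(np.argmin(costs))
        cur[j] = costs[b]
        best = int(cand[b])
        arg[j] = best
        stack.append((jlo, j - 1, ilo, best))
        stack.append((j + 1, jhi, best, ihi))
    return cur, arg


def jenks_breaks(
    values, k: int = 3, max_sample: int = 100_000, seed: int = 0
) -> ClassBreaks:
    """Fit k natural breaks to a finite value multiset.

    Exact when the (possibly subsampled) population has at most
    ``max_sample`` values; otherwise a uniform subsample of that size drawn
    with ``seed`` is fitted instead.  Requires at least k distinct values.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size > max_sample:
        rng = np.random.default_rng(seed)
        v = rng.choice(v, size=max_sample, replace=False)
    n = v.size
    uniq, counts = np.unique(v, return_counts=True)
    u = uniq.size
    if u < k:
        raise ValueError(f"need at least k={k} distinct values, got {u}")

    w = counts.astype(np.float64)
    pw = np.concatenate([[0.0], np.cumsum(w)])
    ps = np.concatenate([[0.0], np.cumsum(w * uniq)])
    pq = np.concatenate([[0.0], np.cumsum(w * uniq * uniq)])

    total_ssd = _interval_ssd(pw, ps, pq, 0, u)

    # layer 1: one class over [0, j)
    js = np.arange(1, u + 1)
    layer = np.full(u + 1, np.inf)
    layer[1:] = _interval_ssd(pw, ps, pq, np.zeros(u, dtype=np.int64), js)
    layers = [layer]
    args = [np.zeros(u + 1, dtype=np.int64)]
    for m in range(2, k + 1):
        cur, arg = _dp_layer(layers[-1], pw, ps, pq, m)
        layers.append(cur)
        args.append(arg)

    within = float(layers[k - 1][u])
    # backtrack the class boundaries (indices into uniq, half-open)
    bounds = [u]
    j = u
    for m in range(k, 1, -1):
        j = int(args[m - 1][j])
        bounds.append(j)
    bounds = bounds[::-1]  # k-1 interior boundaries then u

    breaks = tuple(float(uniq[b - 1]) for b in bounds[:-1])
    gvf = 1.0 if total_ssd == 0 else 1.0 - within / float(total_ssd)
    return ClassBreaks(k=k, breaks=breaks, gvf=min(max(gvf, 0.0), 1.0), sample_size=int(n))
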