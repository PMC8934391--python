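"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a result through a different route than the
implementation (enumeration, pure-python arithmetic, Monte-Carlo
resampling) and shares no helpers with the package.
"""

import itertools
import math
import statistics

import numpy as np
import pandas as pd

from srnatlas.enrichment import (
    GROUP_ENRICHED,
    NOT_ELEVATED,
    TISSUE_ENHANCED,
    TISSUE_ENRICHED,
)


def oracle_classify(expr: pd.Series, fold: float, cutoff: float, max_group: int):
    """Classify by enumerating every candidate tissue and tissue subset.

    Returns (category, tissue set) — for group-enriched, the list of all
    qualifying subsets of the smallest qualifying size.
    """
    tissues = list(expr.index)
    for t in tissues:
        others = expr.drop(t)
        if expr[t] > cutoff and expr[t] >= fold * others.max():
            return TISSUE_ENRICHED, frozenset({t})
    for g in range(2, max_group + 1):
        qualifying = []
        for subset in itertools.combinations(tissues, g):
            inside = expr[list(subset)]
            outside = expr.drop(list(subset))
            if inside.min() > cutoff and inside.min() >= fold * outside.max():
                qualifying.append(frozenset(subset))
        if qualifying:
            return GROUP_ENRICHED, qualifying
    for t in tissues:
        others = expr.drop(t)
        if expr[t] > cutoff and expr[t] >= fold * others.mean():
            return TISSUE_ENHANCED, frozenset({t})
    return NOT_ELEVATED, frozenset()


def brute_force_median_of_ratios(counts: list[list[int]]) -> list[float]:
    """Pure-python median-of-ratios with no shared code path."""
    n_cols = len(counts[0])
    ratios = [[] for _ in range(n_cols)]
    for row in counts:
        if all(c > 0 for c in row):
            gm = math.exp(sum(math.log(c) for c in row) / n_cols)
            for j, c in enumerate(row):
                ratios[j].append(c / gm)
    if not ratios[0]:
        raise ValueError("no all-positive row")
    return [statistics.median(r) for r in ratios]


def monte_carlo_richness(rng, counts, depth, n_draws=20_000):
    """Subsampling oracle: mean richness over hypergeometric draws."""
    draws = rng.multivariate_hypergeometric(np.asarray(counts), depth, size=n_draws)
    richness = (draws > 0).sum(axis=1)
    return richness.mean(), richness.std(ddof=1) / np.sqrt(n_draws)


def bh_oracle(p):
    """Hand-rolled BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = q_sorted[rank]
    return out
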