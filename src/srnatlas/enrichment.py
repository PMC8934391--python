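"""Tissue-specificity classification (Human Protein Atlas categories).

Every sequence (or gene) with a per-tissue expression profile is placed
into exactly one of four mutually exclusive categories, evaluated in
order:

1. ``tissue_enriched`` — expression in one tissue above the expression
   cutoff and at least ``fold`` times the maximum over all other tissues;
2. ``group_enriched`` — the smallest group of 2..``max_group`` tissues
   (necessarily the top tissues by expression) all above the cutoff, with
   the group's minimum at least ``fold`` times the maximum outside the
   group;
3. ``tissue_enhanced`` — expression in one tissue above the cutoff and at
   least ``fold`` times the *mean* of all other tissues, without meeting
   either criterion above;
4. ``not_elevated`` — everything else, including profiles high
   everywhere with no qualifying fold ("All"-specificity rows).

The union of the first three categories is called *tissue-elevated*.

The fold threshold defaults to 7; 5 is the original HPA definitional
value ("at least five-fold") and both are exposed through the same
parameter.  Fold comparisons are inclusive (``>=``); expression-cutoff
comparisons are strict (``>``).  Ties in expression are resolved
deterministically (lexicographic tissue name) and can only move a
profile toward ``not_elevated``, never into a higher category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import NormalizedMatrix, PipelineConfig

TISSUE_ENRICHED = "tissue_enriched"
GROUP_ENRICHED = "group_enriched"
TISSUE_ENHANCED = "tissue_enhanced"
NOT_ELEVATED = "not_elevated"

CATEGORIES = (TISSUE_ENRICHED, GROUP_ENRICHED, TISSUE_ENHANCED, NOT_ELEVATED)

ELEVATED = frozenset({TISSUE_ENRICHED, GROUP_ENRICHED, TISSUE_ENHANCED})


@dataclass(frozen=True)
class TissueProfile:
    """Per-tissue mean expression of one sequence or gene."""

    id: str
    expression: pd.Series  # index: tissue names, values: mean normalized counts

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            raise ValueError(f"{self.id}: duplicate tissue names")
        vals = self.expression.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError(f"{self.id}: expression must be finite and >= 0")


@dataclass(frozen=True)
class EnrichmentCall:
    """The category, defining tissue set and fold change of one profile."""

    id: str
    category: str
    tissues: frozenset[str]
    fold_change: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category in (TISSUE_ENRICHED, TISSUE_ENHANCED) and len(self.tissues) != 1:
            raise ValueError(f"{self.category} requires exactly one tissue")
        if self.category == NOT_ELEVATED and self.tissues:
            raise ValueError("not_elevated carries no tissue set")

    @property
    def elevated(self) -> bool:
        return self.category in ELEVATED


def _ratio(num: float, den: float) -> float:
    return math.inf if den == 0 else num / den


def classify_profile(
    profile: TissueProfile,
    fold: float = 7.0,
    cutoff: float = 1.0,
    max_group: int = 4,
) -> EnrichmentCall:
    """Classify one expression profile into the four categories above."""
    expr = profile.expression
    n = len(expr)
    if n < max_group + 1:
        raise ValueError(
            f"{profile.id}: need at least max_group+1 = {max_group + 1} tissues, "
            f"got {n} (the outside-group set would be empty)"
        )
    # Deterministic order: descending expression, lexicographic tissue name.
    order = sorted(expr.index, key=lambda t: (-expr[t], t))
    values = np.array([expr[t] for t in order], dtype=float)

    # 1. tissue-enriched: only the top tissue can qualify.
    top, second = values[0], values[1]
    if top > cutoff and top >= fold * second:
        return EnrichmentCall(
            profile.id, TISSUE_ENRICHED, frozenset({order[0]}), _ratio(top, second)
        )

    # 2. group-enriched: smallest qualifying top-g group, g in 2..max_group.
    #    A qualifying group must consist of the top-g tissues: any excluded
    #    tissue with expression above an included one would break the
    #    group-min >= fold * outside-max requirement.
    for g in range(2, max_group + 1):
        group_min = values[g - 1]
        rest_max = values[g]
        if group_min > cutoff and group_min >= fold * rest_max:
            return EnrichmentCall(
                profile.id,
                GROUP_ENRICHED,
                frozenset(order[:g]),
                _ratio(group_min, rest_max),
            )

    # 3. tissue-enhanced: best qualifying tissue vs the mean of the others.
    total = float(values.sum())
    for i, tissue in enumerate(order):
        v = values[i]
        if v <= cutoff:
            break  # sorted: no later tissue can clear the cutoff
        mean_others = (total - v) / (n - 1)
        if v >= fold * mean_others:
            return EnrichmentCall(
                profile.id, TISSUE_ENHANCED, frozenset({tissue}), _ratio(v, mean_others)
            )

    return EnrichmentCall(profile.id, NOT_ELEVATED, frozenset(), 0.0)


def classify_sequence(
    profile: TissueProfile,
    fold: float = 7.0,
    cutoff: float = 1.0,
    max_group: int = 4,
) -> EnrichmentCall:
    """Alias of :func:`classify_profile` (sequences and genes classify alike)."""
    return classify_profile(profile, fold=fold, cutoff=cutoff, max_group=max_group)


def tissue_means(normalized: NormalizedMatrix) -> pd.DataFrame:
    """Average replicate columns per source: rows ids, columns tissues."""
    meta = normalized.sample_meta
    groups = {
        source: list(g.index) for source, g in meta.groupby("source")
    }
    return pd.DataFrame(
        {source: normalized.normalized[cols].mean(axis=1) for source, cols in groups.items()}
    )


def classify_matrix(
    normalized: NormalizedMatrix,
    config: PipelineConfig | None = None,
) -> list[EnrichmentCall]:
    """Average replicates per tissue, then classify every row.

    Rows expressed above the cutoff in every tissue without a qualifying
    fold come out ``not_elevated`` (the "All"-specificity removal).
    """
    if config is None:
        config = PipelineConfig()
    means = tissue_means(normalized)
    return [
        classify_profile(
            TissueProfile(str(idx), row),
            fold=config.fold_change_threshold,
            cutoff=config.expression_cutoff,
            max_group=config.max_group_size,
        )
        for idx, row in means.iterrows()
    ]


def elevated_sets(calls: list[EnrichmentCall]) -> dict[str, set[str]]:
    """Union the three elevated categories into per-tissue sequence sets.

    A group-enriched sequence appears in the set of *every* tissue in its
    group (shared sequences are counted for each tissue); not-elevated
    sequences appear nowhere.
    """
    out: dict[str, set[str]] = {}
    for call in calls:
        if not call.elevated:
            continue
        for tissue in call.tissues:
            out.setdefault(tissue, set()).add(call.id)
    return out


def calls_to_frame(calls: list[EnrichmentCall]) -> pd.DataFrame:
    """Tabulate calls as (id, category, tissues ';'-joined, fold_change)."""
    return pd.DataFrame(
        {
            "id": [c.id for c in calls],
            "category": [c.category for c in calls],
            "tissues": [";".join(sorted(c.tissues)) for c in calls],
            "fold_change": [c.fold_change for c in calls],
        }
    )


def frame_to_calls(df: pd.DataFrame) -> list[EnrichmentCall]:
    calls = []
    for rec in df.itertuples(index=False):
        tissues = frozenset(t for t in str(rec.tissues).split(";") if t and t != "nan")
        calls.append(
            EnrichmentCall(str(rec.id), rec.category, tissues, float(rec.fold_change))
        )
    return calls
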