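"""Biofluid detection, tissue attribution, diversity, rarefaction, DE joins.

The "direct" tissue-attribution approach: detect sequences in a biofluid
(same rule as biofluid filtering), intersect the detected set with each
tissue's tissue-elevated set, and report per tissue the number of
detected elevated sequences, the sum of their mean normalized counts in
the biofluid, and that sum as a fraction of the grand total.  A sequence
elevated in several tissues contributes to each of them (double counting
is deliberate and makes fractions sum to one); an alternative
denominator — total detected reads, without double counting — is
available via ``shared_denominator=False``.

Diversity distinguishes *sequence diversity* (unique sequences above a
normalized-expression cutoff) from *gene diversity* (parent genes above
the cutoff after collapsing their isoforms); rarefaction gives the exact
hypergeometric expectation of richness at a reduced depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .enrichment import EnrichmentCall, NOT_ELEVATED
from .filters import filter_biofluid
from .model import CountMatrix, NormalizedMatrix, PipelineConfig, logger


@dataclass
class AttributionResult:
    """Per-tissue detection counts and read fractions in one biofluid."""

    biofluid: str
    table: pd.DataFrame  # index tissue; columns n_detected_sequences, read_sum, read_fraction

    def to_frame(self) -> pd.DataFrame:
        out = self.table.reset_index(names="tissue")
        out.insert(0, "biofluid", self.biofluid)
        return out


@dataclass
class DiversityReport:
    """Sequence vs gene diversity per source at a normalized cutoff."""

    table: pd.DataFrame  # index source; columns gene_diversity, sequence_diversity
    cutoff: float


def detect_in_biofluid(
    matrix: CountMatrix, config: PipelineConfig | None = None
) -> set[str]:
    """Sequences passing the biofluid detection rule, as an id set."""
    if config is None:
        config = PipelineConfig()
    kept, _ = filter_biofluid(
        matrix, config.biofluid_min_count, config.biofluid_min_fraction
    )
    return set(kept.sequences)


def attribute(
    detected: set[str],
    elevated: Mapping[str, set[str]],
    mean_counts: Mapping[str, float],
    biofluid: str = "biofluid",
    shared_denominator: bool = True,
) -> AttributionResult:
    """Attribute detected biofluid sequences to tissue-elevated sets.

    ``mean_counts`` maps each detected sequence to its mean normalized
    count over the biofluid's samples.
    """
    missing = [s for s in detected if s not in mean_counts]
    if missing:
        raise ValueError(f"mean_counts missing for detected sequence(s): {missing[:5]}")
    rows = {}
    for tissue, seqs in elevated.items():
        hit = detected & seqs
        rows[tissue] = {
            "n_detected_sequences": len(hit),
            "read_sum": float(sum(mean_counts[s] for s in hit)),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(
        sorted(rows), fill_value=0
    )
    if table.empty:
        table = pd.DataFrame(columns=["n_detected_sequences", "read_sum", "read_fraction"])
        return AttributionResult(biofluid, table)
    if shared_denominator:
        denom = float(table["read_sum"].sum())
    else:
        attributed = set().union(*(detected & s for s in elevated.values()))
        denom = float(sum(mean_counts[s] for s in attributed))
    if denom == 0:
        logger.warning("attribute: no tissue-elevated reads detected in %s", biofluid)
        table["read_fraction"] = 0.0
    else:
        table["read_fraction"] = table["read_sum"] / denom
    table.index.name = "tissue"
    return AttributionResult(biofluid, table)


def diversity(
    normalized: NormalizedMatrix, cutoff: float = 10.0
) -> DiversityReport:
    """Per-source sequence and gene diversity above a normalized cutoff.

    Gene diversity can exceed what its sequences show individually:
    collapsing can push a parent gene over a cutoff that every one of its
    isoforms misses.
    """
    meta = normalized.sample_meta
    genes = normalized.row_meta["parent_gene"]
    rows = {}
    for source, g in meta.groupby("source"):
        mean = normalized.normalized[list(g.index)].mean(axis=1)
        gene_expr = mean.groupby(genes).sum()
        rows[source] = {
            "gene_diversity": int((gene_expr > cutoff).sum()),
            "sequence_diversity": int((mean > cutoff).sum()),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "source"
    return DiversityReport(table, cutoff)


def rarefaction(counts, depth: int) -> float:
    """Expected richness when subsampling ``depth`` reads without replacement.

    E[S_d] = sum_i (1 - C(N - n_i, d) / C(N, d)) with N the total count;
    binomial coefficients are evaluated in log space.
    """
    n = np.asarray(counts, dtype=np.int64)
    if (n < 0).any():
        raise ValueError("counts must be >= 0")
    n = n[n > 0]
    total = int(n.sum())
    if not 0 <= depth <= total:
        raise ValueError(f"depth {depth} outside [0, {total}]")
    if depth == 0:
        return 0.0

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rest = total - n  # reads not belonging to species i
    p_absent = np.zeros(len(n))
    feasible = rest >= depth  # otherwise species i is certainly sampled
    p_absent[feasible] = np.exp(
        log_choose(rest[feasible], depth) - log_choose(total, depth)
    )
    return float(np.sum(1.0 - p_absent))


def rarefaction_curve(counts, depths) -> pd.Series:
    """Expected richness at each requested depth."""
    return pd.Series({int(d): rarefaction(counts, int(d)) for d in depths})


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotate_de(
    de_table: pd.DataFrame,
    calls: list[EnrichmentCall],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Join a differential-expression table to tissue-elevation calls.

    ``de_table`` needs columns (sequence, log2fc, pvalue); a ``padj``
    column, if present, is passed through (flagged in the log), otherwise
    BH adjustment is computed here.  Each significant record
    (padj < alpha) is labeled with its elevation category and tissues, or
    ``not_elevated`` when absent from the calls.
    """
    required = {"sequence", "log2fc", "pvalue"}
    missing = required - set(de_table.columns)
    if missing:
        raise ValueError(f"de_table missing columns {sorted(missing)}")
    if de_table["sequence"].duplicated().any():
        dups = de_table["sequence"][de_table["sequence"].duplicated()].tolist()
        raise ValueError(f"duplicate sequence ids in de_table: {dups[:5]}")
    out = de_table.copy()
    if "padj" in out.columns:
        logger.info("annotate_de: using pre-adjusted p-values from input")
    else:
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = out["padj"] < alpha
    by_id = {c.id: c for c in calls}
    cats, tissues = [], []
    for seq in out["sequence"]:
        call = by_id.get(seq)
        if call is None or not call.elevated:
            cats.append(NOT_ELEVATED)
            tissues.append("")
        else:
            cats.append(call.category)
            tissues.append(";".join(sorted(call.tissues)))
    out["elevation_category"] = cats
    out["elevation_tissues"] = tissues
    return out
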