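"""Detection filters and median-of-ratios normalization.

Two detection rules are used, both with strict inequalities:

* tissues / blood cells — keep a sequence if, in at least one source,
  strictly more than ``min_count`` (default 25) reads are observed in at
  least ``min_replicates`` (default 2) of that source's replicates.  The
  one-source-suffices reading deliberately retains sequences expressed in
  a single tissue.
* biofluids — keep a sequence iff the fraction of samples with count
  strictly above ``min_count`` (default 10) strictly exceeds
  ``min_fraction`` (default 0.5).

Normalization is the median-of-ratios method: the per-row reference is
the geometric mean across samples, computed only over rows with no zero
count; a sample's size factor is the median of its count/reference ratios
over those rows, and normalized counts are raw counts divided by the
sample's factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CountMatrix, NormalizedMatrix, logger


@dataclass
class FilterReport:
    """Which rows a detection rule kept, and why."""

    n_input_rows: int
    n_kept_rows: int
    rule: str
    keep: pd.Series  # bool per input row

    def __post_init__(self) -> None:
        if self.n_kept_rows > self.n_input_rows:
            raise ValueError("kept more rows than provided")
        if int(self.keep.sum()) != self.n_kept_rows:
            raise ValueError("keep flags inconsistent with n_kept_rows")


def filter_tissue(
    matrix: CountMatrix,
    min_count: int = 25,
    min_replicates: int = 2,
) -> tuple[CountMatrix, FilterReport]:
    """Apply the tissue detection rule (see module docstring)."""
    meta = matrix.sample_meta
    bad = meta[~meta["source_class"].isin(["tissue", "blood_cell"])]
    if len(bad):
        raise ValueError(
            f"filter_tissue expects tissue/blood_cell columns; got "
            f"{sorted(set(bad['source_class']))}"
        )
    keep = pd.Series(False, index=matrix.counts.index)
    for source, group in meta.groupby("source"):
        cols = list(group.index)
        needed = min_replicates
        if len(cols) < min_replicates:
            logger.warning(
                "source %r has %d replicate(s), fewer than min_replicates=%d; "
                "evaluating against available replicates",
                source, len(cols), min_replicates,
            )
            needed = len(cols)
        over = (matrix.counts[cols] > min_count).sum(axis=1)
        keep |= over >= needed
    kept = matrix.subset_rows(matrix.counts.index[keep])
    report = FilterReport(
        n_input_rows=len(matrix.counts),
        n_kept_rows=len(kept.counts),
        rule=f">{min_count} counts in >= {min_replicates} replicates of some source",
        keep=keep,
    )
    logger.info("filter_tissue: kept %d / %d rows", report.n_kept_rows, report.n_input_rows)
    return kept, report


def filter_biofluid(
    matrix: CountMatrix,
    min_count: int = 10,
    min_fraction: float = 0.5,
) -> tuple[CountMatrix, FilterReport]:
    """Apply the biofluid detection rule (see module docstring)."""
    n_samples = len(matrix.samples)
    if n_samples == 0 or len(matrix.counts) == 0:
        keep = pd.Series(False, index=matrix.counts.index, dtype=bool)
    else:
        frac = (matrix.counts > min_count).sum(axis=1) / n_samples
        keep = frac > min_fraction
    kept = matrix.subset_rows(matrix.counts.index[keep])
    report = FilterReport(
        n_input_rows=len(matrix.counts),
        n_kept_rows=len(kept.counts),
        rule=f">{min_count} counts in >{min_fraction:.0%} of samples",
        keep=keep,
    )
    logger.info("filter_biofluid: kept %d / %d rows", report.n_kept_rows, report.n_input_rows)
    return kept, report


def median_of_ratios(matrix: CountMatrix) -> NormalizedMatrix:
    """Median-of-ratios size factors and normalized counts.

    Reference rows are those with all counts > 0 (a zero anywhere removes
    the row from the reference, not from the output).  With an even
    number of reference rows the median is the mean of the two central
    ratios.  A single-sample matrix gets size factor 1 with a warning.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    cols = matrix.counts.columns
    if counts.shape[1] < 2:
        logger.warning("median_of_ratios: single sample; size factor set to 1")
        factors = pd.Series(1.0, index=cols)
    else:
        allpos = (counts > 0).all(axis=1)
        if not allpos.any():
            raise ValueError("no reference features: every row contains a zero count")
        ref_rows = counts[allpos]
        log_ref = np.mean(np.log(ref_rows), axis=1)  # log geometric mean per row
        ratios = ref_rows / np.exp(log_ref)[:, None]
        factors = pd.Series(np.median(ratios, axis=0), index=cols)
    normalized = matrix.counts.astype(float).div(factors, axis=1)
    return NormalizedMatrix(
        normalized=normalized,
        size_factors=factors,
        row_meta=matrix.row_meta.copy(),
        samples=list(matrix.samples),
    )
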