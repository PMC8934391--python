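"""Core domain types, tab-separated I/O, configuration and logging.

The unit of analysis throughout this package is the *unique small-RNA
sequence*: an adapter-trimmed read sequence taken verbatim (isomiRs and
RNA fragments are therefore first-class rows, not collapsed into their
canonical parent).  A dataset is a counts table of unique sequences by
samples, where each sample carries a source (tissue, blood-cell type or
biofluid), a source class and a replicate index.

All tabular artifacts are flat, diff-able TSV: a count matrix has the
columns ``sequence``, ``biotype``, ``parent_gene`` followed by one column
per sample; sample metadata has ``sample_id``, ``source``,
``source_class``, ``replicate``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("srnatlas")

#: RNA classes recognised by the pipeline, in the default multi-mapper
#: priority order (most specific/abundant small-RNA classes first).
BIOTYPES: tuple[str, ...] = (
    "miRNA",
    "YRNA",
    "tRNA",
    "piRNA",
    "protein_coding",
    "other",
)

SOURCE_CLASSES = ("tissue", "blood_cell", "biofluid")

_SEQ_ALPHABET = set("ACGTN")

#: Bounds on plausible small-RNA sequence length (nt).
MIN_SEQ_LEN = 15
MAX_SEQ_LEN = 50


def setup_logging(level: str = "INFO") -> None:
    """Configure structured logging to stderr (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: its source and replicate index."""

    sample_id: str
    source: str
    source_class: str
    replicate: int

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.source:
            raise ValueError(f"sample {self.sample_id!r}: source must be non-empty")
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(
                f"sample {self.sample_id!r}: source_class {self.source_class!r} "
                f"not one of {SOURCE_CLASSES}"
            )
        if int(self.replicate) < 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate must be >= 1")


@dataclass(frozen=True)
class SequenceAnnotation:
    """A unique sequence with its resolved biotype and parent gene.

    ``is_canonical`` marks the reference mature sequence of the parent
    gene; every other family member is an isomiR / fragment.
    """

    sequence: str
    biotype: str
    parent_gene: str
    is_canonical: bool = False

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if not self.parent_gene:
            raise ValueError("parent_gene must be non-empty")


def validate_sequence(seq: str, min_len: int = MIN_SEQ_LEN, max_len: int = MAX_SEQ_LEN) -> None:
    if not seq or set(seq) - _SEQ_ALPHABET:
        raise ValueError(f"sequence {seq!r} contains characters outside ACGTN")
    if not (min_len <= len(seq) <= max_len):
        raise ValueError(
            f"sequence length {len(seq)} outside small-RNA range [{min_len}, {max_len}]"
        )


class CountMatrix:
    """Unique sequences x samples matrix of raw integer counts.

    Parameters
    ----------
    counts
        DataFrame indexed by sequence with one integer column per sample.
    row_meta
        DataFrame indexed by sequence with columns ``biotype`` and
        ``parent_gene``.
    samples
        One :class:`SampleMeta` per counts column, in column order.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        row_meta: pd.DataFrame,
        samples: Sequence[SampleMeta],
        validate_sequences: bool = True,
    ) -> None:
        counts = counts.copy()
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sequence rows: {dups[:5]}")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample columns")
        sample_ids = [s.sample_id for s in samples]
        if list(counts.columns) != sample_ids:
            raise ValueError(
                f"counts columns {list(counts.columns)} do not match sample "
                f"metadata ids {sample_ids}"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample_id in metadata")
        for col in counts.columns:
            try:
                arr = np.asarray(pd.to_numeric(counts[col]), dtype=float)
            except (ValueError, TypeError) as exc:
                raise ValueError(f"non-numeric count in column {col!r}: {exc}") from exc
            bad_mask = ~np.isfinite(arr) | (arr != np.floor(arr))
            if bad_mask.any():
                bad = counts.index[bad_mask][0]
                raise ValueError(f"non-integer count at ({bad!r}, {col!r})")
            counts[col] = arr.astype(np.int64)
        neg = counts.lt(0)
        if neg.to_numpy().any():
            r = neg.any(axis=1).idxmax()
            c = neg.loc[r].idxmax()
            raise ValueError(f"negative count at ({r!r}, {c!r}): {counts.loc[r, c]}")
        missing = counts.index.difference(row_meta.index)
        if len(missing):
            raise ValueError(f"rows missing annotation: {list(missing[:5])}")
        if validate_sequences:
            for seq in counts.index:
                validate_sequence(seq)
        self.counts = counts
        self.row_meta = (
            row_meta.loc[counts.index, ["biotype", "parent_gene"]].astype(object)
        )
        bad_bt = set(self.row_meta["biotype"]) - set(BIOTYPES)
        if bad_bt:
            raise ValueError(f"unknown biotypes: {sorted(bad_bt)}")
        self.samples = list(samples)

    # -- convenience views -------------------------------------------------
    @property
    def sequences(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(s) for s in self.samples]
        ).set_index("sample_id")

    def subset_rows(self, keep: Iterable[str]) -> "CountMatrix":
        keep = [s for s in self.sequences if s in set(keep)]
        return CountMatrix(
            self.counts.loc[keep], self.row_meta.loc[keep], self.samples,
            validate_sequences=False,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        wanted = set(sample_ids)
        samples = [s for s in self.samples if s.sample_id in wanted]
        cols = [s.sample_id for s in samples]
        return CountMatrix(self.counts[cols], self.row_meta, samples,
                           validate_sequences=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.row_meta.equals(other.row_meta)
            and self.samples == other.samples
        )

    def __repr__(self) -> str:
        return f"CountMatrix({len(self.counts)} sequences x {len(self.samples)} samples)"


@dataclass
class NormalizedMatrix:
    """Counts divided by per-sample median-of-ratios size factors."""

    normalized: pd.DataFrame
    size_factors: pd.Series
    row_meta: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("all size factors must be > 0")
        if list(self.normalized.columns) != list(self.size_factors.index):
            raise ValueError("size factor index does not match sample columns")

    @property
    def sample_meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(s) for s in self.samples]
        ).set_index("sample_id")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Scalar thresholds of the whole analysis, with their field defaults.

    ``tissue_min_count``/``tissue_min_replicates`` define tissue detection
    (strictly more than 25 reads in at least 2 replicates of some source);
    ``biofluid_min_count``/``biofluid_min_fraction`` define biofluid
    detection (>10 reads in >50% of samples); ``fold_change_threshold`` is
    the elevation fold cutoff (7 as run here; 5 is the original HPA
    definitional value); ``expression_cutoff`` is the minimum normalized
    expression (1) inside an elevated tissue set; ``diversity_cutoff`` is
    the normalized-expression threshold (10) for diversity counting.
    """

    tissue_min_count: int = 25
    tissue_min_replicates: int = 2
    biofluid_min_count: int = 10
    biofluid_min_fraction: float = 0.5
    fold_change_threshold: float = 7.0
    expression_cutoff: float = 1.0
    max_group_size: int = 4
    diversity_cutoff: float = 10.0
    fdr_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "tissue_min_count",
            "tissue_min_replicates",
            "biofluid_min_count",
            "fold_change_threshold",
            "expression_cutoff",
            "diversity_cutoff",
            "fdr_alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_group_size < 2:
            raise ValueError("max_group_size must be >= 2")
        if not (0.0 < self.biofluid_min_fraction < 1.0):
            raise ValueError("biofluid_min_fraction must be in (0, 1)")


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML/JSON key-value config; absent keys take the defaults.

    Every effective value is echoed to the log so a run records the exact
    thresholds it used.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ValueError(f"config {path}: expected a key/value mapping")
        data = dict(loaded)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in data.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValueError(f"config key {key!r}: non-numeric value {value!r}")
    cfg = PipelineConfig(**data)
    for f in dataclasses.fields(cfg):
        logger.info("config %s = %r", f.name, getattr(cfg, f.name))
    return cfg


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "source", "source_class", "replicate"]
_ROW_COLS = ["sequence", "biotype", "parent_gene"]


def read_sample_meta(meta_path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "source": str})
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{meta_path}: missing metadata columns {sorted(missing)}")
    metas = {}
    for rec in df.itertuples(index=False):
        m = SampleMeta(
            sample_id=str(rec.sample_id),
            source=str(rec.source),
            source_class=str(rec.source_class),
            replicate=int(rec.replicate),
        )
        if m.sample_id in metas:
            raise ValueError(f"{meta_path}: duplicate sample_id {m.sample_id!r}")
        metas[m.sample_id] = m
    return metas


def read_count_matrix(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a TSV count matrix plus its sample metadata.

    Raises a hard error naming the offending cell/column on negative or
    non-integer counts, duplicate sequence rows, or a sample column with
    no metadata entry.
    """
    metas = read_sample_meta(meta_path)
    df = pd.read_csv(
        path, sep="\t",
        dtype={"sequence": str, "biotype": str, "parent_gene": str},
    )
    missing = set(_ROW_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sample_cols = [c for c in df.columns if c not in _ROW_COLS]
    unknown = [c for c in sample_cols if c not in metas]
    if unknown:
        raise ValueError(f"{path}: sample column(s) {unknown} absent from metadata")
    df = df.set_index("sequence")
    counts = df[sample_cols]
    samples = [metas[c] for c in sample_cols]
    return CountMatrix(counts, df[["biotype", "parent_gene"]], samples)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV; exact inverse of :func:`read_count_matrix`."""
    out = matrix.row_meta.copy()
    out.insert(0, "sequence", matrix.counts.index)
    out = out.reset_index(drop=True)
    body = matrix.counts.reset_index(drop=True)
    pd.concat([out, body], axis=1).to_csv(path, sep="\t", index=False)


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in samples]).to_csv(
        path, sep="\t", index=False, columns=_META_COLS
    )


def write_normalized_matrix(matrix: NormalizedMatrix, path: str | Path) -> None:
    out = matrix.row_meta.copy()
    out.insert(0, "sequence", matrix.normalized.index)
    out = out.reset_index(drop=True)
    pd.concat([out, matrix.normalized.reset_index(drop=True)], axis=1).to_csv(
        path, sep="\t", index=False
    )


def read_normalized_matrix(path: str | Path, meta_path: str | Path) -> NormalizedMatrix:
    """Read a normalized matrix written by :func:`write_normalized_matrix`.

    Size factors are not serialised alongside the normalized values; the
    reader restores unit factors (the matrix is already on the normalized
    scale).
    """
    metas = read_sample_meta(meta_path)
    df = pd.read_csv(
        path, sep="\t",
        dtype={"sequence": str, "biotype": str, "parent_gene": str},
    ).set_index("sequence")
    sample_cols = [c for c in df.columns if c not in ("biotype", "parent_gene")]
    unknown = [c for c in sample_cols if c not in metas]
    if unknown:
        raise ValueError(f"{path}: sample column(s) {unknown} absent from metadata")
    return NormalizedMatrix(
        normalized=df[sample_cols].astype(float),
        size_factors=pd.Series(1.0, index=sample_cols),
        row_meta=df[["biotype", "parent_gene"]],
        samples=[metas[c] for c in sample_cols],
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
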