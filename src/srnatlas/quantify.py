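"""Collapse adapter-trimmed reads into unique-sequence count tables.

Small-RNA reads are heavy multi-mappers: one trimmed sequence often has
candidate annotations in several RNA classes (a fragment may match both a
tRNA and a piRNA entry, for instance).  Each unique sequence therefore
receives exactly one (parent gene, biotype) annotation, resolved by a
fixed priority order over biotypes — by default
miRNA > YRNA > tRNA > piRNA > protein_coding > other — with ties inside a
biotype broken lexicographically on the gene id (and logged).

Alignment itself is consumed, not performed: each read arrives with an
:class:`AlignmentEvidence` record saying whether it mapped to the genome
and which (gene, biotype) candidates the transcriptome offered.  A small
exact-match annotator against a reference FASTA is provided to build such
evidence for fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .model import (
    BIOTYPES,
    CountMatrix,
    SampleMeta,
    logger,
)


@dataclass(frozen=True)
class ReadRecord:
    """One adapter-trimmed read (5'->3')."""

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")


@dataclass(frozen=True)
class AlignmentEvidence:
    """Genome-mapping flag and transcriptome candidates for one read."""

    read_id: str
    genome_mapped: bool
    candidates: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for gene, biotype in self.candidates:
            if biotype not in BIOTYPES:
                raise ValueError(
                    f"read {self.read_id!r}: unknown candidate biotype {biotype!r}"
                )


class BiotypePriority:
    """A permutation of the six biotypes; earlier wins for multi-mappers."""

    def __init__(self, order: Sequence[str] = BIOTYPES) -> None:
        if sorted(order) != sorted(BIOTYPES):
            raise ValueError(f"priority must be a permutation of {BIOTYPES}")
        self.order = tuple(order)
        self._rank = {b: i for i, b in enumerate(order)}

    def rank(self, biotype: str) -> int:
        return self._rank[biotype]

    def __repr__(self) -> str:
        return f"BiotypePriority({' > '.join(self.order)})"


DEFAULT_PRIORITY = BiotypePriority()


def assign_biotype(
    candidates: Iterable[tuple[str, str]],
    priority: BiotypePriority = DEFAULT_PRIORITY,
) -> tuple[str, str]:
    """Pick the (parent_gene, biotype) whose biotype ranks highest.

    Deterministic under set semantics: candidate order never matters.
    Equal-priority candidates from different genes are resolved
    lexicographically on the gene id (documented choice; logged).
    """
    cands = set(candidates)
    if not cands:
        raise ValueError("unannotated read: empty candidate set")
    best = min(cands, key=lambda gc: (priority.rank(gc[1]), gc[0]))
    same_rank = [gc for gc in cands if priority.rank(gc[1]) == priority.rank(best[1])]
    if len(same_rank) > 1:
        logger.debug(
            "gene tie at biotype %s: %s -> %s (lexicographic)",
            best[1], sorted(g for g, _ in same_rank), best[0],
        )
    return best


def collapse_reads(
    reads: Sequence[ReadRecord],
    evidence: Sequence[AlignmentEvidence],
    priority: BiotypePriority = DEFAULT_PRIORITY,
    sample: SampleMeta | None = None,
) -> CountMatrix:
    """Collapse reads with identical sequences into a one-sample count table.

    Only genome-mapped reads contribute.  The count of a row is the number
    of contributing reads with that exact sequence; the row annotation is
    resolved by :func:`assign_biotype` over the union of candidates across
    the row's reads.
    """
    if sample is None:
        sample = SampleMeta("sample_1", "unknown", "tissue", 1)
    ev_by_read = {e.read_id: e for e in evidence}
    if len(ev_by_read) != len(evidence):
        raise ValueError("duplicate read_id in evidence")
    counts: dict[str, int] = {}
    cand_union: dict[str, set[tuple[str, str]]] = {}
    for read in reads:
        ev = ev_by_read.get(read.read_id)
        if ev is None:
            raise ValueError(f"no alignment evidence for read {read.read_id!r}")
        if not ev.genome_mapped:
            continue
        counts[read.sequence] = counts.get(read.sequence, 0) + 1
        cand_union.setdefault(read.sequence, set()).update(ev.candidates)
    seqs = sorted(counts)
    genes, biotypes = [], []
    for seq in seqs:
        gene, biotype = assign_biotype(cand_union[seq], priority)
        genes.append(gene)
        biotypes.append(biotype)
    counts_df = pd.DataFrame(
        {sample.sample_id: [counts[s] for s in seqs]}, index=pd.Index(seqs, name="sequence")
    )
    row_meta = pd.DataFrame(
        {"biotype": biotypes, "parent_gene": genes}, index=counts_df.index
    )
    return CountMatrix(counts_df, row_meta, [sample])


def collapse_to_genes(matrix: CountMatrix) -> CountMatrix:
    """Sum sequence counts into their parent genes, per sample.

    The gene inherits its sequences' biotype; a gene annotated with two
    different biotypes is an annotation inconsistency and a hard error.
    Per-sample totals are preserved exactly.
    """
    bt_per_gene = matrix.row_meta.groupby("parent_gene")["biotype"].nunique()
    bad = bt_per_gene[bt_per_gene > 1]
    if len(bad):
        raise ValueError(
            f"gene(s) annotated with multiple biotypes: {list(bad.index[:5])}"
        )
    grouped = matrix.counts.groupby(matrix.row_meta["parent_gene"]).sum()
    grouped.index.name = "sequence"
    biotype = matrix.row_meta.groupby("parent_gene")["biotype"].first()
    row_meta = pd.DataFrame(
        {"biotype": biotype.loc[grouped.index].to_numpy(), "parent_gene": grouped.index},
        index=grouped.index,
    )
    return CountMatrix(grouped, row_meta, matrix.samples, validate_sequences=False)


# ---------------------------------------------------------------------------
# File plumbing: reads (FASTA/FASTQ) and evidence TSV
# ---------------------------------------------------------------------------


def read_reads(path: str | Path) -> list[ReadRecord]:
    """Read adapter-trimmed reads from FASTA or FASTQ (by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [
        ReadRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)
    ]


def read_evidence(path: str | Path) -> list[AlignmentEvidence]:
    """Read evidence TSV: read_id, genome_mapped, ``gene:biotype;...``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for rec in df.itertuples(index=False):
        cands = set()
        for token in rec.candidates.split(";"):
            if not token:
                continue
            gene, _, biotype = token.rpartition(":")
            cands.add((gene, biotype))
        out.append(
            AlignmentEvidence(
                read_id=rec.read_id,
                genome_mapped=str(rec.genome_mapped).lower() in {"1", "true", "yes"},
                candidates=frozenset(cands),
            )
        )
    return out


def write_evidence(evidence: Sequence[AlignmentEvidence], path: str | Path) -> None:
    rows = [
        {
            "read_id": e.read_id,
            "genome_mapped": int(e.genome_mapped),
            "candidates": ";".join(
                f"{g}:{b}" for g, b in sorted(e.candidates)
            ),
        }
        for e in evidence
    ]
    pd.DataFrame(rows, columns=["read_id", "genome_mapped", "candidates"]).to_csv(
        path, sep="\t", index=False
    )


def annotate_exact(
    reads: Sequence[ReadRecord],
    reference_fasta: str | Path,
) -> list[AlignmentEvidence]:
    """Exact-substring annotator against a small reference FASTA.

    Reference headers are ``>gene_id biotype``.  A read is genome-mapped
    iff its sequence occurs verbatim in at least one reference record;
    every matching record contributes a (gene, biotype) candidate.  This
    is a fixture-scale stand-in for a real aligner and is O(reads x refs).
    """
    refs = []
    for rec in SeqIO.parse(str(reference_fasta), "fasta"):
        parts = rec.description.split()
        if len(parts) < 2 or parts[1] not in BIOTYPES:
            raise ValueError(
                f"reference record {rec.id!r}: header must be '>gene biotype'"
            )
        refs.append((rec.id, parts[1], str(rec.seq).upper()))
    out = []
    for read in reads:
        cands = frozenset(
            (gene, biotype) for gene, biotype, seq in refs if read.sequence in seq
        )
        out.append(AlignmentEvidence(read.read_id, bool(cands), cands))
    return out
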