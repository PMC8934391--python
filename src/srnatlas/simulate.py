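"""Synthetic tissue and biofluid count data with planted ground truth.

The generator emulates the structure of a small-RNA tissue atlas at desk
scale:

* sequences come in *isomiR families* — one canonical sequence per gene
  plus end-shift variants (5'/3' trims, single-base 3' additions), so
  sequence-level and gene-level analyses genuinely differ;
* each family draws a log-normal baseline expression level, split across
  its isomiRs by a symmetric Dirichlet draw; the baseline profile is flat
  across tissues;
* *planted* sequences are multiplied by ``planted_fold`` in their target
  tissue(s): single-tissue plants, enhanced-style plants (which
  additionally get a moderate decoy tissue so the single-tissue criterion
  fails while the against-the-mean criterion holds), and — opt-in via
  ``planted_group_fraction`` — 2-4-tissue group plants.  Group planting
  defaults to zero: at the default dispersion the realized group-min /
  outside-max contrast of a group plant concentrates *below* its
  population fold (replicate order statistics consume the margin), so
  group labels planted at a fold near the classification threshold are
  unrecoverable ground truth; plant groups at a comfortably larger fold
  to study that boundary;
* counts are negative-binomial around the expected profile scaled to a
  fixed library size, with one shared dispersion;
* biofluids are weighted mixtures of the tissue mean profiles plus a
  uniform background over a random sequence subset.

Plants are drawn from a mid-abundance band (expected baseline counts
comfortably above the detection filters) so every planted label is
recoverable in principle and the per-tissue planted signal is comparable
across tissues.  All randomness flows from the single configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import (
    GROUP_ENRICHED,
    TISSUE_ENHANCED,
    TISSUE_ENRICHED,
    tissue_means,
)
from .model import (
    BIOTYPES,
    CountMatrix,
    MAX_SEQ_LEN,
    MIN_SEQ_LEN,
    NormalizedMatrix,
    SampleMeta,
    logger,
)
from .quantify import AlignmentEvidence, ReadRecord

#: Default biotype mix, loosely patterned on tissue small-RNA libraries
#: (miRNA-dominated with sizeable tRNA/YRNA/piRNA fragment classes).
DEFAULT_BIOTYPE_PROPORTIONS: dict[str, float] = {
    "miRNA": 0.40,
    "tRNA": 0.20,
    "YRNA": 0.15,
    "piRNA": 0.15,
    "protein_coding": 0.05,
    "other": 0.05,
}

_GENE_PREFIX = {
    "miRNA": "sim-miR",
    "tRNA": "sim-tRF",
    "YRNA": "sim-yRF",
    "piRNA": "sim-piR",
    "protein_coding": "sim-PC",
    "other": "sim-OTHER",
}

# Plant eligibility: sequences between these quantiles of expected baseline
# count (plus an absolute floor above the detection filters).  The band keeps
# every planted label detectable and the planted read mass comparable across
# tissues, so ground truth is identifiable by construction — a wide-open band
# would let one tissue's plants carry several-fold more reads than another's,
# drowning the mixing-weight signal that biofluid attribution recovers.
_PLANT_QUANTILES = (0.60, 0.90)
_PLANT_FLOOR_COUNT = 30.0


@dataclass(frozen=True)
class BiofluidSpec:
    """One biofluid: its tissue mixing weights and background fraction."""

    name: str
    weights: dict[str, float]
    background_fraction: float = 0.1

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biofluid {self.name!r}: weights sum to {total}, not 1")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError(f"biofluid {self.name!r}: background_fraction in [0, 1)")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic atlas.

    Defaults: 3 replicates per tissue, planted 10-fold elevation,
    negative-binomial dispersion 0.1, and a single skewed biofluid
    mixture (weights proportional to 0.7**rank, as real biofluids are
    dominated by a few contributing sources).
    """

    n_tissues: int = 10
    n_replicates: int = 3
    n_families: int = 100
    isomirs_per_family: tuple[int, int] = (1, 5)
    biotype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_PROPORTIONS)
    )
    log_mean: float = 0.0
    log_sd: float = 1.0
    planted_per_tissue: int = 8
    planted_fold: float = 10.0
    planted_group_fraction: float = 0.0
    planted_enhanced_fraction: float = 0.2
    nb_dispersion: float = 0.1
    library_size: int = 100_000
    biofluids: list[BiofluidSpec] | None = None
    n_biofluid_samples: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.biotype_proportions) - set(BIOTYPES):
            raise ValueError("biotype_proportions keys must be known biotypes")
        total = sum(self.biotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biotype_proportions sum to {total}, not 1")
        if self.planted_fold <= 1:
            raise ValueError("planted_fold must be > 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.isomirs_per_family
        if not (1 <= lo <= hi):
            raise ValueError("isomirs_per_family must be a non-empty range")
        if not (0 <= self.planted_group_fraction + self.planted_enhanced_fraction <= 1):
            raise ValueError("planted category fractions must sum to <= 1")

    @property
    def tissue_names(self) -> list[str]:
        return [f"TISSUE_{i:02d}" for i in range(1, self.n_tissues + 1)]

    def effective_biofluids(self) -> list[BiofluidSpec]:
        """Configured biofluids, or the default single skewed mixture."""
        if self.biofluids is not None:
            return list(self.biofluids)
        raw = np.array([0.7 ** (i + 1) for i in range(self.n_tissues)])
        weights = dict(zip(self.tissue_names, raw / raw.sum()))
        return [BiofluidSpec("SYNTHETIC_PLASMA", weights, background_fraction=0.1)]


@dataclass(frozen=True)
class PlantedSequence:
    sequence: str
    category: str
    tissues: frozenset[str]
    fold: float


@dataclass
class GroundTruth:
    """Planted elevation labels, expected counts, biofluid mixing weights."""

    plants: list[PlantedSequence]
    biofluid_weights: dict[str, dict[str, float]]
    #: expected (noise-free) per-replicate counts, sequences x tissues
    expected_counts: pd.DataFrame | None = None

    @property
    def planted_ids(self) -> set[str]:
        return {p.sequence for p in self.plants}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [p.sequence for p in self.plants],
                "category": [p.category for p in self.plants],
                "tissues": [";".join(sorted(p.tissues)) for p in self.plants],
                "fold": [p.fold for p in self.plants],
            }
        )


# ---------------------------------------------------------------------------
# Sequence families
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _isomir(rng: np.random.Generator, canonical: str) -> str:
    """An end-shift variant: 5'/3' trims and/or single-base 3' additions."""
    for _ in range(50):
        t5 = int(rng.integers(0, 3))
        t3 = int(rng.integers(0, 4))
        add = int(rng.integers(0, 3))
        seq = canonical[t5: len(canonical) - t3 if t3 else None]
        seq += "".join(rng.choice(_BASES, size=add))
        if MIN_SEQ_LEN <= len(seq) <= MAX_SEQ_LEN and seq != canonical:
            return seq
    raise RuntimeError("could not generate a distinct isomiR variant")


def _make_families(
    rng: np.random.Generator, config: SimulationConfig
) -> pd.DataFrame:
    """Generate sequences with annotations and baseline expression.

    Returns a DataFrame indexed by sequence with columns biotype,
    parent_gene, is_canonical, base_expr.
    """
    biotypes = list(config.biotype_proportions)
    probs = np.array([config.biotype_proportions[b] for b in biotypes])
    lo, hi = config.isomirs_per_family
    rows: dict[str, dict] = {}
    counters: dict[str, int] = {}
    for _ in range(config.n_families):
        biotype = biotypes[int(rng.choice(len(biotypes), p=probs))]
        counters[biotype] = counters.get(biotype, 0) + 1
        gene = f"{_GENE_PREFIX[biotype]}-{counters[biotype]:04d}"
        canonical = _random_seq(rng, int(rng.integers(19, 25)))
        while canonical in rows:
            canonical = _random_seq(rng, int(rng.integers(19, 25)))
        size = int(rng.integers(lo, hi + 1))
        members = [canonical]
        attempts = 0
        while len(members) < size and attempts < 200:
            attempts += 1
            var = _isomir(rng, canonical)
            if var not in rows and var not in members:
                members.append(var)
        level = float(rng.lognormal(config.log_mean, config.log_sd))
        shares = rng.dirichlet(np.ones(len(members)))
        for i, seq in enumerate(members):
            rows[seq] = {
                "biotype": biotype,
                "parent_gene": gene,
                "is_canonical": i == 0,
                "base_expr": level * float(shares[i]),
            }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Tissue counts with planted elevation
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _choose_plants(
    rng: np.random.Generator,
    families: pd.DataFrame,
    config: SimulationConfig,
) -> list[str]:
    n_needed = config.planted_per_tissue * config.n_tissues
    if n_needed == 0:
        return []
    if n_needed > len(families):
        raise ValueError(
            f"infeasible config: {n_needed} plants requested but only "
            f"{len(families)} sequences generated"
        )
    expected = families["base_expr"] / families["base_expr"].sum() * config.library_size
    lo = max(float(expected.quantile(_PLANT_QUANTILES[0])), _PLANT_FLOOR_COUNT)
    hi = float(expected.quantile(_PLANT_QUANTILES[1]))
    in_band = families.index[(expected >= lo) & (expected <= hi)].to_numpy()
    pool = list(rng.permutation(in_band))
    if len(pool) < n_needed:
        logger.warning(
            "plant abundance band holds %d sequences, need %d; topping up with "
            "most abundant remainder", len(pool), n_needed,
        )
        remainder = expected.drop(index=pool).sort_values(ascending=False)
        pool.extend(s for s in remainder.index if s not in pool)
    return pool[:n_needed]


def simulate_tissue_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, GroundTruth]:
    """Generate the tissue atlas count matrix and its ground truth.

    Bit-identical for identical configs (all draws from ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    families = _make_families(rng, config)
    tissues = config.tissue_names
    seqs = families.index
    mult = pd.DataFrame(1.0, index=seqs, columns=tissues)

    plants: list[PlantedSequence] = []
    pool = _choose_plants(rng, families, config)
    ppt = config.planted_per_tissue
    k_grp = int(round(ppt * config.planted_group_fraction))
    k_enh = int(round(ppt * config.planted_enhanced_fraction))
    k_grp = min(k_grp, ppt)
    k_enh = min(k_enh, ppt - k_grp)
    pos = 0
    for t in tissues:
        others = [u for u in tissues if u != t]
        for j in range(ppt):
            seq = pool[pos]
            pos += 1
            if j < k_grp:
                # group size 2..4 including the anchor tissue
                extra = int(rng.integers(1, min(3, len(others)) + 1))
                partners = [str(u) for u in rng.choice(others, size=extra, replace=False)]
                group = frozenset([t, *partners])
                for u in group:
                    mult.loc[seq, u] = config.planted_fold
                plants.append(
                    PlantedSequence(seq, GROUP_ENRICHED, group, config.planted_fold)
                )
            elif j < k_grp + k_enh:
                decoy = str(rng.choice(others))
                mult.loc[seq, t] = config.planted_fold
                # Decoy breaks the single-tissue criterion without lifting
                # the mean of the other tissues much.
                mult.loc[seq, decoy] = max(1.5, config.planted_fold / 6.0)
                plants.append(
                    PlantedSequence(seq, TISSUE_ENHANCED, frozenset([t]), config.planted_fold)
                )
            else:
                mult.loc[seq, t] = config.planted_fold
                plants.append(
                    PlantedSequence(seq, TISSUE_ENRICHED, frozenset([t]), config.planted_fold)
                )

    base = families["base_expr"].to_numpy()
    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    expected_by_tissue: dict[str, np.ndarray] = {}
    for t in tissues:
        expected = base * mult[t].to_numpy()
        expected = expected / expected.sum() * config.library_size
        expected_by_tissue[t] = expected
        for r in range(1, config.n_replicates + 1):
            sid = f"{t}_R{r}"
            samples.append(SampleMeta(sid, t, "tissue", r))
            columns[sid] = _nb_draw(rng, expected, config.nb_dispersion)

    counts = pd.DataFrame(columns, index=seqs)
    counts.index.name = "sequence"
    matrix = CountMatrix(
        counts, families[["biotype", "parent_gene"]], samples, validate_sequences=False
    )
    truth = GroundTruth(
        plants=plants,
        biofluid_weights={
            bf.name: dict(bf.weights) for bf in config.effective_biofluids()
        },
        expected_counts=pd.DataFrame(expected_by_tissue, index=seqs),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Biofluids as tissue mixtures
# ---------------------------------------------------------------------------


def simulate_biofluid_counts(
    config: SimulationConfig,
    tissue_truth: GroundTruth,
    tissue_profiles: NormalizedMatrix,
) -> CountMatrix:
    """Generate biofluid samples as weighted mixtures of tissue profiles.

    Each biofluid sample's expected profile is the weight-averaged tissue
    mean profile plus a uniform background over a random sequence subset,
    scaled to the library size; counts are negative-binomial.  Draws are
    seeded from ``config.seed`` (offset so tissue and biofluid noise are
    independent).
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    means = tissue_means(tissue_profiles)  # sequences x tissues
    seqs = means.index
    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    for bf in config.effective_biofluids():
        unknown = set(bf.weights) - set(means.columns)
        if unknown:
            raise ValueError(
                f"biofluid {bf.name!r}: weights reference unknown tissue(s) "
                f"{sorted(unknown)}"
            )
        mixture = np.zeros(len(seqs))
        for tissue, w in bf.weights.items():
            prof = means[tissue].to_numpy(dtype=float)
            total = prof.sum()
            if total > 0:
                mixture += w * prof / total
        background = np.zeros(len(seqs))
        if bf.background_fraction > 0:
            n_bg = max(1, len(seqs) // 10)
            idx = rng.choice(len(seqs), size=n_bg, replace=False)
            background[idx] = 1.0 / n_bg
        profile = (1 - bf.background_fraction) * mixture + bf.background_fraction * background
        expected = profile / profile.sum() * config.library_size
        for r in range(1, config.n_biofluid_samples + 1):
            sid = f"{bf.name}_S{r}"
            samples.append(SampleMeta(sid, bf.name, "biofluid", r))
            columns[sid] = _nb_draw(rng, expected, config.nb_dispersion)
    counts = pd.DataFrame(columns, index=seqs)
    counts.index.name = "sequence"
    return CountMatrix(
        counts, tissue_profiles.row_meta, samples, validate_sequences=False
    )


# ---------------------------------------------------------------------------
# Read-level fixtures
# ---------------------------------------------------------------------------


def simulate_reads(
    matrix: CountMatrix,
    annotation_error_rate: float = 0.0,
    unmapped_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[ReadRecord], list[AlignmentEvidence]]:
    """Emit each sequence of a one-sample matrix as individual reads.

    Exactly ``count`` copies of every sequence are produced.  Evidence
    lists the true (gene, biotype); with probability
    ``annotation_error_rate`` a decoy candidate of strictly lower
    priority is added (inert under the priority rule), and a
    ``unmapped_fraction`` of reads is marked genome-unmapped.
    """
    if not 0.0 <= annotation_error_rate <= 1.0:
        raise ValueError("annotation_error_rate must be in [0, 1]")
    if not 0.0 <= unmapped_fraction <= 1.0:
        raise ValueError("unmapped_fraction must be in [0, 1]")
    if len(matrix.samples) != 1:
        raise ValueError("simulate_reads expects a single-sample matrix")
    rng = np.random.default_rng(seed)
    col = matrix.counts.columns[0]
    reads: list[ReadRecord] = []
    evidence: list[AlignmentEvidence] = []
    k = 0
    for seq, row in matrix.row_meta.iterrows():
        count = int(matrix.counts.at[seq, col])
        true_cand = (row["parent_gene"], row["biotype"])
        lower = BIOTYPES[BIOTYPES.index(row["biotype"]) + 1:]
        for _ in range(count):
            k += 1
            rid = f"READ-{k:07d}"
            reads.append(ReadRecord(rid, seq))
            cands = {true_cand}
            if lower and rng.random() < annotation_error_rate:
                decoy_bt = str(rng.choice(lower))
                cands.add((f"decoy-{decoy_bt}-{k:07d}", decoy_bt))
            evidence.append(
                AlignmentEvidence(
                    rid,
                    genome_mapped=bool(rng.random() >= unmapped_fraction),
                    candidates=frozenset(cands),
                )
            )
    return reads, evidence
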