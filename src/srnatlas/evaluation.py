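"""Scoring pipeline output against simulator ground truth."""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import spearmanr

from .biofluid import attribute, detect_in_biofluid
from .enrichment import classify_matrix, elevated_sets
from .filters import filter_tissue, median_of_ratios
from .model import PipelineConfig
from .simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_biofluid_counts,
    simulate_tissue_counts,
)


@dataclass
class RecoveryMetrics:
    """Sensitivity/precision of planted-elevation recovery.

    A plant counts as recovered when its sequence is called elevated and
    the call's tissue set covers the true target set; a call counts as a
    true positive when its sequence was planted.
    """

    sensitivity: float
    precision: float
    n_planted: int
    n_called: int


def recovery_metrics(calls, truth: GroundTruth) -> RecoveryMetrics:
    planted = {p.sequence: p for p in truth.plants}
    call_by_id = {c.id: c for c in calls}
    recovered = sum(
        1
        for seq, plant in planted.items()
        if seq in call_by_id
        and call_by_id[seq].elevated
        and plant.tissues <= call_by_id[seq].tissues
    )
    elevated_calls = [c for c in calls if c.elevated]
    tp = sum(1 for c in elevated_calls if c.id in planted)
    return RecoveryMetrics(
        sensitivity=recovered / len(planted) if planted else 1.0,
        precision=tp / len(elevated_calls) if elevated_calls else 1.0,
        n_planted=len(planted),
        n_called=len(elevated_calls),
    )


def run_tissue_pipeline(sim: SimulationConfig, config: PipelineConfig | None = None):
    """simulate -> detection filter -> normalize -> classify.

    Returns (tissue matrix, truth, normalized matrix, calls).
    """
    if config is None:
        config = PipelineConfig()
    matrix, truth = simulate_tissue_counts(sim)
    kept, _ = filter_tissue(
        matrix, config.tissue_min_count, config.tissue_min_replicates
    )
    normalized = median_of_ratios(kept)
    calls = classify_matrix(normalized, config)
    return matrix, truth, normalized, calls


def attribution_rank_correlation(
    sim: SimulationConfig, config: PipelineConfig | None = None
) -> float:
    """End-to-end biofluid attribution vs planted mixing weights.

    Runs the tissue pipeline, simulates the default biofluid, attributes
    detected sequences, and returns the Spearman correlation between
    recovered per-tissue read fractions and the planted mixing weights
    (tissues without detected elevated sequences contribute fraction 0).
    """
    if config is None:
        config = PipelineConfig()
    _, truth, normalized, calls = run_tissue_pipeline(sim, config)
    fluids = simulate_biofluid_counts(sim, truth, normalized)
    name = next(iter(truth.biofluid_weights))
    detected = detect_in_biofluid(fluids, config)
    fluid_norm = median_of_ratios(fluids)
    mean_counts = fluid_norm.normalized.mean(axis=1).to_dict()
    result = attribute(detected, elevated_sets(calls), mean_counts, biofluid=name)
    weights = truth.biofluid_weights[name]
    tissues = sorted(weights)
    fractions = (
        result.table["read_fraction"].reindex(tissues).fillna(0.0).to_numpy()
    )
    return float(spearmanr([weights[t] for t in tissues], fractions).statistic)
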