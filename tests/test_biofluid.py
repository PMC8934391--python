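"""Biofluid detection, attribution, diversity, rarefaction, BH, DE joins."""

import numpy as np
import pandas as pd
import pytest

from srnatlas import (
    EnrichmentCall,
    NOT_ELEVATED,
    NormalizedMatrix,
    SampleMeta,
    TISSUE_ENRICHED,
    annotate_de,
    attribute,
    bh_adjust,
    detect_in_biofluid,
    diversity,
    filter_biofluid,
    rarefaction,
    rarefaction_curve,
)

from conftest import make_matrix, random_matrix
from oracles import bh_oracle, monte_carlo_richness


class TestDetectInBiofluid:
    def test_detection_rule(self):
        cols = {f"b{j}": [11 if j < 6 else 0, 5] for j in range(10)}
        sources = {f"b{j}": ("URINE", "biofluid", j + 1) for j in range(10)}
        m = make_matrix(cols, sources=sources)
        detected = detect_in_biofluid(m)
        assert detected == {m.sequences[0]}

    def test_empty_matrix_gives_empty_set(self):
        m = make_matrix({"b1": []}, sources={"b1": ("CSF", "biofluid", 1)})
        assert detect_in_biofluid(m) == set()

    def test_consistent_with_filter_biofluid(self, rng):
        for _ in range(20):
            m = random_matrix(rng, 25, 8, source_class="biofluid", max_count=25)
            kept, _ = filter_biofluid(m)
            assert detect_in_biofluid(m) == set(kept.sequences)


class TestAttribute:
    def test_hand_worked_shared_sequence_case(self):
        elevated = {"A": {"s1", "s2"}, "B": {"s2", "s3"}}
        res = attribute(
            {"s1", "s2", "s3"}, elevated, {"s1": 100.0, "s2": 50.0, "s3": 50.0}
        )
        assert res.table.loc["A", "n_detected_sequences"] == 2
        assert res.table.loc["B", "n_detected_sequences"] == 2
        assert res.table.loc["A", "read_sum"] == 150.0
        assert res.table.loc["B", "read_sum"] == 100.0
        assert res.table.loc["A", "read_fraction"] == pytest.approx(0.6)
        assert res.table.loc["B", "read_fraction"] == pytest.approx(0.4)

    def test_disjoint_detected_set_gives_zeros(self, caplog):
        with caplog.at_level("WARNING", logger="srnatlas"):
            res = attribute({"x"}, {"A": {"s1"}}, {"x": 5.0})
        assert (res.table["read_fraction"] == 0).all()

    def test_single_tissue_gets_fraction_one(self):
        res = attribute({"s1"}, {"A": {"s1"}, "B": {"s9"}}, {"s1": 3.0})
        assert res.table.loc["A", "read_fraction"] == 1.0
        assert res.table.loc["B", "read_fraction"] == 0.0

    def test_missing_mean_count_is_error(self):
        with pytest.raises(ValueError, match="mean_counts missing"):
            attribute({"s1"}, {"A": {"s1"}}, {})

    def test_fractions_sum_to_one_with_double_counting(self, rng):
        for _ in range(50):
            seqs = [f"s{i}" for i in range(30)]
            elevated = {
                f"T{t}": set(rng.choice(seqs, size=8, replace=False))
                for t in range(5)
            }
            detected = set(rng.choice(seqs, size=20, replace=False))
            mc = {s: float(rng.uniform(1, 100)) for s in seqs}
            res = attribute(detected, elevated, mc)
            if res.table["read_sum"].sum() > 0:
                assert res.table["read_fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_alternative_denominator_counts_shared_reads_once(self):
        elevated = {"A": {"s1", "s2"}, "B": {"s2"}}
        res = attribute(
            {"s1", "s2"}, elevated, {"s1": 10.0, "s2": 30.0},
            shared_denominator=False,
        )
        # denominator 40 (s2 counted once); A: 40/40, B: 30/40
        assert res.table.loc["A", "read_fraction"] == pytest.approx(1.0)
        assert res.table.loc["B", "read_fraction"] == pytest.approx(0.75)


def _normalized_single_source(values_by_sample, genes, source=("LIVER", "tissue")):
    df = pd.DataFrame(values_by_sample, dtype=float)
    df.index = [f"SEQ{i}" for i in range(len(df))]
    return NormalizedMatrix(
        normalized=df,
        size_factors=pd.Series(1.0, index=df.columns),
        row_meta=pd.DataFrame(
            {"biotype": "miRNA", "parent_gene": genes}, index=df.index
        ),
        samples=[
            SampleMeta(sid, source[0], source[1], i + 1)
            for i, sid in enumerate(df.columns)
        ],
    )


class TestDiversity:
    def test_gene_collapse_can_rescue_sub_cutoff_isoforms(self):
        m = _normalized_single_source(
            {"r1": [12, 11, 4]}, genes=["geneX"] * 3
        )
        rep = diversity(m, cutoff=10)
        assert rep.table.loc["LIVER", "sequence_diversity"] == 2
        assert rep.table.loc["LIVER", "gene_diversity"] == 1  # 27 > 10 collapsed

    def test_all_zero_source(self):
        m = _normalized_single_source({"r1": [0, 0]}, genes=["g1", "g2"])
        rep = diversity(m)
        assert rep.table.loc["LIVER"].tolist() == [0, 0]

    def test_one_sequence_per_gene_identity(self):
        m = _normalized_single_source({"r1": [20, 30, 40]}, genes=["a", "b", "c"])
        rep = diversity(m)
        assert (
            rep.table.loc["LIVER", "gene_diversity"]
            == rep.table.loc["LIVER", "sequence_diversity"]
            == 3
        )

    def test_replicates_averaged_before_cutoff(self):
        m = _normalized_single_source(
            {"r1": [30], "r2": [0]}, genes=["g"]
        )  # mean 15 > 10
        rep = diversity(m)
        assert rep.table.loc["LIVER", "sequence_diversity"] == 1


class TestRarefaction:
    def test_full_depth_returns_observed_richness(self):
        assert rarefaction([5, 0, 3, 2], 10) == pytest.approx(3.0)

    def test_zero_depth(self):
        assert rarefaction([5, 5], 0) == 0.0

    def test_two_species_hand_value(self):
        assert rarefaction([5, 5], 5) == pytest.approx(2 * (1 - 1 / 252), rel=1e-12)

    def test_depth_beyond_total_is_error(self):
        with pytest.raises(ValueError, match="depth"):
            rarefaction([5, 5], 11)

    def test_matches_monte_carlo_oracle(self, rng):
        counts = [40, 25, 10, 5, 3, 1, 1]
        for depth in (5, 20, 60):
            mc, se = monte_carlo_richness(rng, counts, depth)
            assert rarefaction(counts, depth) == pytest.approx(mc, abs=3 * se)

    def test_monotone_and_concave_in_depth(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 40, size=12)
            counts[0] = max(counts[0], 1)
            total = int(counts.sum())
            curve = rarefaction_curve(counts, range(0, total + 1, max(1, total // 25)))
            vals = curve.to_numpy()
            diffs = np.diff(vals)
            assert (diffs >= -1e-9).all()
            assert (np.diff(diffs) <= 1e-9).all()


class TestBHAdjust:
    def test_single_value_is_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_worked_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_independent_oracle_and_permutation_invariant(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            adj = bh_adjust(p)
            assert adj == pytest.approx(bh_oracle(p.tolist()), rel=1e-12)
            perm = rng.permutation(len(p))
            assert bh_adjust(p[perm]) == pytest.approx(adj[perm], rel=1e-12)


class TestAnnotateDE:
    def _calls(self):
        return [
            EnrichmentCall("SEQLIVER", TISSUE_ENRICHED, frozenset({"LIVER"}), 50.0)
        ]

    def test_significant_record_gets_elevation_label(self):
        de = pd.DataFrame(
            {"sequence": ["SEQLIVER"], "log2fc": [2.5], "pvalue": [0.001]}
        )
        out = annotate_de(de, self._calls())
        row = out.iloc[0]
        assert row["significant"]
        assert row["elevation_category"] == TISSUE_ENRICHED
        assert row["elevation_tissues"] == "LIVER"

    def test_nothing_significant(self):
        de = pd.DataFrame(
            {"sequence": ["a", "b"], "log2fc": [1, -1], "pvalue": [0.4, 0.9]}
        )
        out = annotate_de(de, self._calls())
        assert not out["significant"].any()

    def test_record_absent_from_calls_is_not_elevated(self):
        de = pd.DataFrame(
            {"sequence": ["unknown"], "log2fc": [3.0], "pvalue": [0.0001]}
        )
        out = annotate_de(de, self._calls())
        assert out.iloc[0]["elevation_category"] == NOT_ELEVATED

    def test_duplicate_sequences_rejected(self):
        de = pd.DataFrame(
            {"sequence": ["a", "a"], "log2fc": [1, 2], "pvalue": [0.1, 0.2]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            annotate_de(de, [])

    def test_preadjusted_p_values_pass_through(self):
        de = pd.DataFrame(
            {
                "sequence": ["a", "b"],
                "log2fc": [1, 2],
                "pvalue": [0.001, 0.002],
                "padj": [0.2, 0.01],
            }
        )
        out = annotate_de(de, [])
        assert out["padj"].tolist() == [0.2, 0.01]
        assert out["significant"].tolist() == [False, True]

    def test_adjustment_applied_when_padj_absent(self):
        de = pd.DataFrame(
            {
                "sequence": ["a", "b", "c", "d"],
                "log2fc": [0, 0, 0, 0],
                "pvalue": [0.01, 0.02, 0.03, 0.04],
            }
        )
        out = annotate_de(de, [])
        assert out["padj"].tolist() == pytest.approx([0.04] * 4)
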