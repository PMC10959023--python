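"""Reversal statistics: direction guards, rescue/specificity arithmetic,
compartment pooling, baseline restoration and cross-cell-type partitions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gutrescue.rescue import (
    aggregate_compartment,
    baseline_restoration,
    cross_celltype_categories,
    rescue_specificity,
    reversed_intersection,
    summarize_rescue,
)


def brute_force_reversed(diet, surgery):
    return {
        g
        for g in set(diet) | set(surgery)
        if g in diet and g in surgery and diet[g] != surgery[g]
    }


class TestReversedIntersection:
    def test_opposite_directions_rescued(self):
        rescued, _ = reversed_intersection({"g1": "down"}, {"g1": "up"})
        assert rescued == {"g1"}

    def test_same_direction_is_concordant_not_rescued(self):
        rescued, calls = reversed_intersection({"g1": "down"}, {"g1": "down"})
        assert rescued == set()
        assert calls.loc[calls["gene"] == "g1", "category"].iloc[0] == "concordant"

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            reversed_intersection({"g1": "sideways"}, {})

    def test_exhaustive_small_maps(self):
        """All gene-state combinations over 3 genes x {absent, up, down}^2."""
        states = [None, "up", "down"]
        genes = ["a", "b", "c"]
        for combo in itertools.product(states, repeat=6):
            diet = {g: s for g, s in zip(genes, combo[:3]) if s}
            surg = {g: s for g, s in zip(genes, combo[3:]) if s}
            rescued, _ = reversed_intersection(diet, surg)
            assert rescued == brute_force_reversed(diet, surg)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.dictionaries(
            st.sampled_from([f"g{i}" for i in range(12)]),
            st.sampled_from(["up", "down"]),
        ),
        st.dictionaries(
            st.sampled_from([f"g{i}" for i in range(12)]),
            st.sampled_from(["up", "down"]),
        ),
    )
    def test_matches_bruteforce_random_maps(self, diet, surg):
        rescued, calls = reversed_intersection(diet, surg)
        assert rescued == brute_force_reversed(diet, surg)
        # calls partition the union of both maps
        assert set(calls["gene"]) == set(diet) | set(surg)


class TestRescueSpecificity:
    def test_worked_arithmetic(self):
        diet = {f"d{i}": "down" for i in range(10)}
        surg = {f"d{i}": "up" for i in range(6)}
        surg.update({f"s{i}": "up" for i in range(14)})
        row = rescue_specificity(diet, surg)
        assert row.n_reversed == 6
        assert row.rescue_pct == pytest.approx(60.0)
        assert row.specificity_pct == pytest.approx(30.0)

    def test_empty_diet_map_undefined_rescue(self):
        row = rescue_specificity({}, {"g": "up"})
        assert math.isnan(row.rescue_pct)
        assert not row.rescue_defined
        assert row.specificity_pct == 0.0

    def test_full_signflip_gives_100_100(self):
        diet = {"a": "up", "b": "down", "c": "down"}
        surg = {"a": "down", "b": "up", "c": "up"}
        row = rescue_specificity(diet, surg)
        assert row.rescue_pct == 100.0
        assert row.specificity_pct == 100.0

    def test_directional_strata_sum(self):
        diet = {"a": "down", "b": "down", "c": "up", "d": "up"}
        surg = {"a": "up", "c": "down", "x": "up"}
        row = rescue_specificity(diet, surg)
        assert row.n_reversed == row.n_reversed_downup + row.n_reversed_updown
        assert row.n_reversed_downup == 1  # a: down -> up
        assert row.n_reversed_updown == 1  # c: up -> down

    @settings(derandomize=True, max_examples=100)
    @given(
        st.dictionaries(
            st.sampled_from([f"g{i}" for i in range(8)]),
            st.sampled_from(["up", "down"]),
        ),
        st.dictionaries(
            st.sampled_from([f"g{i}" for i in range(8)]),
            st.sampled_from(["up", "down"]),
        ),
    )
    def test_swap_symmetry_and_bounds(self, diet, surg):
        a = rescue_specificity(diet, surg)
        b = rescue_specificity(surg, diet)
        assert a.n_reversed == b.n_reversed
        assert a.n_reversed <= min(a.n_diet_degs, a.n_surgery_degs)
        if a.rescue_defined:
            assert a.rescue_pct == b.specificity_pct

    def test_undefined_is_nan_not_zero(self):
        row = rescue_specificity({}, {})
        assert math.isnan(row.rescue_pct) and math.isnan(row.specificity_pct)


class TestAggregateCompartment:
    def _summary(self, rows):
        cols = [
            "cluster", "n_diet_degs", "n_surgery_degs", "n_reversed",
            "n_reversed_downup", "n_reversed_updown", "rescue_pct",
            "specificity_pct", "rescue_pct_downup", "specificity_pct_downup",
            "rescue_pct_updown", "specificity_pct_updown",
        ]
        return pd.DataFrame(rows, columns=cols)

    def test_single_cluster_identity(self):
        summary = self._summary(
            [["stem", 10, 20, 6, 4, 2, 60.0, 30.0, 40.0, 20.0, 20.0, 10.0]]
        )
        pooled = aggregate_compartment(summary, {"stem": "crypt"}, "crypt")
        assert pooled.n_diet_degs == 10
        assert pooled.rescue_pct == pytest.approx(60.0)

    def test_pooled_arithmetic(self):
        summary = self._summary(
            [
                ["a", 10, 12, 6, 6, 0, 60.0, 50.0, 60, 50, 0, 0],
                ["b", 10, 8, 0, 0, 0, 0.0, 0.0, 0, 0, 0, 0],
            ]
        )
        pooled = aggregate_compartment(summary, {"a": "crypt", "b": "crypt"}, "crypt")
        assert pooled.rescue_pct == pytest.approx(30.0)
        assert pooled.n_reversed <= min(pooled.n_diet_degs, pooled.n_surgery_degs)

    def test_unknown_compartment_rejected(self):
        summary = self._summary([])
        with pytest.raises(ValueError, match="unknown compartment"):
            aggregate_compartment(summary, {"a": "crypt"}, "lumen")


def _de_rows(cluster, contrast, entries):
    """entries: list of (gene, log2fc, passes)"""
    return [
        {
            "cluster": cluster, "contrast": contrast, "gene": g,
            "log2fc": fc, "p": 0.001 if ok else 0.9,
            "padj": 0.01 if ok else 0.95,
            "direction": "up" if fc >= 0 else "down",
            "passes_filter": ok,
        }
        for g, fc, ok in entries
    ]


class TestBaselineRestoration:
    def _table(self, residual_passes):
        rows = (
            _de_rows("stem", "diet", [("g1", -1.5, True)])
            + _de_rows("stem", "surgery", [("g1", 1.4, True)])
            + _de_rows("stem", "residual", [("g1", -0.9, residual_passes)])
        )
        return pd.DataFrame(rows)

    def test_full_rescue_is_restored(self):
        assert baseline_restoration(self._table(False), "g1", "stem")

    def test_partial_rescue_not_restored(self):
        assert not baseline_restoration(self._table(True), "g1", "stem")

    def test_no_diet_effect_never_restored(self):
        rows = _de_rows("stem", "surgery", [("g2", 1.2, True)]) + _de_rows(
            "stem", "residual", [("g2", 0.1, False)]
        )
        assert not baseline_restoration(pd.DataFrame(rows), "g2", "stem")

    def test_missing_residual_contrast_instructive(self):
        rows = _de_rows("stem", "diet", [("g1", -1.5, True)]) + _de_rows(
            "stem", "surgery", [("g1", 1.4, True)]
        )
        with pytest.raises(ValueError, match="residual"):
            baseline_restoration(pd.DataFrame(rows), "g1", "stem")

    def test_planted_full_vs_partial_rescue_simulation(self):
        """A gene reverted fully to control passes restoration; a gene only
        half-reverted keeps a residual difference at large n."""
        from gutrescue.cluster import normalize_log
        from gutrescue.de import Contrast, test_contrast
        from gutrescue.simulate import SimConfig, simulate_counts

        des = {}
        for completeness in (1.0, 0.5):
            cfg = SimConfig(
                n_clusters=1, cells_per_cluster_per_condition=400, n_genes=400,
                markers_per_cluster=10, de_fraction=0.05, de_log2fc=1.5,
                rescue_fraction=1.0, surgery_only_fraction=0.0,
                n_mito_rescued=0, rho=0.0, doublet_rate=0.0,
                n_empty_droplets=0, seed=9, rescue_completeness=completeness,
            )
            bundle, truth = simulate_counts(cfg)
            norm = normalize_log(bundle)
            labels = np.zeros(bundle.n_cells, dtype=int)
            de = pd.concat(
                [
                    test_contrast(bundle, norm, labels, Contrast.standard(c))
                    for c in ("diet", "surgery", "residual")
                ],
                ignore_index=True,
            )
            detected = [
                g for g in truth.rescued[0]
                if g in set(de.loc[(de["contrast"] == "diet") & de["passes_filter"], "gene"])
                and g in set(de.loc[(de["contrast"] == "surgery") & de["passes_filter"], "gene"])
            ]
            assert detected, "no planted rescue detected"
            des[completeness] = (de, detected)

        de_full, genes_full = des[1.0]
        restored_full = np.mean(
            [baseline_restoration(de_full, g, 0) for g in genes_full]
        )
        de_half, genes_half = des[0.5]
        restored_half = np.mean(
            [baseline_restoration(de_half, g, 0) for g in genes_half]
        )
        assert restored_full > 0.8
        assert restored_half < 0.3


class TestCrossCellType:
    def _calls(self, stem_genes, paneth_genes):
        rows = [
            {"cluster": "stem", "gene": g, "category": "rescued"}
            for g in stem_genes
        ] + [
            {"cluster": "paneth", "gene": g, "category": "rescued"}
            for g in paneth_genes
        ]
        return pd.DataFrame(rows, columns=["cluster", "gene", "category"])

    def test_shared_gene_in_both(self):
        parts = cross_celltype_categories(
            self._calls(["a", "b"], ["b", "c"]), ("stem", "paneth")
        )
        assert parts == {"both": {"b"}, "first_only": {"a"}, "second_only": {"c"}}

    def test_disjoint_sets_empty_both(self):
        parts = cross_celltype_categories(
            self._calls(["a"], ["b"]), ("stem", "paneth")
        )
        assert parts["both"] == set()

    @settings(derandomize=True, max_examples=100)
    @given(
        st.sets(st.sampled_from([f"g{i}" for i in range(10)])),
        st.sets(st.sampled_from([f"g{i}" for i in range(10)])),
    )
    def test_partition_sizes_sum_to_union(self, s1, s2):
        parts = cross_celltype_categories(
            self._calls(sorted(s1), sorted(s2)), ("stem", "paneth")
        )
        total = sum(len(v) for v in parts.values())
        assert total == len(s1 | s2)


class TestSummarizeRescue:
    def test_from_de_table(self):
        rows = (
            _de_rows("stem", "diet", [("g1", -1.0, True), ("g2", 1.0, True), ("g3", -2.0, False)])
            + _de_rows("stem", "surgery", [("g1", 1.0, True), ("g2", 1.0, True)])
        )
        summary, calls = summarize_rescue(pd.DataFrame(rows))
        row = summary.iloc[0]
        assert row["n_diet_degs"] == 2  # g3 fails the filter
        assert row["n_reversed"] == 1  # g1 reversed; g2 concordant
        cats = calls.set_index("gene")["category"]
        assert cats["g1"] == "rescued"
        assert cats["g2"] == "concordant"
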