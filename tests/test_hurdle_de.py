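"""Hurdle DE engine: oracle equivalence against direct likelihood
maximization, degenerate-part handling, calibration, BH adjustment and the
DEG bookkeeping operations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from numpy.linalg import lstsq
from scipy.optimize import minimize

from gutrescue.core import MITO_PANEL
from gutrescue.de import (
    Contrast,
    adjust_bh,
    fit_hurdle_gene,
    hurdle_test_genes,
    mito_gene_panel,
    summarize_directional_counts,
)
from gutrescue.de import test_contrast as run_contrast

from conftest import toy_bundle


# --------------------------------------------------------------- oracle

def _oracle_lrt(y, grp, cov):
    """Independent from-scratch maximized-likelihood difference x2: BFGS for
    the logistic part, profiled-sigma OLS for the Gaussian part."""

    def logit_nll(b, X, d):
        eta = X @ b
        return -(d * eta - np.logaddexp(0, eta)).sum()

    def gauss_ll(X, yy):
        b, *_ = lstsq(X, yy, rcond=None)
        rss = ((yy - X @ b) ** 2).sum()
        n = len(yy)
        return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)

    n = len(y)
    cov = cov.reshape(n, -1)
    Xf = np.column_stack([np.ones(n), grp, cov])
    Xr = np.column_stack([np.ones(n), cov])
    d = (y > 0).astype(float)
    lrt = 0.0
    if 0 < d.sum() < n:
        lf = -minimize(logit_nll, np.zeros(Xf.shape[1]), args=(Xf, d),
                       method="BFGS", options={"gtol": 1e-12}).fun
        lr = -minimize(logit_nll, np.zeros(Xr.shape[1]), args=(Xr, d),
                       method="BFGS", options={"gtol": 1e-12}).fun
        lrt += 2 * (lf - lr)
    pos = y > 0
    if pos.sum() >= Xf.shape[1] + 1 and len(np.unique(grp[pos])) == 2:
        lrt += 2 * (gauss_ll(Xf[pos], y[pos]) - gauss_ll(Xr[pos], y[pos]))
    return lrt


# 20-cell fixture with zeros in both groups
FIXTURE_Y = np.array(
    [0.0, 0.0, 1.2, 2.1, 0.0, 0.8, 0.0, 3.0, 1.1, 0.0,
     0.5, 0.0, 2.2, 1.8, 0.0, 0.0, 2.9, 0.4, 0.0, 1.0]
)
FIXTURE_GROUP = np.repeat([0.0, 1.0], 10)
FIXTURE_COV = np.array(
    [0.3, -1.0, 0.2, 1.5, -0.4, 0.0, 0.7, -0.9, 1.1, -0.2,
     0.5, -0.6, 0.1, 0.9, -1.2, 0.4, -0.3, 0.8, -0.7, 0.6]
)


class TestHurdleFit:
    def test_matches_independent_mle_oracle(self):
        fit = fit_hurdle_gene(FIXTURE_Y, FIXTURE_GROUP, FIXTURE_COV)
        oracle = _oracle_lrt(FIXTURE_Y, FIXTURE_GROUP, FIXTURE_COV)
        assert fit.lrt == pytest.approx(oracle, abs=1e-6)
        assert fit.df == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_30cell_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        y = np.where(rng.random(n) < 0.4, 0.0, rng.gamma(2, 1, n))
        grp = (np.arange(n) >= n // 2).astype(float)
        cov = rng.normal(size=n)
        if not 0 < (y > 0).sum() < n:
            pytest.skip("degenerate draw")
        fit = fit_hurdle_gene(y, grp, cov)
        assert fit.lrt == pytest.approx(_oracle_lrt(y, grp, cov), abs=1e-6)

    def test_vectorized_engine_matches_scalar(self):
        rng = np.random.default_rng(3)
        n, G = 40, 25
        Y = np.where(rng.random((G, n)) < 0.35, 0.0, rng.gamma(2, 1, (G, n)))
        grp = np.repeat([0.0, 1.0], n // 2)
        cov = rng.normal(size=(n, 1))
        res = hurdle_test_genes(Y, grp, cov)
        for g in range(G):
            fit = fit_hurdle_gene(Y[g], grp, cov)
            if fit.tested and not fit.separated:
                assert res.loc[g, "lrt"] == pytest.approx(fit.lrt, abs=1e-5)
                assert res.loc[g, "df"] == fit.df

    def test_identical_groups_null(self):
        y = np.tile([0.0, 1.0, 2.0, 0.0, 0.7], 4)
        grp = np.repeat([0.0, 1.0], 10)
        fit = fit_hurdle_gene(y, grp)
        assert fit.p > 0.9

    def test_all_detected_reduces_to_continuous_df1(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(2, 1, 30) + 0.1
        grp = np.repeat([0.0, 1.0], 15)
        fit = fit_hurdle_gene(y, grp)
        assert fit.df == 1
        assert fit.lrt_discrete == 0.0

    def test_all_zero_gene_not_tested(self):
        fit = fit_hurdle_gene(np.zeros(20), np.repeat([0.0, 1.0], 10))
        assert not fit.tested

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            fit_hurdle_gene(np.ones(10), np.zeros(10))

    def test_power_monotone_in_effect_and_n(self):
        """Detection power rises with both effect size and cells per group."""
        rng = np.random.default_rng(42)
        G = 60
        powers = {}
        for eff in (0.5, 1.0, 1.5):
            for n_half in (50, 150, 300):
                n = 2 * n_half
                grp = np.repeat([0.0, 1.0], n_half)
                lam = np.exp(rng.normal(0, 0.5, G))[:, None] * np.exp(
                    np.log(2) * eff * grp
                )
                counts = rng.poisson(lam, size=(G, n))
                Y = np.log2(1 + counts.astype(float))
                res = hurdle_test_genes(Y, grp)
                powers[(eff, n_half)] = (
                    res.loc[res["tested"], "p"] < 0.05
                ).mean()
        for n_half in (50, 150, 300):
            assert powers[(0.5, n_half)] <= powers[(1.0, n_half)] + 0.02
            assert powers[(1.0, n_half)] <= powers[(1.5, n_half)] + 0.02
        for eff in (0.5, 1.0, 1.5):
            assert powers[(eff, 50)] <= powers[(eff, 150)] + 0.02
            assert powers[(eff, 150)] <= powers[(eff, 300)] + 0.02


class TestAdjustBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_padj_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        assert (adjust_bh(p) >= p).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    def test_matches_bruteforce_step_up_all_orderings(self):
        base = np.array([0.011, 0.04, 0.049, 0.2, 0.9])

        def brute(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = np.inf
            for rank in range(m - 1, -1, -1):
                i = order[rank]
                running = min(running, p[i] * m / (rank + 1))
                adj[i] = min(running, 1.0)
            return adj

        for perm in itertools.permutations(range(5)):
            p = base[list(perm)]
            np.testing.assert_allclose(adjust_bh(p), brute(p), atol=1e-12)


class TestContrast:
    def test_same_groups_rejected(self):
        with pytest.raises(ValueError):
            Contrast("x", "HFD_sham", "HFD_sham")

    def _two_group_bundle(self, effect_genes=(), log2fc=1.5, n_half=150, seed=0):
        rng = np.random.default_rng(seed)
        G = 60
        lam = np.exp(rng.normal(0.3, 0.7, G))
        counts_a = rng.poisson(lam, size=(n_half, G))
        lam_b = lam.copy()
        for g in effect_genes:
            lam_b[g] *= 2.0 ** log2fc
        counts_b = rng.poisson(lam_b, size=(n_half, G))
        counts = np.vstack([counts_a, counts_b])
        conds = ["LFD_sham"] * n_half + ["HFD_sham"] * n_half
        return toy_bundle(counts, conditions=conds)

    def test_planted_effect_recovered(self):
        from gutrescue.cluster import normalize_log

        bundle = self._two_group_bundle(effect_genes=(3,))
        norm = normalize_log(bundle)
        de = run_contrast(
            bundle, norm, np.zeros(bundle.n_cells, dtype=int),
            Contrast.standard("diet"),
        )
        row = de[de["gene"] == "G3"].iloc[0]
        assert row["passes_filter"]
        assert row["direction"] == "up"

    def test_gene_below_min_frac_absent(self):
        from gutrescue.cluster import normalize_log

        bundle = self._two_group_bundle()
        counts = np.asarray(bundle.counts.todense())
        counts[:, 5] = 0
        counts[0, 5] = 3  # detected in <10 % of either group
        bundle = toy_bundle(counts, conditions=bundle.cells["condition"].tolist())
        norm = normalize_log(bundle)
        de = run_contrast(
            bundle, norm, np.zeros(bundle.n_cells, dtype=int),
            Contrast.standard("diet"), min_frac=0.10,
        )
        assert "G5" not in set(de["gene"])

    def test_cluster_missing_group_skipped(self):
        from gutrescue.cluster import normalize_log

        bundle = self._two_group_bundle()
        norm = normalize_log(bundle)
        clusters = np.zeros(bundle.n_cells, dtype=int)
        clusters[bundle.cells["condition"] == "HFD_sham"] = 1  # cluster 0 pure
        de = run_contrast(bundle, norm, clusters, Contrast.standard("diet"))
        assert len(de) == 0


class TestBookkeeping:
    @pytest.mark.parametrize(
        "n_down,n_up,total",
        [(646, 88, 734), (140, 772, 912), (669, 827, 1496), (2400, 2314, 4714)],
    )
    def test_directional_counts_sum_to_total(self, n_down, n_up, total):
        de = pd.DataFrame(
            {
                "cluster": 0,
                "contrast": "diet",
                "gene": [f"g{i}" for i in range(n_down + n_up)],
                "direction": ["down"] * n_down + ["up"] * n_up,
                "passes_filter": True,
            }
        )
        out = summarize_directional_counts(de)
        assert out.loc[0, "n_total"] == total
        assert out.loc[0, "n_total"] == out.loc[0, "n_up"] + out.loc[0, "n_down"]

    def test_empty_table(self):
        de = pd.DataFrame(
            columns=["cluster", "contrast", "gene", "direction", "passes_filter"]
        )
        out = summarize_directional_counts(de)
        assert len(out) == 0

    def test_multiplicity_vs_unique(self):
        de = pd.DataFrame(
            {
                "cluster": [0, 1],
                "contrast": "surgery",
                "gene": ["gA", "gA"],
                "direction": ["up", "up"],
                "passes_filter": True,
            }
        )
        assert summarize_directional_counts(de).loc[0, "n_total"] == 2
        assert (
            summarize_directional_counts(de, unique_genes=True).loc[0, "n_total"] == 1
        )


class TestMitoPanel:
    def test_panel_has_13_genes(self):
        assert len(MITO_PANEL) == 13
        assert all(g.startswith("mt-") for g in MITO_PANEL)

    def _panel_table(self):
        rows = []
        for mode in ("ngenes_only", "ngenes_plus_mito"):
            for g in ("mt-Co1", "mt-Nd6", "gX"):
                rows.append(
                    {
                        "cluster": "stem", "contrast": "surgery", "gene": g,
                        "log2fc": 1.0, "p": 0.001, "padj": 0.01,
                        "direction": "up",
                        "passes_filter": not (g == "mt-Nd6" and mode == "ngenes_plus_mito"),
                        "covariate_mode": mode,
                    }
                )
        return pd.DataFrame(rows)

    def test_restricts_to_panel_and_flags_changes(self):
        panel = mito_gene_panel(self._panel_table(), gene_space=list(MITO_PANEL) + ["gX"])
        assert set(panel["gene"]) == {"mt-Co1", "mt-Nd6"}
        changed = panel[panel["gene"] == "mt-Nd6"]["filter_changed"]
        assert changed.all()
        assert not panel[panel["gene"] == "mt-Co1"]["filter_changed"].any()

    def test_missing_panel_genes_rejected(self):
        with pytest.raises(ValueError, match="mt-"):
            mito_gene_panel(self._panel_table(), gene_space=["gX"])

    def test_empty_table_gives_empty_panel(self):
        de = pd.DataFrame(
            columns=["cluster", "contrast", "gene", "log2fc", "p", "padj",
                     "direction", "passes_filter", "covariate_mode"]
        )
        out = mito_gene_panel(de)
        assert len(out) == 0
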