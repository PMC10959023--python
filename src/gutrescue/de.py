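"""Two-part (hurdle) differential expression with per-cell covariates.

Single-cell expression is zero-inflated: whether a gene is detected at all
and how much is expressed when detected carry separate information.  The
hurdle model therefore combines

* a *discrete* part — logistic regression of detection (y > 0) on the group
  indicator plus covariates — and
* a *continuous* part — a Gaussian model of log-normalized expression among
  the detected cells, on the same design —

and tests the group effect with a likelihood-ratio statistic summed over the
two parts (chi-square, df = number of non-degenerate parts).  Per-cell
detected-gene count (and optionally mitochondrial read fraction) enter as
nuisance covariates.

DEG filtering uses the triple gate p < 0.05, BH-adjusted p < 0.20 and
|log2FC| > 0.50, with log2FC defined as the difference of mean log2
normalized expression (zeros included) between the groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import MITO_PANEL, CountBundle

logger = logging.getLogger(__name__)

#: default contrasts: group_a vs group_b, log2FC positive when higher in group_a
CONTRASTS = {
    "diet": ("HFD_sham", "LFD_sham"),
    "surgery": ("HFD_VSG", "HFD_sham"),
    "residual": ("HFD_VSG", "LFD_sham"),
}

DEFAULT_P = 0.05
DEFAULT_PADJ = 0.20
DEFAULT_MIN_ABS_LOG2FC = 0.50
DEFAULT_MIN_FRAC = 0.10


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison between experimental conditions."""

    name: str
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")

    @classmethod
    def standard(cls, name: str) -> "Contrast":
        a, b = CONTRASTS[name]
        return cls(name, a, b)


# ---------------------------------------------------------------------------
# likelihood machinery


def _logit_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), stable via logaddexp
    return float((y * eta).sum() - np.logaddexp(0.0, eta).sum())


def fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-10):
    """Newton/IRLS logistic MLE.

    Returns (beta, loglik, separated).  ``separated`` flags quasi-complete
    separation (fitted probabilities pinned at 0/1); the achieved loglik is
    still returned, which is what the LRT needs.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll = _logit_loglik(X @ beta, y)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        g = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), g)
        except np.linalg.LinAlgError:
            break
        # step-halving line search
        for _ in range(30):
            cand = beta + step
            ll_new = _logit_loglik(np.clip(X @ cand, -500, 500), y)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        if ll_new < ll + tol and np.abs(step).max() < 1e3:
            beta = cand
            ll = ll_new
            break
        beta = cand
        ll = ll_new
    eta = X @ beta
    separated = bool(np.abs(eta).max() > 25)
    return beta, ll, separated


def _gauss_loglik_from_rss(rss: float, n: int) -> float:
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def _ols_loglik(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    return _gauss_loglik_from_rss(rss, len(y))


@dataclass
class HurdleFit:
    """Result row for one gene: component LRT statistics, combined statistic,
    degrees of freedom and p-value."""

    lrt_discrete: float
    lrt_continuous: float
    lrt: float
    df: int
    p: float
    separated: bool = False
    tested: bool = True


def fit_hurdle_gene(
    y: np.ndarray, group: np.ndarray, covariates: np.ndarray | None = None
) -> HurdleFit:
    """Hurdle LRT of the group effect for one gene.

    Parameters
    ----------
    y
        normalized (log-scale) expression per cell; zeros mean undetected.
    group
        binary indicator per cell; both groups must be non-empty.
    covariates
        optional cells x k matrix of nuisance covariates.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    if group.min() == group.max():
        raise ValueError("both groups must be non-empty")
    n = len(y)
    cov = (
        np.empty((n, 0))
        if covariates is None
        else np.asarray(covariates, dtype=float).reshape(n, -1)
    )
    det = (y > 0).astype(float)
    if det.sum() == 0:
        return HurdleFit(np.nan, np.nan, np.nan, 0, np.nan, tested=False)

    X_red = np.column_stack([np.ones(n), cov])
    X_full = np.column_stack([np.ones(n), group, cov])

    lrt_d = 0.0
    df = 0
    separated = False
    if 0 < det.sum() < n:  # discrete part informative
        _, ll_full, separated = fit_logistic(X_full, det)
        _, ll_red, _ = fit_logistic(X_red, det)
        lrt_d = max(0.0, 2.0 * (ll_full - ll_red))
        df += 1

    lrt_c = 0.0
    pos = det.astype(bool)
    n_pos = int(pos.sum())
    both_pos = pos.any() and len(np.unique(group[pos])) == 2
    if separated:
        # perfect separation: the continuous part is confounded with the
        # group indicator; fall back to the detection part alone
        both_pos = False
    if both_pos and n_pos >= X_full.shape[1] + 1:
        yp = y[pos]
        if np.ptp(yp) > 0:
            ll_full_c = _ols_loglik(X_full[pos], yp)
            ll_red_c = _ols_loglik(X_red[pos], yp)
            lrt_c = max(0.0, 2.0 * (ll_full_c - ll_red_c))
            df += 1

    if df == 0:
        return HurdleFit(lrt_d, lrt_c, lrt_d + lrt_c, 0, np.nan, separated, tested=False)
    lrt = lrt_d + lrt_c
    p = float(stats.chi2.sf(lrt, df))
    return HurdleFit(lrt_d, lrt_c, lrt, df, p, separated)


# ---------------------------------------------------------------------------
# vectorized engine: many genes sharing one design matrix


def _logistic_many(X: np.ndarray, Y: np.ndarray, max_iter: int = 40):
    """Newton iterations for G logistic regressions sharing the design X.

    Y is genes x cells boolean.  Returns (loglik per gene, separated flags).
    """
    G, n = Y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    Yf = Y.astype(float)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T, -30, 30)  # G x n
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu) + 1e-10
        grad = (Yf - mu) @ X  # G x p
        # Hessians: G x p x p
        H = np.einsum("gn,np,nq->gpq", w, X, X)
        try:
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            H = H + 1e-8 * np.eye(p)[None]
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        beta = beta + step
        if np.abs(step).max() < 1e-9:
            break
    eta = beta @ X.T
    ll = (Yf * eta).sum(axis=1) - np.logaddexp(0.0, np.clip(eta, -500, 500)).sum(axis=1)
    separated = np.abs(eta).max(axis=1) > 25
    return ll, separated


def hurdle_test_genes(
    Y: np.ndarray, group: np.ndarray, covariates: np.ndarray | None = None
) -> pd.DataFrame:
    """Hurdle LRT for many genes at once (rows of Y), one shared design.

    Uses a vectorized Newton solver for the logistic parts and per-gene OLS
    for the continuous parts.  Genes with a degenerate discrete part
    (all-detected / none-detected) or a degenerate continuous part fall back
    to the remaining part with df = 1, matching :func:`fit_hurdle_gene`.
    """
    Y = np.asarray(Y, dtype=float)
    group = np.asarray(group, dtype=float)
    G, n = Y.shape
    cov = (
        np.empty((n, 0))
        if covariates is None
        else np.asarray(covariates, dtype=float).reshape(n, -1)
    )
    X_red = np.column_stack([np.ones(n), cov])
    X_full = np.column_stack([np.ones(n), group, cov])

    det = Y > 0
    n_det = det.sum(axis=1)
    informative = (n_det > 0) & (n_det < n)

    lrt_d = np.zeros(G)
    separated = np.zeros(G, dtype=bool)
    if informative.any():
        ll_full, sep = _logistic_many(X_full, det[informative])
        ll_red, _ = _logistic_many(X_red, det[informative])
        lrt_d[informative] = np.maximum(0.0, 2.0 * (ll_full - ll_red))
        separated[informative] = sep
    df = informative.astype(int)

    lrt_c = np.zeros(G)
    min_pos = X_full.shape[1] + 1
    for g in range(G):
        if separated[g]:
            continue
        pos = det[g]
        n_pos = int(pos.sum())
        if n_pos < min_pos or len(np.unique(group[pos])) < 2:
            continue
        yp = Y[g, pos]
        if np.ptp(yp) == 0:
            continue
        lrt_c[g] = max(
            0.0, 2.0 * (_ols_loglik(X_full[pos], yp) - _ols_loglik(X_red[pos], yp))
        )
        df[g] += 1

    lrt = lrt_d + lrt_c
    with np.errstate(invalid="ignore"):
        p = stats.chi2.sf(lrt, np.maximum(df, 1))
    p = np.where(df > 0, p, np.nan)
    return pd.DataFrame(
        {
            "lrt_discrete": lrt_d,
            "lrt_continuous": lrt_c,
            "lrt": lrt,
            "df": df,
            "p": p,
            "separated": separated,
            "tested": (df > 0) & (n_det > 0),
        }
    )


# ---------------------------------------------------------------------------
# BH adjustment and the DE table


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _covariate_matrix(
    bundle: CountBundle, idx: np.ndarray, mode: str
) -> np.ndarray:
    """Per-cell nuisance covariates, z-scored within the tested cell set."""
    n_genes = bundle.genes_detected()[idx].astype(float)
    cols = [_zscore(n_genes)]
    if mode == "ngenes_plus_mito":
        cols.append(_zscore(bundle.mito_fraction()[idx]))
    elif mode != "ngenes_only":
        raise ValueError(f"unknown covariate_mode {mode!r}")
    return np.column_stack(cols)


def test_contrast(
    bundle: CountBundle,
    norm: np.ndarray,
    clusters: np.ndarray,
    contrast: Contrast,
    min_frac: float = DEFAULT_MIN_FRAC,
    covariate_mode: str = "ngenes_only",
    p_thresh: float = DEFAULT_P,
    padj_thresh: float = DEFAULT_PADJ,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    only_clusters=None,
) -> pd.DataFrame:
    """Per-cluster hurdle DE between two conditions.

    For each cluster, genes detected in at least ``min_frac`` of cells in
    either group are tested; BH adjustment is applied within (cluster,
    contrast); log2FC is the difference in mean log2 normalized expression
    (zeros included), positive when higher in ``contrast.group_a``.

    Returns the DE table with columns (cluster, contrast, gene, log2fc, p,
    padj, direction, passes_filter, covariate_mode).
    """
    conditions = bundle.cells["condition"].to_numpy()
    clusters = np.asarray(clusters)
    rows = []
    uniq = [c for c in pd.unique(clusters) if not (isinstance(c, (int, np.integer)) and c < 0)]
    if only_clusters is not None:
        uniq = [c for c in uniq if c in set(only_clusters)]
    for c in sorted(uniq):
        in_c = clusters == c
        a = in_c & (conditions == contrast.group_a)
        b = in_c & (conditions == contrast.group_b)
        if a.sum() == 0 or b.sum() == 0:
            logger.warning(
                "cluster %s lacks cells for %s vs %s; skipped",
                c, contrast.group_a, contrast.group_b,
            )
            continue
        idx = np.flatnonzero(a | b)
        sub = norm[idx]
        grp = (conditions[idx] == contrast.group_a).astype(float)
        det = sub > 0
        frac_a = det[grp == 1].mean(axis=0)
        frac_b = det[grp == 0].mean(axis=0)
        testable = np.flatnonzero((frac_a >= min_frac) | (frac_b >= min_frac))
        if len(testable) == 0:
            continue
        cov = _covariate_matrix(bundle, idx, covariate_mode)
        res = hurdle_test_genes(sub[:, testable].T, grp, cov)
        lfc = sub[grp == 1][:, testable].mean(axis=0) - sub[grp == 0][:, testable].mean(axis=0)
        tab = pd.DataFrame(
            {
                "cluster": c,
                "contrast": contrast.name,
                "gene": bundle.genes["symbol"].to_numpy()[testable],
                "log2fc": lfc,
                "p": res["p"].to_numpy(),
                "df": res["df"].to_numpy(),
            }
        )
        tab = tab[res["tested"].to_numpy()].reset_index(drop=True)
        tab["padj"] = adjust_bh(tab["p"].to_numpy())
        rows.append(tab)
    if not rows:
        return pd.DataFrame(
            columns=[
                "cluster", "contrast", "gene", "log2fc", "p", "df", "padj",
                "direction", "passes_filter", "covariate_mode",
            ]
        )
    de = pd.concat(rows, ignore_index=True)
    de["direction"] = np.where(de["log2fc"] >= 0, "up", "down")
    de["passes_filter"] = (
        (de["p"] < p_thresh)
        & (de["padj"] < padj_thresh)
        & (de["log2fc"].abs() > min_abs_log2fc)
    )
    de["covariate_mode"] = covariate_mode
    return de


def summarize_directional_counts(
    de: pd.DataFrame, scope=None, unique_genes: bool = False
) -> pd.DataFrame:
    """Filtered DEG counts (total / up / down) per contrast over a cluster
    scope.  By default per-cluster rows count with multiplicity (a gene DE in
    two clusters counts twice); ``unique_genes=True`` collapses to unique
    gene symbols.  n_total = n_up + n_down by construction.
    """
    sub = de[de["passes_filter"]] if len(de) else de
    if scope is not None and len(sub):
        sub = sub[sub["cluster"].isin(set(scope))]
    out = []
    contrasts = sub["contrast"].unique() if len(sub) else []
    for ct in contrasts:
        s = sub[sub["contrast"] == ct]
        if unique_genes:
            up = s.loc[s["direction"] == "up", "gene"].nunique()
            down = s.loc[s["direction"] == "down", "gene"].nunique()
        else:
            up = int((s["direction"] == "up").sum())
            down = int((s["direction"] == "down").sum())
        out.append({"contrast": ct, "n_total": up + down, "n_up": up, "n_down": down})
    return pd.DataFrame(out, columns=["contrast", "n_total", "n_up", "n_down"])


def mito_gene_panel(
    de: pd.DataFrame, mito_genes=MITO_PANEL, gene_space=None
) -> pd.DataFrame:
    """Restrict a DE table (stacked over covariate modes) to the 13
    mitochondrial protein-coding genes and flag genes whose filter status
    changes between covariate modes — the robustness check for mito-fraction
    confounding.
    """
    mito_genes = list(mito_genes)
    if gene_space is not None:
        missing = sorted(set(mito_genes) - set(gene_space))
        if missing:
            raise ValueError(f"mitochondrial panel genes absent: {missing}")
    panel = de[de["gene"].isin(set(mito_genes))].copy()
    if len(panel) == 0:
        panel["filter_changed"] = pd.Series(dtype=bool)
        return panel
    pivot = panel.groupby(["cluster", "contrast", "gene"])["passes_filter"].nunique()
    changed = pivot[pivot > 1].index
    key = panel.set_index(["cluster", "contrast", "gene"]).index
    panel["filter_changed"] = key.isin(changed)
    return panel
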