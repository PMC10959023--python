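"""Normalization, graph clustering, marker-based cell-type annotation,
immune-cluster removal, and cell-cycle scoring.

Normalization is scale-factor log transformation (log2(1 + scale * c / total)
per cell); highly variable genes are chosen by standardized dispersion after
binning by mean; clustering is Leiden community detection on a 15-NN graph in
PC space (defaults: 30 PCs, resolution 0.4).  Clusters are assigned to cell
types by the overlap of their top enriched genes (one-vs-rest hurdle test)
with reference lineage marker sets, and clusters matching the immune
signature are flagged for removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scanpy as sc
import anndata as ad

from .core import CountBundle, MarkerReference
from . import de as de_mod

logger = logging.getLogger(__name__)

DEFAULT_N_HVG = 2000
DEFAULT_N_PCS = 30
DEFAULT_RESOLUTION = 0.4
DEFAULT_KNN = 15
DEFAULT_TOP_N_MARKERS = 100
DEFAULT_MIN_MARKER_LFC = 0.50
DEFAULT_OVERLAP_FLOOR = 0.10


def normalize_log(bundle: CountBundle, scale: float = 1e4) -> np.ndarray:
    """Per-cell scale-factor normalization: y = log2(1 + scale * c / total).

    Zeros map to zeros; per-cell rank order of counts is preserved.  Cells
    with zero total counts are an error (they should have been filtered).
    """
    totals = bundle.total_counts().astype(float)
    if (totals == 0).any():
        n0 = int((totals == 0).sum())
        raise ValueError(f"{n0} cells have zero total counts; filter them first")
    X = bundle.counts.multiply(scale / totals[:, None]).tocsr()
    X.data = np.log2(1.0 + X.data)
    return np.asarray(X.todense())


def select_hvg(
    norm: np.ndarray, n: int, n_bins: int = 20, exclude: np.ndarray | None = None
) -> np.ndarray:
    """Indices of the ``n`` genes with highest standardized dispersion.

    Dispersion = variance / mean of normalized expression; genes are binned
    by mean expression and dispersions z-scored within bin, so highly
    expressed genes do not dominate.  Deterministic; constant genes get
    dispersion 0 and rank last (ties broken by gene index).  ``exclude``
    masks genes (e.g. the mitochondrial block) from selection entirely.
    """
    n_genes = norm.shape[1]
    if n > n_genes:
        raise ValueError(f"requested {n} HVGs but only {n_genes} genes present")
    mean = norm.mean(axis=0)
    var = norm.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, n_bins)
    z = np.zeros(n_genes)
    for b in bins:
        if len(b) == 0:
            continue
        mu, sd = disp[b].mean(), disp[b].std()
        z[b] = (disp[b] - mu) / sd if sd > 0 else 0.0
    if exclude is not None:
        z = np.where(np.asarray(exclude, dtype=bool), -np.inf, z)
        n = min(n, int((~np.asarray(exclude, dtype=bool)).sum()))
    # rank by z descending, stable in gene index
    ranked = np.lexsort((np.arange(n_genes), -z))
    return np.sort(ranked[:n])


def cluster_graph(
    norm: np.ndarray,
    hvgs: np.ndarray,
    n_pcs: int = DEFAULT_N_PCS,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
    knn: int = DEFAULT_KNN,
    sample_labels: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Leiden community detection on a kNN graph in PC space of the scaled
    HVG matrix.  Deterministic given the seed.  Returns integer labels.

    ``covariates`` (cells x k, e.g. detected-gene count and mito fraction)
    are regressed out of the scaled matrix gene-wise before PCA, so
    technical per-cell gradients do not drive the graph.  ``sample_labels``
    enables integration-lite: gene means are additionally centered within
    each sample, so sample-level shifts (library batch, condition-wide
    expression changes) do not drive it either — a lightweight stand-in for
    anchor-based sample integration on well-mixed designs.
    """
    X = norm[:, hvgs]
    n_cells = X.shape[0]
    if n_cells <= n_pcs:
        raise ValueError(f"{n_cells} cells cannot support {n_pcs} PCs")
    adata = ad.AnnData(X=X.astype(np.float32))
    sc.pp.scale(adata, max_value=10)
    if covariates is not None:
        C = np.column_stack(
            [np.ones(n_cells), np.asarray(covariates, dtype=float).reshape(n_cells, -1)]
        )
        beta, *_ = np.linalg.lstsq(C, adata.X, rcond=None)
        adata.X = adata.X - (C @ beta).astype(np.float32)
    if sample_labels is not None:
        sample_labels = np.asarray(sample_labels)
        for s in np.unique(sample_labels):
            m = sample_labels == s
            adata.X[m] -= adata.X[m].mean(axis=0, keepdims=True)
    n_comps = min(n_pcs, min(adata.shape) - 1)
    sc.pp.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=knn, use_rep="X_pca", random_state=seed)
    sc.tl.leiden(
        adata,
        resolution=resolution,
        random_state=seed,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    return adata.obs["leiden"].astype(int).to_numpy()


def find_cluster_markers(
    bundle: CountBundle,
    norm: np.ndarray,
    clusters: np.ndarray,
    min_lfc: float = DEFAULT_MIN_MARKER_LFC,
    top_n: int = DEFAULT_TOP_N_MARKERS,
    min_frac: float = de_mod.DEFAULT_MIN_FRAC,
    covariate_mode: str = "ngenes_plus_mito",
) -> dict[int, list[str]]:
    """Top enriched genes per cluster by one-vs-rest hurdle test.

    Candidate genes must exceed ``min_lfc`` mean log2 difference over the
    rest and be detected in at least ``min_frac`` of the cluster's cells;
    candidates are then ranked by hurdle p-value (per-cell detected-gene
    count and mito fraction as covariates) and the top ``top_n`` returned.
    """
    clusters = np.asarray(clusters)
    symbols = bundle.genes["symbol"].to_numpy()
    out: dict[int, list[str]] = {}
    idx_all = np.arange(bundle.n_cells)
    for c in sorted(pd.unique(clusters)):
        in_c = clusters == c
        if in_c.sum() < 2:
            logger.warning("cluster %s has <2 cells; marker search skipped", c)
            out[int(c)] = []
            continue
        lfc = norm[in_c].mean(axis=0) - norm[~in_c].mean(axis=0)
        det_frac = (norm[in_c] > 0).mean(axis=0)
        cand = np.flatnonzero((lfc >= min_lfc) & (det_frac >= min_frac))
        if len(cand) == 0:
            out[int(c)] = []
            continue
        cov = de_mod._covariate_matrix(bundle, idx_all, covariate_mode)
        res = de_mod.hurdle_test_genes(
            norm[:, cand].T, in_c.astype(float), cov
        )
        tab = pd.DataFrame(
            {"gene": symbols[cand], "p": res["p"], "lfc": lfc[cand],
             "tested": res["tested"]}
        )
        tab = tab[tab["tested"]].sort_values(
            ["p", "lfc"], ascending=[True, False], kind="stable"
        )
        out[int(c)] = tab["gene"].head(top_n).tolist()
    return out


@dataclass
class ClusterAssignment:
    """Cluster ids per barcode plus per-cluster annotation."""

    barcode_cluster: pd.Series  # index barcode -> cluster id
    cell_type: dict[int, str] = field(default_factory=dict)
    compartment: dict[int, str] = field(default_factory=dict)
    is_immune: dict[int, bool] = field(default_factory=dict)
    overlap: dict[int, dict[str, float]] = field(default_factory=dict)

    def labels_for(self, bundle: CountBundle) -> np.ndarray:
        return self.barcode_cluster.reindex(bundle.cells["barcode"]).to_numpy()

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": c,
                "cell_type": self.cell_type.get(c, "unassigned"),
                "compartment": self.compartment.get(c, "unknown"),
                "is_immune": self.is_immune.get(c, False),
            }
            for c in sorted(self.cell_type)
        ]
        return pd.DataFrame(rows)


def assign_cell_types(
    marker_lists: dict[int, list[str]],
    ref: MarkerReference,
    bundle: CountBundle | None = None,
    norm: np.ndarray | None = None,
    clusters: np.ndarray | None = None,
    floor: float = DEFAULT_OVERLAP_FLOOR,
) -> ClusterAssignment:
    """Label clusters by marker overlap with the reference.

    The overlap score for (cluster, cell type) is |top markers ∩ reference
    set| / |reference set|; the argmax wins if it clears ``floor``, otherwise
    the cluster is "unassigned".  Ties are broken by mean reference-marker
    expression in the cluster when expression is supplied, else
    alphabetically.  A cluster whose best match is the immune set is flagged
    ``is_immune``.
    """
    if not ref.sets:
        raise ValueError("marker reference is empty")
    cell_type: dict[int, str] = {}
    is_immune: dict[int, bool] = {}
    overlaps: dict[int, dict[str, float]] = {}
    compartment: dict[int, str] = {}
    sym_to_col = (
        {s: j for j, s in enumerate(bundle.genes["symbol"])} if bundle is not None else {}
    )
    for c, markers in marker_lists.items():
        mset = set(markers)
        scores = {
            ct: len(mset & genes) / len(genes) for ct, genes in ref.sets.items()
        }
        overlaps[c] = scores
        best = max(scores.values()) if scores else 0.0
        if not mset or best < floor or best == 0.0:
            cell_type[c] = "unassigned"
            is_immune[c] = False
            continue
        tied = sorted(ct for ct, s in scores.items() if s == best)
        if len(tied) > 1 and norm is not None and clusters is not None:
            means = {}
            in_c = np.asarray(clusters) == c
            for ct in tied:
                cols = [sym_to_col[g] for g in ref.sets[ct] if g in sym_to_col]
                means[ct] = norm[np.ix_(in_c, cols)].mean() if cols else -np.inf
            winner = max(tied, key=lambda ct: (means[ct], ct))
        else:
            winner = tied[0]
        cell_type[c] = winner
        is_immune[c] = winner == ref.immune_label

    if bundle is not None and clusters is not None:
        comp = bundle.cells["compartment"].to_numpy()
        for c in marker_lists:
            in_c = np.asarray(clusters) == c
            if in_c.any():
                vals, counts = np.unique(comp[in_c], return_counts=True)
                compartment[c] = str(vals[counts.argmax()])
    barcode_cluster = (
        pd.Series(
            np.asarray(clusters),
            index=bundle.cells["barcode"].to_numpy(),
            name="cluster",
        )
        if bundle is not None and clusters is not None
        else pd.Series(dtype=int)
    )
    return ClusterAssignment(
        barcode_cluster=barcode_cluster,
        cell_type=cell_type,
        compartment=compartment,
        is_immune=is_immune,
        overlap=overlaps,
    )


def drop_immune(
    bundle: CountBundle, assignment: ClusterAssignment, clusters: np.ndarray
) -> tuple[CountBundle, np.ndarray]:
    """Remove all cells in clusters flagged immune.  Idempotent."""
    clusters = np.asarray(clusters)
    immune_ids = {c for c, flag in assignment.is_immune.items() if flag}
    keep = ~np.isin(clusters, list(immune_ids))
    return bundle.subset_cells(keep), clusters[keep]


def _score_with_controls(
    norm: np.ndarray, gene_cols: np.ndarray, ctrl_cols: np.ndarray
) -> np.ndarray:
    """Mean expression of a gene set minus mean expression of a control set."""
    return norm[:, gene_cols].mean(axis=1) - norm[:, ctrl_cols].mean(axis=1)


def score_cell_cycle(
    norm: np.ndarray,
    symbols,
    s_genes,
    g2m_genes,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression-bin-matched S and G2/M scores per cell.

    For each marker set, control genes are sampled (seeded) from the mean-
    expression bin of each marker, and the score is mean(marker expression)
    - mean(control expression); the phase call is the argmax of (S, G2M) if
    either score is positive, else G1.  Invariant to gene order.
    """
    symbols = np.asarray(list(symbols))
    lookup = {s: j for j, s in enumerate(symbols)}
    rng = np.random.default_rng(seed)
    mean = norm.mean(axis=0)
    # canonical ordering by (mean, symbol) so results do not depend on the
    # storage order of the gene space
    order = np.lexsort((symbols, mean))
    bin_of = np.empty(len(symbols), dtype=int)
    for i, b in enumerate(np.array_split(order, n_bins)):
        bin_of[b] = i
    by_bin = {
        i: sorted(np.flatnonzero(bin_of == i), key=lambda j: symbols[j])
        for i in range(n_bins)
    }

    scores = {}
    for name, gene_set in (("S_score", s_genes), ("G2M_score", g2m_genes)):
        marker_syms = sorted(g for g in set(gene_set) if g in lookup)
        if not marker_syms:
            raise ValueError(f"no {name} marker genes present in the gene space")
        cols = np.array([lookup[g] for g in marker_syms], dtype=int)
        ctrl: set[str] = set()
        for j in cols:
            pool = by_bin[bin_of[j]]
            take = min(n_ctrl, len(pool))
            picks = rng.choice(len(pool), size=take, replace=False)
            ctrl.update(symbols[pool[i]] for i in picks)
        ctrl_cols = np.array([lookup[s] for s in sorted(ctrl)], dtype=int)
        scores[name] = _score_with_controls(norm, cols, ctrl_cols)

    out = pd.DataFrame(scores)
    phase = np.where(
        (out["S_score"] <= 0) & (out["G2M_score"] <= 0),
        "G1",
        np.where(out["S_score"] >= out["G2M_score"], "S", "G2M"),
    )
    out["phase"] = phase
    return out
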