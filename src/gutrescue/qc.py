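"""Quality control: ambient-RNA ("soup") estimation and correction, doublet
scoring, and cell-level filtering.

The ambient stage follows the soup-correction logic used for droplet data:
the soup expression profile is read off barcodes with near-empty totals, the
contaminated fraction ``rho`` is estimated from genes that a coarse cluster
should not express (whatever such a cluster does show of them must have come
from the soup), and counts are corrected by subtracting each cell's expected
soup contribution.

Cell filters mirror the standard gates for intestinal epithelium droplet
data: cells with fewer than 750 detected genes or more than 20 % of reads
mapping to mitochondrial genes are removed, as are called doublets.  The
boundary is kept: exactly 750 genes or exactly 20.00 % mito is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core import CountBundle

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 750
DEFAULT_MAX_MITO = 0.20
DEFAULT_EMPTY_TOTAL_MAX = 100


@dataclass
class AmbientEstimate:
    """Soup profile (per-gene fractions summing to 1) and estimated
    contamination fraction rho_hat in [0, 0.5]."""

    profile: np.ndarray
    rho_hat: float

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.min() < 0:
            raise ValueError("ambient profile has negative entries")
        if abs(self.profile.sum() - 1.0) > 1e-9:
            raise ValueError("ambient profile must sum to 1")


def _log_cpm(counts: sp.spmatrix, scale: float = 1e4) -> np.ndarray:
    totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    totals = np.maximum(totals, 1.0)
    X = counts.multiply(scale / totals[:, None]).tocsr()
    X.data = np.log2(1.0 + X.data)
    return np.asarray(X.todense())


def estimate_ambient(
    bundle: CountBundle,
    empty_total_max: int = DEFAULT_EMPTY_TOTAL_MAX,
    n_coarse: int = 8,
    min_profile_quantile: float = 0.5,
    specificity: float = 5.0,
    seed: int = 0,
) -> AmbientEstimate:
    """Estimate the soup profile and contamination fraction.

    The profile is the normalized summed counts over empty barcodes (total
    counts <= ``empty_total_max``).  For rho, cells are coarsely clustered
    (KMeans on PCA of log-normalized counts) and cluster-exclusive marker
    genes are identified from pseudobulk profiles (expression share in the
    top cluster at least ``specificity`` times that in any other cluster).
    In every cluster that should not express a marker, whatever expression is
    observed must have come from the soup, so rho is the pooled ratio of
    observed off-cluster marker counts to their expected soup counts
    (rho * cluster total * soup fraction).  Pooling counts rather than
    averaging per-gene ratios avoids minimum-order-statistic bias.  The
    estimate is clipped to [0, 0.5].
    """
    totals = bundle.total_counts()
    empty = totals <= empty_total_max
    if not empty.any():
        raise ValueError(
            f"no barcodes with total counts <= {empty_total_max}; "
            "lower empty_total_max or provide unfiltered droplet data"
        )
    soup_counts = np.asarray(bundle.counts[empty].sum(axis=0)).ravel().astype(float)
    if soup_counts.sum() == 0:
        raise ValueError("empty barcodes contain no counts")
    profile = soup_counts / soup_counts.sum()

    cell_mask = ~empty
    cells = bundle.counts[cell_mask]
    n_cells = cells.shape[0]
    k = min(n_coarse, max(1, n_cells))
    if n_cells < 2 * k:
        k = max(1, n_cells // 2)

    X = _log_cpm(cells)
    n_pcs = min(20, X.shape[0] - 1, X.shape[1] - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    labels = KMeans(n_clusters=k, n_init=3, random_state=seed).fit_predict(pcs)

    uniq = np.unique(labels)
    pb = np.vstack(
        [np.asarray(cells[labels == c].sum(axis=0)).ravel() for c in uniq]
    ).astype(float)
    cluster_totals = pb.sum(axis=1)
    frac = pb / np.maximum(cluster_totals[:, None], 1.0)

    abundant = (profile > 0) & (
        profile >= np.quantile(profile[profile > 0], min_profile_quantile)
    )
    top_frac = frac.max(axis=0)
    # a cluster "expresses" a gene if it carries a non-trivial share of the
    # top cluster's level; soup leakage sits well below this at rho <= 0.5
    expressing = frac >= (1.0 / specificity) * np.maximum(top_frac, 1e-300)[None, :]
    n_expr = expressing.sum(axis=0)
    k_clusters = frac.shape[0]
    specific = abundant & (n_expr <= max(1, k_clusters // 2)) & (top_frac > 0)
    if not specific.any():
        logger.warning(
            "no cluster-specific genes found (homogeneous data?); "
            "rho_hat falls back to 0"
        )
        return AmbientEstimate(profile=profile, rho_hat=0.0)

    off = ~expressing & specific[None, :]
    obs = pb[off].sum()
    exp = (cluster_totals[:, None] * profile[None, :] * off).sum()
    rho_hat = float(np.clip(obs / exp if exp > 0 else 0.0, 0.0, 0.5))
    return AmbientEstimate(profile=profile, rho_hat=rho_hat)


def estimate_ambient_per_sample(
    bundle: CountBundle,
    empty_total_max: int = DEFAULT_EMPTY_TOTAL_MAX,
    n_coarse: int = 8,
    min_profile_quantile: float = 0.5,
    specificity: float = 5.0,
    seed: int = 0,
) -> dict[str, AmbientEstimate]:
    """Per-sample soup estimates with *jointly* derived cluster structure.

    Coarse clusters and cluster-specific genes are computed across all
    samples at once (a sample holding a single cell type cannot support its
    own cluster structure; pooling is what soup-correction tools expect when
    given externally derived clusters).  Each sample then gets its own soup
    profile (from its empty barcodes) and its own pooled off-cluster
    marker ratio as rho.
    """
    totals = bundle.total_counts()
    empty = totals <= empty_total_max
    if not empty.any():
        raise ValueError(
            f"no barcodes with total counts <= {empty_total_max}; "
            "lower empty_total_max or provide unfiltered droplet data"
        )
    cell_mask = ~empty
    cells = bundle.counts[cell_mask]
    samples_all = bundle.cells["sample"].to_numpy()
    samples = samples_all[cell_mask]

    # pooled soup profile just for candidate-gene selection
    pooled_soup = np.asarray(bundle.counts[empty].sum(axis=0)).ravel().astype(float)
    if pooled_soup.sum() == 0:
        raise ValueError("empty barcodes contain no counts")
    pooled_profile = pooled_soup / pooled_soup.sum()

    n_cells = cells.shape[0]
    k = min(n_coarse, max(1, n_cells))
    if n_cells < 2 * k:
        k = max(1, n_cells // 2)
    X = _log_cpm(cells)
    n_pcs = min(20, X.shape[0] - 1, X.shape[1] - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    labels = KMeans(n_clusters=k, n_init=3, random_state=seed).fit_predict(pcs)

    uniq = np.unique(labels)
    pb = np.vstack(
        [np.asarray(cells[labels == c].sum(axis=0)).ravel() for c in uniq]
    ).astype(float)
    frac = pb / np.maximum(pb.sum(axis=1)[:, None], 1.0)
    abundant = (pooled_profile > 0) & (
        pooled_profile
        >= np.quantile(pooled_profile[pooled_profile > 0], min_profile_quantile)
    )
    top_frac = frac.max(axis=0)
    expressing = frac >= (1.0 / specificity) * np.maximum(top_frac, 1e-300)[None, :]
    specific = abundant & (expressing.sum(axis=0) <= max(1, len(uniq) // 2)) & (
        top_frac > 0
    )

    out: dict[str, AmbientEstimate] = {}
    for s in pd.unique(samples_all):
        s_empty = empty & (samples_all == s)
        soup_s = np.asarray(bundle.counts[s_empty].sum(axis=0)).ravel().astype(float)
        profile_s = soup_s / soup_s.sum() if soup_s.sum() > 0 else pooled_profile
        if not specific.any():
            out[s] = AmbientEstimate(profile=profile_s, rho_hat=0.0)
            continue
        in_s = samples == s
        obs = 0.0
        exp = 0.0
        for ci, c in enumerate(uniq):
            rows = in_s & (labels == c)
            if not rows.any():
                continue
            pb_sc = np.asarray(cells[rows].sum(axis=0)).ravel().astype(float)
            off = ~expressing[ci] & specific
            obs += pb_sc[off].sum()
            exp += (pb_sc.sum() * profile_s[off]).sum()
        rho = float(np.clip(obs / exp if exp > 0 else 0.0, 0.0, 0.5))
        out[s] = AmbientEstimate(profile=profile_s, rho_hat=rho)
    return out


def correct_ambient(bundle: CountBundle, est: AmbientEstimate) -> CountBundle:
    """Subtract the expected soup contribution from every count.

    corrected[i, g] = max(0, round(c[i, g] - rho_hat * t_i * profile[g]))
    with round-half-away-from-zero.  Never increases a count; output stays
    integral.  Zero entries stay zero, so the sparse structure is preserved.
    """
    if len(est.profile) != bundle.n_genes:
        raise ValueError(
            f"ambient profile covers {len(est.profile)} genes but bundle has "
            f"{bundle.n_genes}"
        )
    if est.rho_hat == 0:
        return bundle.copy()
    totals = bundle.total_counts().astype(float)
    out = bundle.counts.tocoo(copy=True)
    expected = est.rho_hat * totals[out.row] * est.profile[out.col]
    corrected = np.floor(out.data - expected + 0.5)
    out.data = np.clip(corrected, 0, out.data).astype(np.int64)
    return CountBundle(
        counts=sp.csr_matrix(out), cells=bundle.cells.copy(), genes=bundle.genes.copy()
    )


def score_doublets(
    bundle: CountBundle,
    k: int = 20,
    n_artificial: int | None = None,
    seed: int = 0,
    expected_rate: float = 0.05,
    n_pcs: int = 20,
) -> pd.DataFrame:
    """kNN doublet scoring against artificial same-sample cell-pair sums.

    Generates artificial doublets, co-embeds real and artificial barcodes in
    PCA space of log-normalized counts, and scores each real barcode as the
    fraction of artificial doublets among its ``k`` nearest neighbors.
    Barcodes with score above the (1 - expected_rate) quantile are called.

    Returns a DataFrame (barcode, doublet_score, is_doublet_called).
    """
    n = bundle.n_cells
    if n_artificial is None:
        n_artificial = n
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} cells, got {n}")
    rng = np.random.default_rng(seed)

    samples = bundle.cells["sample"].to_numpy()
    by_sample = {s: np.flatnonzero(samples == s) for s in np.unique(samples)}
    eligible = [s for s, idx in by_sample.items() if len(idx) >= 2]
    pairs_a = np.empty(n_artificial, dtype=int)
    pairs_b = np.empty(n_artificial, dtype=int)
    for i in range(n_artificial):
        s = eligible[int(rng.integers(len(eligible)))]
        a, b = rng.choice(by_sample[s], size=2, replace=False)
        pairs_a[i], pairs_b[i] = a, b
    art = bundle.counts[pairs_a] + bundle.counts[pairs_b]

    stacked = sp.vstack([bundle.counts, art], format="csr")
    X = _log_cpm(stacked)
    n_pcs = min(n_pcs, X.shape[0] - 1, X.shape[1] - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs[:n])
    neigh = idx[:, 1:]  # drop self
    scores = (neigh >= n).mean(axis=1)

    if expected_rate <= 0:
        called = np.zeros(n, dtype=bool)
    else:
        thresh = np.quantile(scores, 1.0 - expected_rate)
        called = scores > thresh
    return pd.DataFrame(
        {
            "barcode": bundle.cells["barcode"],
            "doublet_score": scores,
            "is_doublet_called": called,
        }
    )


def compute_cell_qc(
    bundle: CountBundle,
    doublet_calls: pd.DataFrame | None = None,
    min_genes: int = DEFAULT_MIN_GENES,
    max_mito: float = DEFAULT_MAX_MITO,
) -> pd.DataFrame:
    """Per-cell QC table with the keep flag.

    keep <=> n_genes_detected >= min_genes AND mito_fraction <= max_mito AND
    not doublet-called.
    """
    qc = pd.DataFrame(
        {
            "barcode": bundle.cells["barcode"],
            "n_genes_detected": bundle.genes_detected(),
            "total_counts": bundle.total_counts(),
            "mito_fraction": bundle.mito_fraction(),
        }
    )
    if doublet_calls is not None:
        calls = doublet_calls.set_index("barcode")
        qc["doublet_score"] = calls["doublet_score"].reindex(qc["barcode"]).fillna(0.0).to_numpy()
        qc["is_doublet_called"] = (
            calls["is_doublet_called"].reindex(qc["barcode"]).fillna(False).to_numpy().astype(bool)
        )
    else:
        qc["doublet_score"] = 0.0
        qc["is_doublet_called"] = False
    qc["keep"] = (
        (qc["n_genes_detected"] >= min_genes)
        & (qc["mito_fraction"] <= max_mito)
        & ~qc["is_doublet_called"]
    )
    return qc


def filter_cells(bundle: CountBundle, qc: pd.DataFrame) -> CountBundle:
    """Retain exactly the barcodes flagged keep=True.  Idempotent."""
    keep = qc.set_index("barcode")["keep"]
    missing = set(bundle.cells["barcode"]) - set(keep.index)
    if missing:
        raise ValueError(
            f"QC table missing {len(missing)} barcodes, e.g. {sorted(missing)[:3]}"
        )
    mask = keep.reindex(bundle.cells["barcode"]).to_numpy().astype(bool)
    return bundle.subset_cells(mask)
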