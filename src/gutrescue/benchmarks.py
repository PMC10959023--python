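"""Ground-truth evaluation routines on synthetic data.

Each function generates data with the study-condition generator defaults,
runs the relevant pipeline stages from scratch, and scores the result
against the planted truth: hurdle-test type-I calibration, soup-fraction
(rho) recovery, clustering/annotation recovery, and recovery of the planted
rescue/specificity percentages.  Used by the acceptance checks and usable as
a sanity harness when tuning the generator for new designs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import cluster as cl
from . import de as de_mod
from . import qc as qc_mod
from . import rescue as rs
from .core import MarkerReference
from .simulate import SimConfig, inject_ambient, simulate_bundle, simulate_counts


def type_i_error(
    n_genes: int = 2000,
    n_per_group: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Empirical type-I error of the hurdle test on null NB genes.

    Both groups are drawn from identical negative-binomial distributions
    (log-normal gene means, shared dispersion); expression is log-normalized
    and tested with the detected-gene-count covariate, exactly as in the
    pipeline's DE stage.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    grp = np.repeat([0.0, 1.0], n_per_group)
    lam = rng.lognormal(0.0, 1.0, size=n_genes)
    size = 10.0
    counts = rng.negative_binomial(
        size, size / (size + lam[:, None] * np.ones(n)), size=(n_genes, n)
    )
    totals = np.maximum(counts.sum(axis=0), 1).astype(float)
    Y = np.log2(1.0 + 1e4 * counts / totals)
    ngenes = (counts > 0).sum(axis=0).astype(float)
    sd = ngenes.std()
    cov = ((ngenes - ngenes.mean()) / sd if sd > 0 else np.zeros(n))[:, None]
    res = de_mod.hurdle_test_genes(Y, grp, cov)
    p = res.loc[res["tested"], "p"]
    return float((p < alpha).mean())


def rho_recovery(
    rhos=(0.03, 0.165, 0.279), n_seeds: int = 20, base_seed: int = 0
) -> pd.DataFrame:
    """Absolute error of the soup-fraction estimator at planted rho values."""
    rows = []
    for rho in rhos:
        for i in range(n_seeds):
            seed = base_seed + i
            cfg = SimConfig(seed=seed, rho=rho)
            bundle, _ = simulate_counts(cfg)
            bundle = inject_ambient(
                bundle, rho=rho, seed=seed + 10_000, n_empty=cfg.n_empty_droplets
            )
            est = qc_mod.estimate_ambient(bundle)
            rows.append({"rho": rho, "seed": seed, "rho_hat": est.rho_hat,
                         "abs_error": abs(est.rho_hat - rho)})
    return pd.DataFrame(rows)


def _qc_and_cluster(bundle, truth, config: SimConfig, seed: int):
    """Shared QC -> clustering -> annotation path (pipeline equivalent)."""
    est_bundles = []
    samples = bundle.cells["sample"].to_numpy()
    import scipy.sparse as sp

    estimates = qc_mod.estimate_ambient_per_sample(bundle, seed=seed)
    order = []
    for s in pd.unique(samples):
        mask = samples == s
        sub = bundle.subset_cells(mask)
        est_bundles.append(qc_mod.correct_ambient(sub, estimates[s]))
        order.append(np.flatnonzero(mask))
    perm = np.concatenate(order)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    from .core import CountBundle

    stacked = CountBundle(
        counts=sp.vstack([b.counts for b in est_bundles], format="csr")[inv],
        cells=pd.concat([b.cells for b in est_bundles], ignore_index=True)
        .iloc[inv]
        .reset_index(drop=True),
        genes=bundle.genes.copy(),
    )
    nonempty = stacked.subset_cells(stacked.total_counts() > 100)
    dbl = qc_mod.score_doublets(
        nonempty, k=20, seed=seed, expected_rate=config.doublet_rate
    )
    filtered = qc_mod.filter_cells(nonempty, qc_mod.compute_cell_qc(nonempty, dbl))
    norm = cl.normalize_log(filtered)
    hvgs = cl.select_hvg(
        norm,
        min(cl.DEFAULT_N_HVG, filtered.n_genes),
        exclude=filtered.genes["is_mito"].to_numpy(),
    )
    cov = np.column_stack([filtered.genes_detected(), filtered.mito_fraction()])
    labels = cl.cluster_graph(
        norm,
        hvgs,
        n_pcs=min(cl.DEFAULT_N_PCS, len(hvgs) - 1),
        seed=seed,
        sample_labels=filtered.cells["sample"].to_numpy(),
        covariates=cov,
    )
    return filtered, norm, labels


def clustering_ari(n_seeds: int = 20, base_seed: int = 0) -> pd.DataFrame:
    """Leiden recovery of planted clusters on well-separated data (cluster
    structure only; no condition effects)."""
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = SimConfig(
            seed=seed,
            de_fraction=0.0,
            rescue_fraction=0.0,
            surgery_only_fraction=0.0,
            n_mito_rescued=0,
        )
        bundle, truth = simulate_bundle(cfg)
        filtered, _, labels = _qc_and_cluster(bundle, truth, cfg, seed)
        tl = np.array(
            [truth.cluster_labels.get(bc, -1) for bc in filtered.cells["barcode"]]
        )
        m = tl >= 0
        rows.append(
            {
                "seed": seed,
                "n_communities": len(set(labels)),
                "ari": adjusted_rand_score(tl[m], labels[m]),
            }
        )
    return pd.DataFrame(rows)


def annotation_recovery(seed: int = 0, config: SimConfig | None = None) -> dict:
    """Cell-type label recovery on the default study-condition generator
    (planted DE present; subclusters may form but must annotate correctly)."""
    cfg = config or SimConfig(seed=seed)
    bundle, truth = simulate_bundle(cfg)
    filtered, norm, labels = _qc_and_cluster(bundle, truth, cfg, seed)
    markers = cl.find_cluster_markers(filtered, norm, labels)
    assignment = cl.assign_cell_types(
        markers, MarkerReference.builtin(), bundle=filtered, norm=norm, clusters=labels
    )
    tl = np.array(
        [truth.cluster_labels.get(bc, -1) for bc in filtered.cells["barcode"]]
    )
    m = tl >= 0
    true_types = np.array([truth.cell_types[c] for c in tl[m]])
    pred_types = np.array([assignment.cell_type[c] for c in np.asarray(labels)[m]])
    return {
        "label_accuracy": float((true_types == pred_types).mean()),
        "label_ari": float(adjusted_rand_score(true_types, pred_types)),
        "all_types_recovered": set(true_types) == set(pred_types),
    }


def rescue_recovery(
    seed: int = 0, surgery_only_fraction: float = 0.05
) -> pd.DataFrame:
    """Full-path estimate of rescue/specificity on the study-condition
    generator: simulate -> soup correction -> doublet & cell filters ->
    cluster -> annotate -> hurdle DE (diet + surgery) -> reversal summary.
    """
    cfg = SimConfig(seed=seed, surgery_only_fraction=surgery_only_fraction)
    bundle, truth = simulate_bundle(cfg)
    filtered, norm, labels = _qc_and_cluster(bundle, truth, cfg, seed)
    markers = cl.find_cluster_markers(filtered, norm, labels)
    assignment = cl.assign_cell_types(
        markers, MarkerReference.builtin(), bundle=filtered, norm=norm, clusters=labels
    )
    cell_types = np.array([assignment.cell_type[c] for c in labels], dtype=object)
    de = pd.concat(
        [
            de_mod.test_contrast(
                filtered, norm, cell_types, de_mod.Contrast.standard(c)
            )
            for c in ("diet", "surgery")
        ],
        ignore_index=True,
    )
    summary, _ = rs.summarize_rescue(de)
    summary["seed"] = seed
    summary["surgery_only_fraction"] = surgery_only_fraction
    return summary
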