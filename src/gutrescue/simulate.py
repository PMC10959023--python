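"""Droplet scRNA-seq simulator for the three-arm diet/surgery design.

Generates CellRanger-style count bundles for a two-compartment (crypt /
villus), three-condition (LFD_sham, HFD_sham, HFD_VSG) experiment with fully
known ground truth:

* cluster structure: each cluster is an intestinal epithelial cell type with
  near-exclusive marker genes drawn from the bundled marker reference;
* diet perturbation: a configurable fraction of genes per cluster shift their
  negative-binomial log-mean by ``±de_log2fc`` in both high-fat-diet arms;
* surgical rescue: a configurable fraction of those diet-perturbed genes
  revert to the control mean in the HFD_VSG arm (so the surgery contrast sees
  them move in the opposite direction), plus surgery-only effects;
* a mitochondrial gene block whose per-cell read fraction is Beta-distributed
  with an upper tail past the 20 % QC gate, with optional planted rescue of
  mitochondrial protein-coding genes;
* ambient ("soup") contamination at a controllable fraction rho, empty
  droplets, and planted same-sample doublets.

Every planted effect is recorded in :class:`SimTruth` so downstream stages
can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import (
    CONDITIONS,
    MITO_PANEL,
    CountBundle,
    MarkerReference,
    builtin_cell_cycle_genes,
)


class SimConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


# cluster identities cycle through this order; compartment is the cell type's
# home along the crypt-villus axis
_CELL_TYPE_CYCLE = (
    ("stem", "crypt"),
    ("enterocyte", "villus"),
    ("paneth", "crypt"),
    ("eec", "villus"),
    ("goblet", "crypt"),
    ("tuft", "villus"),
)


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults describe the study conditions emulated throughout the test
    suite: three epithelial clusters, 300 cells per cluster per condition,
    diet effects of 1.5 log2 units on 10 % of genes, 60 % of which are
    reverted by surgery.
    """

    n_clusters: int = 3
    cells_per_cluster_per_condition: int = 300
    n_genes: int = 1500
    n_mito_genes: int = 13
    baseline_mean: float = 1.0
    nb_dispersion: float = 0.1
    de_fraction: float = 0.10
    de_log2fc: float = 1.5
    rescue_fraction: float = 0.6
    surgery_only_fraction: float = 0.05
    rho: float = 0.05
    doublet_rate: float = 0.05
    n_empty_droplets: int = 2000
    seed: int = 0
    # generator shape knobs
    markers_per_cluster: int = 40
    marker_log2fc: float = 3.0
    marker_off_factor: float = 0.005
    gene_mean_sigma: float = 1.0
    library_sigma: float = 0.25
    mito_fraction_mean: float = 0.08
    mito_fraction_conc: float = 25.0
    n_mito_rescued: int = 6
    cc_boost: float = 2.0
    n_immune_clusters: int = 0
    rescue_completeness: float = 1.0  # 1 = full reversion to control mean

    def validate(self) -> None:
        fracs = {
            "de_fraction": self.de_fraction,
            "rescue_fraction": self.rescue_fraction,
            "surgery_only_fraction": self.surgery_only_fraction,
            "doublet_rate": self.doublet_rate,
            "rescue_completeness": self.rescue_completeness,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise SimConfigError(f"rho={self.rho} outside [0, 1)")
        if self.n_mito_genes > self.n_genes:
            raise SimConfigError("n_mito_genes exceeds n_genes")
        if self.rescue_fraction > 0 and self.de_fraction == 0:
            raise SimConfigError(
                "rescue_fraction > 0 requires de_fraction > 0 (no diet DEGs to rescue)"
            )
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise SimConfigError("baseline_mean and nb_dispersion must be positive")
        if min(self.n_clusters, self.cells_per_cluster_per_condition, self.n_genes) < 1:
            raise SimConfigError("n_clusters, cells and genes must be >= 1")


@dataclass
class SimTruth:
    """Planted ground truth of a simulated bundle.

    Directions follow the contrast conventions used downstream: ``diet_degs``
    records the sign of the HFD_sham-vs-LFD_sham change, ``surgery_degs`` the
    sign of the HFD_VSG-vs-HFD_sham change.
    """

    diet_degs: dict[int, dict[str, str]] = field(default_factory=dict)
    surgery_degs: dict[int, dict[str, str]] = field(default_factory=dict)
    rescued: dict[int, frozenset[str]] = field(default_factory=dict)
    rho_true: float = 0.0
    doublet_barcodes: frozenset[str] = frozenset()
    cluster_labels: dict[str, int] = field(default_factory=dict)
    cell_types: dict[int, str] = field(default_factory=dict)
    immune_clusters: frozenset[int] = frozenset()

    def validate(self) -> None:
        for k, resc in self.rescued.items():
            diet = self.diet_degs.get(k, {})
            surg = self.surgery_degs.get(k, {})
            for g in resc:
                if g not in diet or g not in surg:
                    raise AssertionError(
                        f"rescued gene {g} in cluster {k} missing from a DEG map"
                    )
                if diet[g] == surg[g]:
                    raise AssertionError(
                        f"rescued gene {g} in cluster {k} has same direction "
                        "in both contrasts"
                    )

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["rescued"] = {k: sorted(v) for k, v in self.rescued.items()}
        payload["doublet_barcodes"] = sorted(self.doublet_barcodes)
        payload["immune_clusters"] = sorted(self.immune_clusters)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            diet_degs={int(k): v for k, v in d["diet_degs"].items()},
            surgery_degs={int(k): v for k, v in d["surgery_degs"].items()},
            rescued={int(k): frozenset(v) for k, v in d["rescued"].items()},
            rho_true=d["rho_true"],
            doublet_barcodes=frozenset(d["doublet_barcodes"]),
            cluster_labels=d["cluster_labels"],
            cell_types={int(k): v for k, v in d["cell_types"].items()},
            immune_clusters=frozenset(d["immune_clusters"]),
        )


def _build_gene_table(config: SimConfig, rng: np.random.Generator):
    """Assemble the gene space: mito panel, cell-cycle genes, cluster markers,
    then anonymous filler genes."""
    ref = MarkerReference.builtin()
    s_genes, g2m_genes = builtin_cell_cycle_genes()

    if config.n_mito_genes <= len(MITO_PANEL):
        mito = list(MITO_PANEL[: config.n_mito_genes])
    else:
        mito = list(MITO_PANEL) + [
            f"mt-x{i}" for i in range(config.n_mito_genes - len(MITO_PANEL))
        ]

    n_epi = config.n_clusters
    types = [
        _CELL_TYPE_CYCLE[k % len(_CELL_TYPE_CYCLE)] for k in range(n_epi)
    ]
    cluster_types = [t for t, _ in types]
    compartments = [c for _, c in types]
    for _ in range(config.n_immune_clusters):
        cluster_types.append("immune")
        compartments.append("crypt")

    marker_sets: list[list[str]] = []
    used: set[str] = set(mito)
    for k, ct in enumerate(cluster_types):
        base = sorted(ref.sets[ct] - used)
        used.update(base)
        extra = max(0, config.markers_per_cluster - len(base))
        base += [f"mk{k}_{i:03d}" for i in range(extra)]
        marker_sets.append(base)

    cc = [g for g in s_genes + g2m_genes if g not in used]
    used.update(cc)

    n_named = len(mito) + sum(len(m) for m in marker_sets) + len(cc)
    n_filler = config.n_genes - n_named
    if n_filler < 0:
        raise SimConfigError(
            f"n_genes={config.n_genes} too small for {n_named} named genes "
            "(mito + markers + cell-cycle); increase n_genes"
        )
    filler = [f"g{i:05d}" for i in range(n_filler)]
    symbols = mito + [g for m in marker_sets for g in m] + cc + filler
    genes = pd.DataFrame(
        {"symbol": symbols, "is_mito": [s.startswith("mt-") for s in symbols]}
    )
    return genes, cluster_types, compartments, marker_sets, (s_genes, g2m_genes), filler


def simulate_counts(config: SimConfig) -> tuple[CountBundle, SimTruth]:
    """Simulate clean (no soup, no doublets, no empty droplets) counts.

    Returns the bundle and the planted truth.  Deterministic: identical
    config (including seed) yields a bit-identical bundle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    (
        genes,
        cluster_types,
        compartments,
        marker_sets,
        (s_genes, g2m_genes),
        filler,
    ) = _build_gene_table(config, rng)

    n_genes = len(genes)
    is_mito = genes["is_mito"].to_numpy()
    mito_idx = np.flatnonzero(is_mito)
    nonmito_idx = np.flatnonzero(~is_mito)
    sym = genes["symbol"].to_numpy()
    sym_to_col = {s: j for j, s in enumerate(sym)}

    # baseline per-gene means (non-mito genes live on this scale; mito genes
    # are driven by the per-cell mito-fraction mechanism below)
    base_mean = config.baseline_mean * np.exp(
        rng.normal(0.0, config.gene_mean_sigma, size=n_genes)
    )

    n_clusters_total = len(cluster_types)
    cc_cols = np.array(
        [sym_to_col[g] for g in s_genes + g2m_genes if g in sym_to_col], dtype=int
    )

    # planted condition effects -------------------------------------------
    truth = SimTruth(rho_true=0.0)
    n_de = int(round(config.de_fraction * config.n_genes))
    n_surg_only = int(round(config.surgery_only_fraction * config.n_genes))
    filler_cols = np.array([sym_to_col[g] for g in filler], dtype=int)

    per_cluster_effects = []  # (diet_cols, diet_signs, rescued_mask, surg_cols, surg_signs)
    for k in range(n_clusters_total):
        if cluster_types[k] == "immune" or len(filler_cols) == 0:
            diet_cols = np.array([], dtype=int)
            diet_signs = np.array([], dtype=int)
            rescued_mask = np.array([], dtype=bool)
            surg_cols = np.array([], dtype=int)
            surg_signs = np.array([], dtype=int)
        else:
            n_de_k = min(n_de, len(filler_cols))
            n_so_k = min(n_surg_only, len(filler_cols) - n_de_k)
            chosen = rng.choice(
                filler_cols, size=n_de_k + n_so_k, replace=False
            )
            diet_cols = chosen[:n_de_k]
            surg_cols = chosen[n_de_k:]
            diet_signs = rng.choice([-1, 1], size=n_de_k)
            surg_signs = rng.choice([-1, 1], size=n_so_k)
            n_resc = int(round(config.rescue_fraction * n_de_k))
            rescued_mask = np.zeros(n_de_k, dtype=bool)
            if n_resc:
                rescued_mask[
                    rng.choice(n_de_k, size=n_resc, replace=False)
                ] = True
        per_cluster_effects.append(
            (diet_cols, diet_signs, rescued_mask, surg_cols, surg_signs)
        )

    # mitochondrial planted rescue: chosen mt genes drop in both HFD arms and
    # revert under VSG (profile-level effect, shared across epithelial clusters)
    n_mt_resc = min(config.n_mito_rescued, len(mito_idx))
    mt_resc_cols = (
        rng.choice(mito_idx, size=n_mt_resc, replace=False)
        if n_mt_resc
        else np.array([], dtype=int)
    )
    mito_w_base = np.exp(rng.normal(0.0, 0.7, size=len(mito_idx)))

    def mito_weights(condition: str) -> np.ndarray:
        w = mito_w_base.copy()
        if n_mt_resc and condition == "HFD_sham":
            pos = np.searchsorted(mito_idx, mt_resc_cols)
            w[pos] *= 2.0 ** (-config.de_log2fc)
        # HFD_VSG reverts to control weights (full mito rescue)
        return w / w.sum()

    # record truth
    for k in range(n_clusters_total):
        diet_cols, diet_signs, rescued_mask, surg_cols, surg_signs = (
            per_cluster_effects[k]
        )
        if cluster_types[k] == "immune":
            continue
        dmap: dict[str, str] = {}
        smap: dict[str, str] = {}
        resc: set[str] = set()
        for j, s, r in zip(diet_cols, diet_signs, rescued_mask):
            g = sym[j]
            dmap[g] = "up" if s > 0 else "down"
            if r:
                smap[g] = "down" if s > 0 else "up"
                resc.add(g)
        for j, s in zip(surg_cols, surg_signs):
            smap[sym[j]] = "up" if s > 0 else "down"
        for j in mt_resc_cols:
            g = sym[j]
            dmap[g] = "down"
            smap[g] = "up"
            resc.add(g)
        truth.diet_degs[k] = dmap
        truth.surgery_degs[k] = smap
        truth.rescued[k] = frozenset(resc)
        truth.cell_types[k] = cluster_types[k]
    truth.immune_clusters = frozenset(
        k for k, ct in enumerate(cluster_types) if ct == "immune"
    )
    for k in truth.immune_clusters:
        truth.cell_types[k] = "immune"
        truth.diet_degs[k] = {}
        truth.surgery_degs[k] = {}
        truth.rescued[k] = frozenset()

    # per-cluster x condition mean matrices, then sampling ------------------
    size = 1.0 / config.nb_dispersion  # NB size parameter (var = mu + a*mu^2)
    beta_a = config.mito_fraction_mean * config.mito_fraction_conc
    beta_b = (1.0 - config.mito_fraction_mean) * config.mito_fraction_conc

    blocks = []
    cell_rows = []
    n_cells_pc = config.cells_per_cluster_per_condition
    cell_counter = 0
    for k in range(n_clusters_total):
        ct = cluster_types[k]
        comp = compartments[k]
        mu_k = base_mean.copy()
        # marker structure: near-exclusive high expression in the home cluster
        for kk, mset in enumerate(marker_sets):
            cols = np.array([sym_to_col[g] for g in mset], dtype=int)
            if kk == k:
                mu_k[cols] = base_mean[cols] * 2.0**config.marker_log2fc
            else:
                mu_k[cols] = base_mean[cols] * config.marker_off_factor
        if ct == "stem" and len(cc_cols):
            mu_k[cc_cols] = mu_k[cc_cols] * config.cc_boost

        diet_cols, diet_signs, rescued_mask, _surg_cols, _surg_signs = (
            per_cluster_effects[k]
        )
        for cond in CONDITIONS:
            mu = mu_k.copy()
            if len(diet_cols):
                fc = 2.0 ** (config.de_log2fc * diet_signs)
                if cond == "HFD_sham":
                    mu[diet_cols] *= fc
                elif cond == "HFD_VSG":
                    # rescued genes revert toward control; the rest keep the
                    # diet-induced shift
                    revert = np.where(
                        rescued_mask, fc ** (1.0 - config.rescue_completeness), fc
                    )
                    mu[diet_cols] *= revert
            if cond == "HFD_VSG" and len(_surg_cols):
                mu[_surg_cols] *= 2.0 ** (config.de_log2fc * _surg_signs)

            lib = np.exp(
                rng.normal(
                    -0.5 * config.library_sigma**2,
                    config.library_sigma,
                    size=n_cells_pc,
                )
            )
            mu_cells = lib[:, None] * mu[None, nonmito_idx]
            p = size / (size + mu_cells)
            nonmito_counts = rng.negative_binomial(size, p)

            counts = np.zeros((n_cells_pc, n_genes), dtype=np.int64)
            counts[:, nonmito_idx] = nonmito_counts
            if len(mito_idx):
                f = rng.beta(beta_a, beta_b, size=n_cells_pc)
                t_nm = nonmito_counts.sum(axis=1)
                m_tot = np.round(f / (1.0 - f) * t_nm).astype(np.int64)
                w = mito_weights(cond)
                counts[:, mito_idx] = rng.multinomial(m_tot, w)

            sample = f"{cond}_{comp}"
            for i in range(n_cells_pc):
                bc = f"BC{cell_counter:06d}"
                cell_counter += 1
                cell_rows.append((bc, sample, cond, comp))
                truth.cluster_labels[bc] = k
            blocks.append(sp.csr_matrix(counts))

    cells = pd.DataFrame(
        cell_rows, columns=["barcode", "sample", "condition", "compartment"]
    )
    bundle = CountBundle(
        counts=sp.vstack(blocks, format="csr"), cells=cells, genes=genes
    )
    truth.validate()
    return bundle, truth


def ambient_profile(bundle: CountBundle) -> np.ndarray:
    """Library-size-weighted mean expression: the 'soup' a lysed-cell pool
    would contribute.  Per-gene fractions summing to 1."""
    totals = np.asarray(bundle.counts.sum(axis=0)).ravel().astype(float)
    s = totals.sum()
    if s == 0:
        raise ValueError("bundle has no counts")
    return totals / s


def inject_ambient(
    bundle: CountBundle,
    rho: float,
    seed: int,
    n_empty: int = 0,
    empty_total_range: tuple[int, int] = (20, 90),
) -> CountBundle:
    """Replace a Binomial(total_i, rho) portion of each cell's counts with
    draws from the dataset-wide ambient profile; append ambient-only empty
    droplets.  Per-cell totals are preserved exactly."""
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho={rho} outside [0, 1)")
    rng = np.random.default_rng(seed)
    profile = ambient_profile(bundle)
    counts = bundle.counts.toarray()

    if rho > 0:
        totals = counts.sum(axis=1)
        n_swap = rng.binomial(totals, rho)
        for i in range(counts.shape[0]):
            if n_swap[i] == 0:
                continue
            removed = rng.multivariate_hypergeometric(
                counts[i], n_swap[i], method="marginals"
            )
            counts[i] -= removed
            counts[i] += rng.multinomial(n_swap[i], profile)

    cells = bundle.cells.copy()
    if n_empty > 0:
        samples = cells["sample"].unique()
        meta = cells.drop_duplicates("sample").set_index("sample")
        lo, hi = empty_total_range
        tot = rng.integers(lo, hi + 1, size=n_empty)
        empty_counts = rng.multinomial(tot, profile)
        rows = []
        for i in range(n_empty):
            s = samples[i % len(samples)]
            rows.append(
                (
                    f"EMPTY{i:05d}",
                    s,
                    meta.loc[s, "condition"],
                    meta.loc[s, "compartment"],
                )
            )
        empties = pd.DataFrame(
            rows, columns=["barcode", "sample", "condition", "compartment"]
        )
        cells = pd.concat([cells, empties], ignore_index=True)
        counts = np.vstack([counts, empty_counts])

    return CountBundle(
        counts=sp.csr_matrix(counts.astype(np.int64)),
        cells=cells,
        genes=bundle.genes.copy(),
    )


def inject_doublets(
    bundle: CountBundle,
    rate: float,
    seed: int,
    truth: SimTruth | None = None,
    min_total: int = 0,
) -> tuple[CountBundle, SimTruth]:
    """Append synthetic doublets, each the gene-wise sum of two distinct
    randomly chosen same-sample cells.  ``min_total`` excludes near-empty
    barcodes from pairing (doublets arise from real cells, not ambient
    droplets); the number appended is ``round(rate * n_eligible)``.  Original
    rows are left untouched; doublet identities are recorded in the returned
    truth."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"doublet rate={rate} outside [0, 1)")
    truth = truth if truth is not None else SimTruth()
    rng = np.random.default_rng(seed)
    eligible_mask = bundle.total_counts() > min_total
    n = int(eligible_mask.sum())
    n_doub = int(round(rate * n))
    if n_doub == 0:
        truth.doublet_barcodes = frozenset(truth.doublet_barcodes)
        return bundle, truth

    samples = np.where(eligible_mask, bundle.cells["sample"].to_numpy(), None)
    meta = bundle.cells.drop_duplicates("sample").set_index("sample")
    by_sample = {
        s: np.flatnonzero(samples == s) for s in np.unique(samples[eligible_mask])
    }
    eligible = [s for s, idx in by_sample.items() if len(idx) >= 2]
    rows = []
    new_counts = []
    names = []
    for i in range(n_doub):
        s = eligible[int(rng.integers(len(eligible)))]
        a, b = rng.choice(by_sample[s], size=2, replace=False)
        new_counts.append(bundle.counts[a] + bundle.counts[b])
        bc = f"DBL{i:05d}"
        names.append(bc)
        rows.append((bc, s, meta.loc[s, "condition"], meta.loc[s, "compartment"]))

    out = CountBundle(
        counts=sp.vstack([bundle.counts] + new_counts, format="csr"),
        cells=pd.concat(
            [
                bundle.cells,
                pd.DataFrame(
                    rows, columns=["barcode", "sample", "condition", "compartment"]
                ),
            ],
            ignore_index=True,
        ),
        genes=bundle.genes.copy(),
    )
    truth.doublet_barcodes = frozenset(set(truth.doublet_barcodes) | set(names))
    return out, truth


def simulate_bundle(config: SimConfig) -> tuple[CountBundle, SimTruth]:
    """Full generative pipeline: clean counts -> ambient soup + empty
    droplets -> doublets.  This is the study-condition generator used by the
    pipeline's synthetic mode."""
    bundle, truth = simulate_counts(config)
    bundle = inject_ambient(
        bundle,
        rho=config.rho,
        seed=np.random.SeedSequence([config.seed, 1]).generate_state(1)[0] % 2**31,
        n_empty=config.n_empty_droplets,
    )
    truth.rho_true = config.rho
    bundle, truth = inject_doublets(
        bundle,
        rate=config.doublet_rate,
        seed=np.random.SeedSequence([config.seed, 2]).generate_state(1)[0] % 2**31,
        truth=truth,
        min_total=100 if config.n_empty_droplets > 0 else 0,
    )
    return bundle, truth


def synthetic_gene_sets(
    symbols,
    n_terms: int = 20,
    term_size: int = 25,
    seed: int = 0,
    planted: dict[str, set[str]] | None = None,
) -> dict[str, set[str]]:
    """Random gene-set library over a gene space, optionally with planted
    terms, for exercising the enrichment stage without external downloads."""
    rng = np.random.default_rng(seed)
    symbols = list(symbols)
    lib: dict[str, set[str]] = {}
    for i in range(n_terms):
        size = min(term_size, len(symbols))
        lib[f"RANDOM_SET_{i:02d}"] = set(
            rng.choice(symbols, size=size, replace=False)
        )
    if planted:
        for name, genes in planted.items():
            lib[name] = set(genes)
    return lib
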