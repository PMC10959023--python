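"""End-to-end pipeline: simulate/ingest -> QC -> cluster+annotate -> hurdle
DE -> rescue -> enrichment, with a declarative config, per-stage outputs,
provenance capture and a markdown report.

Stage outputs are plain TSV/JSON so runs can be diffed; a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from . import cluster as cl
from . import de as de_mod
from . import enrich as en
from . import qc as qc_mod
from . import rescue as rs
from .core import COMPARTMENTS, CountBundle, MarkerReference, builtin_cell_cycle_genes, read_bundle
from .simulate import SimConfig, simulate_bundle, synthetic_gene_sets

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "cluster", "de", "rescue", "enrich")


class QCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_genes: int = Field(qc_mod.DEFAULT_MIN_GENES, gt=0)
    max_mito: float = Field(qc_mod.DEFAULT_MAX_MITO, gt=0, le=1.0)
    empty_total_max: int = Field(qc_mod.DEFAULT_EMPTY_TOTAL_MAX, gt=0)
    doublet_k: int = Field(20, gt=0)
    expected_doublet_rate: float = Field(0.05, ge=0, lt=1)


class ClusteringConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_hvg: int = Field(cl.DEFAULT_N_HVG, gt=0)
    n_pcs: int = Field(cl.DEFAULT_N_PCS, gt=0)
    resolution: float = Field(cl.DEFAULT_RESOLUTION, gt=0)
    knn: int = Field(cl.DEFAULT_KNN, gt=1)
    marker_min_lfc: float = Field(cl.DEFAULT_MIN_MARKER_LFC, ge=0)
    marker_top_n: int = Field(cl.DEFAULT_TOP_N_MARKERS, gt=0)
    overlap_floor: float = Field(cl.DEFAULT_OVERLAP_FLOOR, ge=0, le=1)
    integrate_samples: bool = True
    regress_covariates: bool = True


class DEConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p: float = Field(de_mod.DEFAULT_P, gt=0, le=1)
    padj: float = Field(de_mod.DEFAULT_PADJ, gt=0, le=1)
    min_abs_log2fc: float = Field(de_mod.DEFAULT_MIN_ABS_LOG2FC, ge=0)
    min_frac: float = Field(de_mod.DEFAULT_MIN_FRAC, ge=0, le=1)
    contrasts: list[str] = ["diet", "surgery", "residual"]

    @field_validator("contrasts")
    @classmethod
    def _known(cls, v):
        unknown = set(v) - set(de_mod.CONTRASTS)
        if unknown:
            raise ValueError(f"unknown contrasts {sorted(unknown)}")
        return v


class EnrichConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gmt_paths: list[str] = []
    n_synthetic_terms: int = Field(20, ge=0)
    padj_heatmap_threshold: float = Field(1.0, gt=0, le=1)


class PipelineConfig(BaseModel):
    """Declarative pipeline configuration.

    Defaults are the analysis' standard gates: QC at 750 genes / 20 % mito,
    2000 HVGs, 30 PCs, Leiden resolution 0.4, DEG filter p < 0.05,
    padj < 0.20, |log2FC| > 0.50, min detection fraction 0.10.
    """

    model_config = ConfigDict(extra="forbid")
    synthetic: SimConfigModel | None = None
    bundle_paths: list[str] = []
    marker_reference: str | None = None
    qc: QCConfig = QCConfig()
    clustering: ClusteringConfig = ClusteringConfig()
    de: DEConfig = DEConfig()
    enrich: EnrichConfig = EnrichConfig()
    seed: int = 0
    save_counts: bool = False

    def sim_config(self) -> SimConfig:
        model = self.synthetic or SimConfigModel()
        cfg = SimConfig(**model.model_dump())
        cfg.seed = cfg.seed if model.seed_set else self.seed
        return cfg


class SimConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_clusters: int = Field(SimConfig.n_clusters, gt=0)
    cells_per_cluster_per_condition: int = Field(
        SimConfig.cells_per_cluster_per_condition, gt=0
    )
    n_genes: int = Field(SimConfig.n_genes, gt=0)
    n_mito_genes: int = Field(SimConfig.n_mito_genes, ge=0)
    baseline_mean: float = Field(SimConfig.baseline_mean, gt=0)
    nb_dispersion: float = Field(SimConfig.nb_dispersion, gt=0)
    de_fraction: float = Field(SimConfig.de_fraction, ge=0, le=1)
    de_log2fc: float = Field(SimConfig.de_log2fc, ge=0)
    rescue_fraction: float = Field(SimConfig.rescue_fraction, ge=0, le=1)
    surgery_only_fraction: float = Field(SimConfig.surgery_only_fraction, ge=0, le=1)
    rho: float = Field(SimConfig.rho, ge=0, lt=1)
    doublet_rate: float = Field(SimConfig.doublet_rate, ge=0, lt=1)
    n_empty_droplets: int = Field(SimConfig.n_empty_droplets, ge=0)
    seed: int | None = None
    n_immune_clusters: int = Field(SimConfig.n_immune_clusters, ge=0)
    n_mito_rescued: int = Field(SimConfig.n_mito_rescued, ge=0)

    @property
    def seed_set(self) -> bool:
        return self.seed is not None

    def model_dump(self, **kw):  # noqa: D102 - drop the sentinel
        d = super().model_dump(**kw)
        if d.get("seed") is None:
            d["seed"] = 0
        return d


PipelineConfig.model_rebuild()


def validate_config(path) -> PipelineConfig:
    """Parse, default and schema-validate a YAML config file.  Unknown keys
    and out-of-range values are rejected with the offending key named."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw or {})


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(
    config: PipelineConfig, outdir, seed: int | None = None, upto: str = "enrich"
) -> dict:
    """Execute the pipeline through stage ``upto`` and write all artifacts.

    Returns a dict of in-memory results keyed by stage.  Raises
    :class:`PipelineError` naming the failing stage; earlier outputs are
    retained on disk.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; stages are {STAGES}")
    last = STAGES.index(upto)
    state: dict = {"config": config}
    timings: dict[str, float] = {}
    provenance = {
        "gutrescue_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": config.model_dump(),
        "notes": [
            "normalization: log2(1 + 1e4 * c / total) scale-factor transform "
            "(regularized-NB normalization intentionally not used)",
            "sample integration: per-sample centering of the scaled HVG "
            "matrix plus per-cell covariate regression (detected genes, "
            "mito fraction)",
            "enrichment: plain hypergeometric + BH on the tested-gene "
            "universe of each cluster",
        ],
    }

    for i in range(last + 1):
        stage = STAGES[i]
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](state, out)
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001 - re-raise naming the stage
            raise PipelineError(f"stage {stage!r} failed: {e}") from e
        timings[stage] = round(time.time() - t0, 2)
        logger.info("stage %s done in %.1fs", stage, timings[stage])

    provenance["stage_seconds"] = timings
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1)
    if last >= STAGES.index("rescue"):
        _write_report(state, out)
    return state


# --------------------------------------------------------------------- stages


def _stage_simulate(state: dict, out: Path) -> None:
    config: PipelineConfig = state["config"]
    if config.bundle_paths:
        bundles = [read_bundle(p) for p in config.bundle_paths]
        if len(bundles) == 1:
            bundle = bundles[0]
        else:
            import scipy.sparse as sp

            genes = bundles[0].genes
            for b in bundles[1:]:
                if not b.genes["symbol"].equals(genes["symbol"]):
                    raise ValueError("bundles have mismatched gene spaces")
            bundle = CountBundle(
                counts=sp.vstack([b.counts for b in bundles], format="csr"),
                cells=pd.concat([b.cells for b in bundles], ignore_index=True),
                genes=genes.copy(),
            )
        truth = None
    else:
        bundle, truth = simulate_bundle(config.sim_config())
        truth.to_json(out / "sim_truth.json")
    state["bundle"] = bundle
    state["truth"] = truth
    if config.save_counts:
        from .core import write_bundle as _wb

        _wb(bundle, out / "bundle", overwrite=True)


def _stage_qc(state: dict, out: Path) -> None:
    config: PipelineConfig = state["config"]
    bundle: CountBundle = state["bundle"]
    qcc = config.qc

    # per-sample soup estimation (joint cluster structure) and correction
    samples = bundle.cells["sample"].to_numpy()
    estimates = qc_mod.estimate_ambient_per_sample(
        bundle, empty_total_max=qcc.empty_total_max, seed=config.seed
    )
    corrected = []
    order = []
    rho_rows = []
    for s in pd.unique(samples):
        sub = bundle.subset_cells(samples == s)
        corrected.append(qc_mod.correct_ambient(sub, estimates[s]))
        order.append(np.flatnonzero(samples == s))
        rho_rows.append({"sample": s, "rho_hat": estimates[s].rho_hat})
    import scipy.sparse as sp

    perm = np.concatenate(order)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    stacked = CountBundle(
        counts=sp.vstack([c.counts for c in corrected], format="csr")[inv],
        cells=pd.concat([c.cells for c in corrected], ignore_index=True).iloc[inv].reset_index(drop=True),
        genes=bundle.genes.copy(),
    )
    _tsv(pd.DataFrame(rho_rows), out / "ambient_rho.tsv")

    # drop empty droplets, score doublets, apply cell filters
    nonempty = stacked.subset_cells(stacked.total_counts() > qcc.empty_total_max)
    dbl = qc_mod.score_doublets(
        nonempty,
        k=qcc.doublet_k,
        seed=config.seed,
        expected_rate=qcc.expected_doublet_rate,
    )
    qctab = qc_mod.compute_cell_qc(
        nonempty, dbl, min_genes=qcc.min_genes, max_mito=qcc.max_mito
    )
    _tsv(qctab, out / "cell_qc.tsv")
    filtered = qc_mod.filter_cells(nonempty, qctab)
    if filtered.n_cells == 0:
        raise PipelineError("stage 'qc' failed: no cells after QC filters")
    state["bundle_qc"] = filtered
    state["qc_table"] = qctab
    state["rho_table"] = pd.DataFrame(rho_rows)


def _stage_cluster(state: dict, out: Path) -> None:
    config: PipelineConfig = state["config"]
    bundle: CountBundle = state["bundle_qc"]
    cc = config.clustering
    norm = cl.normalize_log(bundle)
    hvgs = cl.select_hvg(
        norm,
        min(cc.n_hvg, bundle.n_genes),
        exclude=bundle.genes["is_mito"].to_numpy(),
    )
    cov = (
        np.column_stack([bundle.genes_detected(), bundle.mito_fraction()])
        if cc.regress_covariates
        else None
    )
    labels = cl.cluster_graph(
        norm,
        hvgs,
        n_pcs=min(cc.n_pcs, len(hvgs) - 1, bundle.n_cells - 1),
        resolution=cc.resolution,
        seed=config.seed,
        knn=cc.knn,
        sample_labels=bundle.cells["sample"].to_numpy() if cc.integrate_samples else None,
        covariates=cov,
    )
    markers = cl.find_cluster_markers(
        bundle, norm, labels, min_lfc=cc.marker_min_lfc, top_n=cc.marker_top_n
    )
    ref = (
        MarkerReference.from_tsv(config.marker_reference)
        if config.marker_reference
        else MarkerReference.builtin()
    )
    assignment = cl.assign_cell_types(
        markers, ref, bundle=bundle, norm=norm, clusters=labels, floor=cc.overlap_floor
    )
    epi, epi_labels = cl.drop_immune(bundle, assignment, labels)
    epi_norm = cl.normalize_log(epi)
    cell_types = np.array(
        [assignment.cell_type[c] for c in epi_labels], dtype=object
    )

    s_genes, g2m_genes = builtin_cell_cycle_genes()
    cc_scores = cl.score_cell_cycle(
        epi_norm, epi.genes["symbol"], s_genes, g2m_genes, seed=config.seed
    )
    cc_scores.insert(0, "barcode", epi.cells["barcode"].to_numpy())

    _tsv(
        pd.DataFrame(
            {
                "barcode": bundle.cells["barcode"],
                "cluster": labels,
                "cell_type": [assignment.cell_type[c] for c in labels],
                "compartment": bundle.cells["compartment"],
                "is_immune": [assignment.is_immune[c] for c in labels],
            }
        ),
        out / "clusters.tsv",
    )
    _tsv(assignment.table(), out / "cluster_annotation.tsv")
    _tsv(
        pd.DataFrame(
            [(c, i, g) for c, gl in markers.items() for i, g in enumerate(gl)],
            columns=["cluster", "rank", "gene"],
        ),
        out / "cluster_markers.tsv",
    )
    _tsv(cc_scores, out / "cell_cycle.tsv")

    state.update(
        bundle_epi=epi,
        norm=epi_norm,
        leiden=epi_labels,
        cell_types=cell_types,
        assignment=assignment,
        markers=markers,
    )


def _stage_de(state: dict, out: Path) -> None:
    config: PipelineConfig = state["config"]
    dec = config.de
    bundle = state["bundle_epi"]
    norm = state["norm"]
    groups = state["cell_types"]

    tables = []
    for cname in dec.contrasts:
        tables.append(
            de_mod.test_contrast(
                bundle,
                norm,
                groups,
                de_mod.Contrast.standard(cname),
                min_frac=dec.min_frac,
                covariate_mode="ngenes_only",
                p_thresh=dec.p,
                padj_thresh=dec.padj,
                min_abs_log2fc=dec.min_abs_log2fc,
            )
        )
    de = pd.concat(tables, ignore_index=True)

    # robustness rerun with the mito-fraction covariate for the crypt
    # stem/paneth mitochondrial panel
    crypt_types = [
        t for t in ("stem", "paneth") if t in set(groups)
    ]
    mito_tables = []
    if crypt_types and bundle.genes["is_mito"].any():
        for cname in dec.contrasts:
            mito_tables.append(
                de_mod.test_contrast(
                    bundle,
                    norm,
                    groups,
                    de_mod.Contrast.standard(cname),
                    min_frac=dec.min_frac,
                    covariate_mode="ngenes_plus_mito",
                    p_thresh=dec.p,
                    padj_thresh=dec.padj,
                    min_abs_log2fc=dec.min_abs_log2fc,
                    only_clusters=crypt_types,
                )
            )
    de_all_modes = pd.concat([de] + mito_tables, ignore_index=True)

    mito_syms = bundle.genes.loc[bundle.genes["is_mito"], "symbol"].tolist()
    if mito_syms:
        panel = de_mod.mito_gene_panel(
            de_all_modes[de_all_modes["cluster"].isin(crypt_types)]
            if crypt_types
            else de_all_modes.iloc[0:0],
            mito_genes=mito_syms,
            gene_space=bundle.genes["symbol"],
        )
        _tsv(panel, out / "mito_panel.tsv")

    _tsv(de_all_modes, out / "de_table.tsv")

    comp_of = {
        c: state["assignment"].compartment.get(c, "unknown")
        for c in state["assignment"].cell_type
    }
    type_comp = _celltype_compartments(state)
    summaries = []
    for comp in COMPARTMENTS:
        scope = [t for t, cp in type_comp.items() if cp == comp]
        s = de_mod.summarize_directional_counts(de, scope=scope)
        s.insert(0, "compartment", comp)
        s["unique_genes"] = False
        su = de_mod.summarize_directional_counts(de, scope=scope, unique_genes=True)
        su.insert(0, "compartment", comp)
        su["unique_genes"] = True
        summaries.extend([s, su])
    _tsv(pd.concat(summaries, ignore_index=True), out / "deg_counts.tsv")

    state["de"] = de
    state["de_all_modes"] = de_all_modes


def _celltype_compartments(state: dict) -> dict[str, str]:
    """Majority compartment per annotated cell type."""
    comp = state["bundle_epi"].cells["compartment"].to_numpy()
    out = {}
    for t in pd.unique(state["cell_types"]):
        vals, counts = np.unique(comp[state["cell_types"] == t], return_counts=True)
        out[t] = str(vals[counts.argmax()])
    return out


def _stage_rescue(state: dict, out: Path) -> None:
    de = state["de"]
    summary, calls = rs.summarize_rescue(de)

    have_residual = "residual" in set(de["contrast"])
    restored = []
    for _, row in calls.iterrows():
        if row["category"] == "rescued" and have_residual:
            restored.append(
                rs.baseline_restoration(de, row["gene"], row["cluster"])
            )
        else:
            restored.append(False)
    calls["restored_to_baseline"] = restored

    type_comp = _celltype_compartments(state)
    pooled = []
    for comp in COMPARTMENTS:
        if comp in set(type_comp.values()):
            pooled.append(
                rs.aggregate_compartment(summary, type_comp, comp).as_dict()
            )
    full = pd.concat(
        [summary, pd.DataFrame(pooled)], ignore_index=True
    ) if pooled else summary
    _tsv(full.round(6), out / "rescue_summary.tsv")
    _tsv(calls, out / "gene_rescue_calls.tsv")

    heat_cols = [
        "rescue_pct", "specificity_pct", "rescue_pct_downup",
        "specificity_pct_downup", "rescue_pct_updown", "specificity_pct_updown",
    ]
    _tsv(
        summary.set_index("cluster")[heat_cols].round(4),
        out / "rescue_heatmap.tsv",
        index=True,
    )

    pair = [t for t in ("stem", "paneth") if t in set(summary["cluster"])]
    if len(pair) == 2:
        parts = rs.cross_celltype_categories(calls, (pair[0], pair[1]))
        _tsv(
            pd.DataFrame(
                [(k, g) for k, gs in parts.items() for g in sorted(gs)],
                columns=["category", "gene"],
            ),
            out / "stem_paneth_rescue_overlap.tsv",
        )
        shared = sorted(parts["both"])[:10]
        if shared:
            _tsv(
                rs.expression_long_format(
                    state["norm"],
                    state["bundle_epi"].genes["symbol"],
                    state["bundle_epi"].cells["condition"].to_numpy(),
                    state["cell_types"],
                    shared,
                    cluster_scope=pair,
                ),
                out / "rescued_gene_expression.tsv",
            )

    state["rescue_summary"] = full
    state["rescue_calls"] = calls


def _stage_enrich(state: dict, out: Path) -> None:
    config: PipelineConfig = state["config"]
    de = state["de"]
    calls = state["rescue_calls"]
    bundle = state["bundle_epi"]

    libraries = [
        en.read_gmt(p) for p in config.enrich.gmt_paths
    ]
    if not libraries and config.enrich.n_synthetic_terms > 0:
        planted = {}
        truth = state.get("truth")
        rescued_union = set(
            calls.loc[calls["category"] == "rescued", "gene"]
        )
        if truth is not None and truth.rescued:
            planted["PLANTED_RESCUED_GENES"] = set().union(*truth.rescued.values())
        elif rescued_union:
            planted["OBSERVED_RESCUED_GENES"] = rescued_union
        libraries = [
            en.GeneSetLibrary(
                name="synthetic_pathways",
                terms=synthetic_gene_sets(
                    bundle.genes["symbol"],
                    n_terms=config.enrich.n_synthetic_terms,
                    seed=config.seed,
                    planted=planted,
                ),
            )
        ]

    rows = []
    matrices = {}
    for lib in libraries:
        per_query: dict[str, dict] = {"surgery_up": {}, "surgery_down": {}, "rescued": {}}
        for ctype in pd.unique(state["cell_types"]):
            surg = de[(de["cluster"] == ctype) & (de["contrast"] == "surgery")]
            universe = set(surg["gene"])
            if not universe:
                continue
            queries = {
                "surgery_up": set(
                    surg.loc[surg["passes_filter"] & (surg["direction"] == "up"), "gene"]
                ),
                "surgery_down": set(
                    surg.loc[surg["passes_filter"] & (surg["direction"] == "down"), "gene"]
                ),
                "rescued": set(
                    calls.loc[
                        (calls["cluster"] == ctype) & (calls["category"] == "rescued"),
                        "gene",
                    ]
                ),
            }
            for qname, query in queries.items():
                if not query:
                    continue
                res = en.hypergeom_enrich(query, lib, universe)
                res.insert(0, "query", qname)
                res.insert(0, "cluster", ctype)
                res.insert(0, "library", lib.name)
                rows.append(res)
                per_query[qname][ctype] = res
        for qname, results in per_query.items():
            if results:
                mat = en.enrichment_matrix(
                    results, threshold=config.enrich.padj_heatmap_threshold
                )
                matrices[(lib.name, qname)] = mat
                safe = Path(lib.name).stem.replace("/", "_")
                _tsv(mat, out / f"enrichment_matrix_{safe}_{qname}.tsv", index=True)

    result = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["library", "cluster", "query", "term", "k", "K", "n", "N", "p", "padj"]
        )
    )
    _tsv(result, out / "enrichment.tsv")
    state["enrichment"] = result
    state["enrichment_matrices"] = matrices


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "de": _stage_de,
    "rescue": _stage_rescue,
    "enrich": _stage_enrich,
}


def cell_bookkeeping(bundle: CountBundle) -> pd.DataFrame:
    """Cells per condition x compartment group plus the grand total row —
    the report's accounting table (the group counts must sum to the total).
    """
    counts = (
        bundle.cells.groupby(["condition", "compartment"], observed=True)
        .size()
        .reset_index(name="n_cells")
        .sort_values(["condition", "compartment"], kind="stable")
        .reset_index(drop=True)
    )
    total = pd.DataFrame(
        [{"condition": "total", "compartment": "all", "n_cells": counts["n_cells"].sum()}]
    )
    return pd.concat([counts, total], ignore_index=True)


def _write_report(state: dict, out: Path) -> None:
    epi = state["bundle_epi"]
    book = cell_bookkeeping(epi)
    _tsv(book, out / "cell_bookkeeping.tsv")
    lines = ["# Pipeline report", ""]
    lines += ["## Cell bookkeeping (post-QC epithelial cells)", ""]
    lines += [book.to_markdown(index=False), ""]
    if "rescue_summary" in state:
        lines += ["## Rescue / specificity by cluster", ""]
        cols = [
            "cluster", "n_diet_degs", "n_surgery_degs", "n_reversed",
            "rescue_pct", "specificity_pct",
        ]
        lines += [state["rescue_summary"][cols].round(1).to_markdown(index=False), ""]
    (out / "report.md").write_text("\n".join(lines))
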