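"""Reversal ("rescue") statistics: the core intervention-reversal analysis.

For each cluster two filtered DEG lists are compared — genes altered by diet
(HFD_sham vs LFD_sham) and genes altered by surgery (HFD_VSG vs HFD_sham).
A gene present in both lists with opposite directions is *rescued*:

* ``Rescue %``      = 100 * |reversed| / |diet DEGs| — how much of the diet
  perturbation surgery reverses;
* ``Specificity %`` = 100 * |reversed| / |surgery DEGs| — how much of the
  surgery response corresponds to reversing diet effects rather than
  diet-independent action.

Both are decomposed by directionality (diet-down→surgery-up and
diet-up→surgery-down strata) and pooled across the crypt / villus
compartments by summing counts with per-cluster multiplicity.  A rescued
gene is additionally *restored to baseline* when the residual contrast
(HFD_VSG vs LFD_sham) shows no remaining difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

_OPP = {"up": "down", "down": "up"}


def degs_from_table(de: pd.DataFrame, cluster, contrast: str) -> dict[str, str]:
    """Directional map gene -> direction of filtered DEGs for one
    (cluster, contrast)."""
    sub = de[
        (de["cluster"] == cluster)
        & (de["contrast"] == contrast)
        & de["passes_filter"]
    ]
    return dict(zip(sub["gene"], sub["direction"]))


def reversed_intersection(
    diet_degs: dict[str, str], surgery_degs: dict[str, str]
) -> tuple[set[str], pd.DataFrame]:
    """Genes present in both maps with opposite directions, plus per-gene
    category calls.

    Categories: ``rescued`` (both lists, opposite directions), ``concordant``
    (both lists, same direction — never counted as rescue), ``diet_only``,
    ``surgery_only``.
    """
    for name, m in (("diet", diet_degs), ("surgery", surgery_degs)):
        bad = {d for d in m.values() if d not in _OPP}
        if bad:
            raise ValueError(f"{name} map has invalid directions {bad}")
    calls = []
    for g in sorted(set(diet_degs) | set(surgery_degs)):
        in_d, in_s = g in diet_degs, g in surgery_degs
        if in_d and in_s:
            cat = "rescued" if diet_degs[g] != surgery_degs[g] else "concordant"
        elif in_d:
            cat = "diet_only"
        else:
            cat = "surgery_only"
        calls.append(
            {
                "gene": g,
                "diet_direction": diet_degs.get(g),
                "surgery_direction": surgery_degs.get(g),
                "category": cat,
            }
        )
    table = pd.DataFrame(
        calls, columns=["gene", "diet_direction", "surgery_direction", "category"]
    )
    rescued = set(table.loc[table["category"] == "rescued", "gene"])
    return rescued, table


@dataclass
class RescueSummary:
    """Per-cluster (or pooled) reversal bookkeeping.

    Percentages with a zero denominator are NaN and flagged via the
    ``*_defined`` properties rather than coerced to 0.
    """

    cluster: object
    n_diet_degs: int
    n_surgery_degs: int
    n_reversed: int
    n_reversed_downup: int
    n_reversed_updown: int
    rescue_pct: float
    specificity_pct: float
    rescue_pct_downup: float
    specificity_pct_downup: float
    rescue_pct_updown: float
    specificity_pct_updown: float

    @property
    def rescue_defined(self) -> bool:
        return not math.isnan(self.rescue_pct)

    @property
    def specificity_defined(self) -> bool:
        return not math.isnan(self.specificity_pct)

    def as_dict(self) -> dict:
        return asdict(self)


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def rescue_specificity(
    diet_degs: dict[str, str], surgery_degs: dict[str, str], cluster=None
) -> RescueSummary:
    """Full reversal summary for one cluster, including the directional
    decomposition (diet-down→surgery-up and diet-up→surgery-down strata)."""
    rescued, _ = reversed_intersection(diet_degs, surgery_degs)
    down_up = {g for g in rescued if diet_degs[g] == "down"}
    up_down = rescued - down_up
    n_diet_down = sum(1 for d in diet_degs.values() if d == "down")
    n_diet_up = len(diet_degs) - n_diet_down
    n_surg_up = sum(1 for d in surgery_degs.values() if d == "up")
    n_surg_down = len(surgery_degs) - n_surg_up
    return RescueSummary(
        cluster=cluster,
        n_diet_degs=len(diet_degs),
        n_surgery_degs=len(surgery_degs),
        n_reversed=len(rescued),
        n_reversed_downup=len(down_up),
        n_reversed_updown=len(up_down),
        rescue_pct=_pct(len(rescued), len(diet_degs)),
        specificity_pct=_pct(len(rescued), len(surgery_degs)),
        rescue_pct_downup=_pct(len(down_up), n_diet_down),
        specificity_pct_downup=_pct(len(down_up), n_surg_up),
        rescue_pct_updown=_pct(len(up_down), n_diet_up),
        specificity_pct_updown=_pct(len(up_down), n_surg_down),
    )


def summarize_rescue(
    de: pd.DataFrame,
    diet_contrast: str = "diet",
    surgery_contrast: str = "surgery",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster rescue summaries and gene-level category calls from a DE
    table.  Returns (summary table, gene calls table)."""
    clusters = sorted(de["cluster"].unique()) if len(de) else []
    summaries = []
    calls = []
    for c in clusters:
        diet = degs_from_table(de, c, diet_contrast)
        surg = degs_from_table(de, c, surgery_contrast)
        summaries.append(rescue_specificity(diet, surg, cluster=c).as_dict())
        _, tab = reversed_intersection(diet, surg)
        tab.insert(0, "cluster", c)
        calls.append(tab)
    summary = pd.DataFrame(
        summaries,
        columns=[f.name for f in RescueSummary.__dataclass_fields__.values()]
        if not summaries
        else None,
    )
    call_table = (
        pd.concat(calls, ignore_index=True)
        if calls
        else pd.DataFrame(
            columns=["cluster", "gene", "diet_direction", "surgery_direction", "category"]
        )
    )
    return summary, call_table


def aggregate_compartment(
    summary: pd.DataFrame, compartment_of: dict, compartment: str
) -> RescueSummary:
    """Pool per-cluster counts over one compartment (with per-cluster
    multiplicity) and recompute percentages from the pooled counts."""
    known = set(compartment_of.values())
    if compartment not in known:
        raise ValueError(
            f"unknown compartment {compartment!r}; have {sorted(known)}"
        )
    clusters = [c for c in summary["cluster"] if compartment_of.get(c) == compartment]
    sub = summary[summary["cluster"].isin(clusters)]
    n_diet = int(sub["n_diet_degs"].sum())
    n_surg = int(sub["n_surgery_degs"].sum())
    n_rev = int(sub["n_reversed"].sum())
    n_du = int(sub["n_reversed_downup"].sum())
    n_ud = int(sub["n_reversed_updown"].sum())
    # directional denominators are not carried in the summary rows; pooled
    # directional percentages are reported against the pooled totals
    return RescueSummary(
        cluster=compartment,
        n_diet_degs=n_diet,
        n_surgery_degs=n_surg,
        n_reversed=n_rev,
        n_reversed_downup=n_du,
        n_reversed_updown=n_ud,
        rescue_pct=_pct(n_rev, n_diet),
        specificity_pct=_pct(n_rev, n_surg),
        rescue_pct_downup=_pct(n_du, n_diet),
        specificity_pct_downup=_pct(n_du, n_surg),
        rescue_pct_updown=_pct(n_ud, n_diet),
        specificity_pct_updown=_pct(n_ud, n_surg),
    )


def baseline_restoration(de: pd.DataFrame, gene: str, cluster) -> bool:
    """True when a gene is rescued *and* shows no residual difference between
    the treated arm and control (HFD_VSG vs LFD_sham not passing the filter).
    """
    contrasts = set(de.loc[de["cluster"] == cluster, "contrast"])
    if "residual" not in contrasts:
        raise ValueError(
            f"residual contrast missing for cluster {cluster!r}; run the "
            "HFD_VSG vs LFD_sham contrast first"
        )
    diet = degs_from_table(de, cluster, "diet")
    surg = degs_from_table(de, cluster, "surgery")
    if gene not in diet or gene not in surg or diet[gene] == surg[gene]:
        return False
    resid = degs_from_table(de, cluster, "residual")
    return gene not in resid


def cross_celltype_categories(
    calls: pd.DataFrame, clusters: tuple
) -> dict[str, set[str]]:
    """Partition rescued genes of two clusters into {both, first_only,
    second_only} by membership."""
    a, b = clusters
    resc = calls[calls["category"] == "rescued"]
    set_a = set(resc.loc[resc["cluster"] == a, "gene"])
    set_b = set(resc.loc[resc["cluster"] == b, "gene"])
    return {
        "both": set_a & set_b,
        "first_only": set_a - set_b,
        "second_only": set_b - set_a,
    }


def expression_long_format(
    norm: np.ndarray,
    symbols,
    conditions,
    clusters,
    genes,
    cluster_scope=None,
) -> pd.DataFrame:
    """Violin-ready long-format export of normalized expression for selected
    genes: one row per (cell, gene) with cluster and condition labels."""
    symbols = np.asarray(list(symbols))
    lookup = {s: j for j, s in enumerate(symbols)}
    missing = [g for g in genes if g not in lookup]
    if missing:
        raise KeyError(f"genes absent from gene space: {missing}")
    clusters = np.asarray(clusters)
    conditions = np.asarray(conditions)
    mask = (
        np.isin(clusters, list(cluster_scope))
        if cluster_scope is not None
        else np.ones(len(clusters), dtype=bool)
    )
    rows = []
    idx = np.flatnonzero(mask)
    for g in genes:
        j = lookup[g]
        rows.append(
            pd.DataFrame(
                {
                    "gene": g,
                    "cluster": clusters[idx],
                    "condition": conditions[idx],
                    "expression": norm[idx, j],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
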