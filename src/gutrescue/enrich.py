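"""Hypergeometric gene-set over-representation analysis (ORA).

A local, exact replacement for web-based enrichment services: for a query
gene set (e.g. the genes a cluster's surgery contrast upregulates, or its
rescued genes) and a GMT library, each term is scored with the
hypergeometric upper-tail probability of the observed overlap given the
tested-gene universe, then BH-adjusted across the library's terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import adjust_bh

logger = logging.getLogger(__name__)


@dataclass
class GeneSetLibrary:
    """Named collection of term -> gene set mappings."""

    name: str
    terms: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for term, genes in self.terms.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"term {term!r} has no genes")
            clean[term] = genes
        self.terms = clean

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path, name: str | None = None) -> GeneSetLibrary:
    """Parse a GMT file (term, description, tab-separated genes).

    Duplicate genes within a term are deduplicated; a line with fewer than
    three fields is an error reported with its line number.
    """
    terms: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (term, description, genes), got {len(fields)}"
                )
            term = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if term in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = genes
    return GeneSetLibrary(name=name or str(path), terms=terms)


def write_gmt(library: GeneSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for term, genes in library.terms.items():
            fh.write("\t".join([term, library.name] + sorted(genes)) + "\n")


def hypergeom_enrich(
    query, library: GeneSetLibrary, universe
) -> pd.DataFrame:
    """Over-representation of a query set in each library term.

    p = P[X >= k] for X ~ Hypergeom(N=|universe|, K=|term ∩ universe|,
    n=|query|); BH across terms; sorted by (padj, p, term).  Query genes
    outside the universe are dropped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning(
            "%d query genes outside the universe dropped (e.g. %s)",
            len(outside), sorted(outside)[:3],
        )
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for term, genes in library.terms.items():
        K = len(genes & universe)
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    res = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    res["padj"] = adjust_bh(res["p"].to_numpy()) if len(res) else res["p"]
    return res.sort_values(["padj", "p", "term"], kind="stable").reset_index(drop=True)


def enrichment_matrix(
    results: dict[object, pd.DataFrame], threshold: float | None = None
) -> pd.DataFrame:
    """Cluster x term matrix of -log10(padj) from per-cluster enrichment
    results sharing a library.  ``threshold`` zeroes cells with padj above
    it (heatmap sparsification); padj = 1 maps to 0."""
    mats = {}
    for key, res in results.items():
        vals = -np.log10(np.maximum(res["padj"].to_numpy(), 1e-300))
        if threshold is not None:
            vals = np.where(res["padj"].to_numpy() <= threshold, vals, 0.0)
        mats[key] = pd.Series(vals, index=res["term"].to_numpy())
    mat = pd.DataFrame(mats).T.fillna(0.0)
    mat.index.name = "cluster"
    return mat
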