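"""Core containers and on-disk formats.

The central in-memory object is :class:`CountBundle`, a droplet-style sparse
cell x gene count matrix plus per-cell labels (sample, condition, compartment)
and per-gene annotation (symbol, mitochondrial flag).  On disk a bundle is the
CellRanger triplet layout (``matrix.mtx`` with genes as rows, ``features.tsv``,
``barcodes.tsv``) plus a ``metadata.tsv`` sidecar carrying the per-barcode
condition and compartment labels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

CONDITIONS = ("LFD_sham", "HFD_sham", "HFD_VSG")
COMPARTMENTS = ("crypt", "villus")

#: The 13 protein-coding genes of the mouse mitochondrial genome.
MITO_PANEL = (
    "mt-Nd1", "mt-Nd2", "mt-Nd3", "mt-Nd4", "mt-Nd4l", "mt-Nd5", "mt-Nd6",
    "mt-Co1", "mt-Co2", "mt-Co3", "mt-Cytb", "mt-Atp6", "mt-Atp8",
)


class BundleError(ValueError):
    """Raised when a CountBundle violates its structural contract."""


@dataclass
class CountBundle:
    """Sparse droplet counts with cell and gene annotation.

    Attributes
    ----------
    counts
        ``cells x genes`` CSR matrix of non-negative integers.
    cells
        DataFrame indexed 0..n-1 with columns ``barcode``, ``sample``,
        ``condition`` and ``compartment``.
    genes
        DataFrame with columns ``symbol`` and ``is_mito``.
    """

    counts: sp.csr_matrix
    cells: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.cells):
            raise BundleError(
                f"count matrix has {self.counts.shape[0]} rows but cell table "
                f"has {len(self.cells)} entries"
            )
        if self.counts.shape[1] != len(self.genes):
            raise BundleError(
                f"count matrix has {self.counts.shape[1]} columns but gene "
                f"table has {len(self.genes)} entries"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise BundleError("counts must be non-negative")
        barcodes = self.cells["barcode"]
        if barcodes.duplicated().any():
            dup = barcodes[barcodes.duplicated()].iloc[0]
            raise BundleError(f"duplicate barcode {dup!r}")
        self.cells = self.cells.reset_index(drop=True)
        self.genes = self.genes.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> pd.Series:
        return self.cells["barcode"]

    @property
    def symbols(self) -> pd.Series:
        return self.genes["symbol"]

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Mitochondrial counts / total counts per cell (0 for empty cells)."""
        totals = self.total_counts().astype(float)
        mito = np.asarray(
            self.counts[:, self.genes["is_mito"].to_numpy()].sum(axis=1)
        ).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
        return frac

    def subset_cells(self, mask: np.ndarray) -> "CountBundle":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountBundle(
            counts=self.counts[idx],
            cells=self.cells.iloc[idx].reset_index(drop=True),
            genes=self.genes.copy(),
        )

    def gene_index(self, symbols) -> np.ndarray:
        """Column indices for gene symbols; raises on missing symbols."""
        lookup = {s: i for i, s in enumerate(self.genes["symbol"])}
        missing = [s for s in symbols if s not in lookup]
        if missing:
            raise KeyError(f"genes absent from gene space: {missing}")
        return np.array([lookup[s] for s in symbols], dtype=int)

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.astype(np.float32),
            obs=self.cells.set_index("barcode"),
            var=self.genes.set_index("symbol"),
        )
        return adata

    def copy(self) -> "CountBundle":
        return CountBundle(self.counts.copy(), self.cells.copy(), self.genes.copy())


def write_bundle(bundle: CountBundle, dir_path, overwrite: bool = False) -> Path:
    """Write a bundle in CellRanger triplet layout plus a metadata sidecar.

    Files written: ``matrix.mtx`` (genes x cells, integer), ``features.tsv``,
    ``barcodes.tsv``, ``metadata.tsv``.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    targets = ["matrix.mtx", "features.tsv", "barcodes.tsv", "metadata.tsv"]
    if not overwrite:
        clashes = [t for t in targets if (out / t).exists()]
        if clashes:
            raise FileExistsError(
                f"{clashes} already present in {out}; pass overwrite=True"
            )
    # CellRanger stores the matrix genes-as-rows.
    mat = sp.coo_matrix(bundle.counts.T.astype(np.int64))
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    feats = pd.DataFrame(
        {
            "gene_id": bundle.genes["symbol"],
            "gene_symbol": bundle.genes["symbol"],
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    bundle.cells[["barcode"]].to_csv(
        out / "barcodes.tsv", sep="\t", header=False, index=False
    )
    bundle.cells.to_csv(out / "metadata.tsv", sep="\t", index=False)
    return out


def read_bundle(dir_path) -> CountBundle:
    """Read a bundle written by :func:`write_bundle`.

    Also accepts a bare CellRanger triplet (no ``metadata.tsv``); labels then
    default to a single unknown sample.
    """
    src = Path(dir_path)
    mat = scipy.io.mmread(str(src / "matrix.mtx"))
    counts = sp.csr_matrix(mat.T).astype(np.int64)
    feats = pd.read_csv(src / "features.tsv", sep="\t", header=None)
    symbols = feats.iloc[:, 1] if feats.shape[1] > 1 else feats.iloc[:, 0]
    genes = pd.DataFrame(
        {
            "symbol": symbols.astype(str).to_numpy(),
            "is_mito": symbols.astype(str).str.startswith("mt-").to_numpy(),
        }
    )
    meta_path = src / "metadata.tsv"
    if meta_path.exists():
        cells = pd.read_csv(meta_path, sep="\t", dtype={"barcode": str})
    else:
        bc_path = src / "barcodes.tsv"
        barcodes = (
            pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str)
            if bc_path.stat().st_size > 0
            else pd.Series([], dtype=str)
        )
        cells = pd.DataFrame(
            {
                "barcode": barcodes,
                "sample": "unknown",
                "condition": "unknown",
                "compartment": "unknown",
            }
        )
    return CountBundle(counts=counts, cells=cells, genes=genes)


@dataclass
class MarkerReference:
    """Cell type -> marker gene symbols, e.g. the intestinal epithelial
    lineage markers used for cluster annotation."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    immune_label: str = "immune"

    def __post_init__(self) -> None:
        clean = {}
        for cell_type, genes in self.sets.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"marker set for {cell_type!r} is empty")
            clean[cell_type] = genes
        self.sets = clean

    @property
    def cell_types(self) -> list[str]:
        return list(self.sets)

    @classmethod
    def from_tsv(cls, path) -> "MarkerReference":
        df = pd.read_csv(path, sep="\t")
        sets = {
            ct: frozenset(sub["gene"]) for ct, sub in df.groupby("cell_type")
        }
        return cls(sets=sets)

    @classmethod
    def builtin(cls) -> "MarkerReference":
        with importlib.resources.as_file(
            importlib.resources.files("gutrescue.data") / "marker_reference.tsv"
        ) as p:
            return cls.from_tsv(p)


def builtin_cell_cycle_genes() -> tuple[list[str], list[str]]:
    """Bundled S-phase and G2/M marker gene lists (mouse symbols)."""
    out = []
    for name in ("s_genes.txt", "g2m_genes.txt"):
        with importlib.resources.as_file(
            importlib.resources.files("gutrescue.data") / name
        ) as p:
            out.append([ln.strip() for ln in p.read_text().splitlines() if ln.strip()])
    return out[0], out[1]
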