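import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from gutrescue.core import CountBundle, MarkerReference
from gutrescue.simulate import SimConfig, simulate_bundle, simulate_counts


def small_config(**overrides) -> SimConfig:
    """Desk-scale simulation used by unit tests: 3 clusters, 100 cells per
    cluster per condition, 500 genes."""
    base = dict(
        n_clusters=3,
        cells_per_cluster_per_condition=100,
        n_genes=500,
        markers_per_cluster=25,
        n_empty_droplets=500,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_clean():
    """Clean (no soup / doublets / empties) small bundle with truth."""
    return simulate_counts(small_config())


@pytest.fixture(scope="session")
def small_full():
    """Small bundle with soup, empty droplets and doublets."""
    return simulate_bundle(small_config())


@pytest.fixture(scope="session")
def marker_ref():
    return MarkerReference.builtin()


def toy_bundle(counts, samples=None, conditions=None, compartments=None, symbols=None):
    """Hand-built bundle from a dense count array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    cells = pd.DataFrame(
        {
            "barcode": [f"T{i:03d}" for i in range(n)],
            "sample": samples if samples is not None else ["s1"] * n,
            "condition": conditions if conditions is not None else ["LFD_sham"] * n,
            "compartment": compartments if compartments is not None else ["crypt"] * n,
        }
    )
    symbols = symbols if symbols is not None else [f"G{j}" for j in range(g)]
    genes = pd.DataFrame(
        {"symbol": symbols, "is_mito": [s.startswith("mt-") for s in symbols]}
    )
    return CountBundle(counts=sp.csr_matrix(counts), cells=cells, genes=genes)


def marker_leakage(bundle, truth, ref) -> float:
    """Mean fraction of a cluster's reads falling on *other* clusters'
    reference markers — the soup-contamination read-out used in tests."""
    lab = np.array([truth.cluster_labels.get(bc, -1) for bc in bundle.cells["barcode"]])
    sym = {s: j for j, s in enumerate(bundle.genes["symbol"])}
    vals = []
    for k, ct in truth.cell_types.items():
        own = truth.cell_types[k]
        other_marks = [
            g
            for kk, ct2 in truth.cell_types.items()
            if kk != k and ct2 != own
            for g in ref.sets.get(ct2, ())
            if g in sym
        ]
        cells = bundle.counts[lab == k]
        if cells.shape[0] == 0 or not other_marks:
            continue
        cols = [sym[g] for g in set(other_marks)]
        tot = cells.sum()
        vals.append(cells[:, cols].sum() / tot if tot else 0.0)
    return float(np.mean(vals))
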