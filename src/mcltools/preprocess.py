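"""Single-cell QC, normalization, clustering, cell typing and rank-sum DE.

The container convention throughout the package is :class:`anndata.AnnData`:
raw integer counts in ``.X``, per-cell metadata in ``.obs`` (sample, barcode
and derived QC stats), per-gene metadata in ``.var`` (symbol index,
chromosome, 1-based start, mito/ribo/immunoglobulin flags).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_MARKER_SETS: dict[str, list[str]] = {
    "B": ["CD19", "MS4A1", "CD79A"],
    "T": ["CD3D", "CD3E", "CD3G"],
    "NK": ["XCL2", "NKG7", "GNLY"],
    "myeloid": ["CD68", "CD33", "CST3"],
    "erythrocyte": ["HBQ1", "HBM", "GYPA"],
}
# fixed order used for deterministic tie-breaking
TYPE_ORDER = list(DEFAULT_MARKER_SETS)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # per-cell integer cluster label, dense from 0
    resolution: float
    seed: int
    sizes: pd.Series = field(default=None)

    def __post_init__(self):
        if self.sizes is None:
            self.sizes = self.labels.value_counts().sort_index()

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    def fractions(self, samples: pd.Series) -> pd.DataFrame:
        """Per-sample fractional cluster abundances (rows sum to 1)."""
        tab = pd.crosstab(samples, self.labels)
        return tab.div(tab.sum(axis=1), axis=0)


@dataclass
class CellTypeCall:
    cluster_types: dict[int, str]
    scores: pd.DataFrame  # clusters x types

    def cell_types(self, labels: pd.Series) -> pd.Series:
        return labels.map(self.cluster_types).rename("cell_type")


def compute_qc_stats(adata: ad.AnnData) -> ad.AnnData:
    """Attach n_genes_detected, total_counts, pct_mito, pct_ribo to ``.obs``."""
    for flag in ("is_mito", "is_ribo"):
        if flag not in adata.var:
            prefix = ("MT-",) if flag == "is_mito" else ("RPL", "RPS")
            adata.var[flag] = adata.var_names.str.startswith(prefix)
    X = sp.csr_matrix(adata.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    detected = X.getnnz(axis=1)
    mito = np.asarray(X[:, adata.var["is_mito"].to_numpy()].sum(axis=1)).ravel()
    ribo = np.asarray(X[:, adata.var["is_ribo"].to_numpy()].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(totals > 0, 100.0 * mito / totals, 0.0)
        pct_ribo = np.where(totals > 0, 100.0 * ribo / totals, 0.0)
    adata.obs["n_genes_detected"] = detected
    adata.obs["total_counts"] = totals
    adata.obs["pct_mito"] = pct_mito
    adata.obs["pct_ribo"] = pct_ribo
    return adata


def apply_qc(
    adata: ad.AnnData,
    min_genes: int = 500,
    max_genes: int = 5000,
    max_counts: float = 40_000,
    max_pct_mito: float = 20.0,
    min_pct_ribo: float = 5.0,
    min_cells_per_gene: int = 3,
) -> ad.AnnData:
    """QC filtering: genes detected in >=3 cells first, then cell filters.

    Cells are kept when ``min_genes <= n_genes_detected <= max_genes``,
    ``total_counts <= max_counts``, ``pct_mito <= max_pct_mito`` and
    ``pct_ribo >= min_pct_ribo`` — i.e. cells with strictly more than 20%
    mitochondrial or strictly less than 5% ribosomal transcripts are
    removed. Cell statistics are recomputed on the gene-filtered matrix.
    Idempotent; an empty result is a warning, not an error.
    """
    if "is_mito" not in adata.var or "is_ribo" not in adata.var:
        compute_qc_stats(adata)
    if adata.n_obs == 0:
        return adata.copy()
    X = sp.csr_matrix(adata.X)
    cells_per_gene = (X > 0).sum(axis=0).A.ravel()
    adata = adata[:, cells_per_gene >= min_cells_per_gene].copy()
    compute_qc_stats(adata)
    obs = adata.obs
    keep = (
        (obs["n_genes_detected"] >= min_genes)
        & (obs["n_genes_detected"] <= max_genes)
        & (obs["total_counts"] <= max_counts)
        & (obs["pct_mito"] <= max_pct_mito)
        & (obs["pct_ribo"] >= min_pct_ribo)
    )
    if not keep.any():
        warnings.warn("QC removed every cell")
    return adata[keep.to_numpy()].copy()


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Library-size normalization: value = log1p(count / cell_total * 1e4).

    Raw counts are preserved in ``.layers['counts']``. All-zero cells pass
    through as all-zero rows with a warning.
    """
    out = adata.copy()
    X = sp.csr_matrix(out.X).astype(np.float64)
    out.layers["counts"] = X.copy()
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} all-zero cells passed through")
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    out.X = sp.csr_matrix(X)
    return out


def cluster_cells(
    adata: ad.AnnData,
    resolution: float = 0.6,
    seed: int = 0,
    n_pcs: int = 30,
    n_neighbors: int = 15,
) -> ClusterAssignment:
    """SNN-graph modularity clustering on top principal components.

    PCA (30 components by default, fewer when rank-limited) on the
    log-normalized matrix, a shared-nearest-neighbor graph, and Leiden
    modularity optimization at the given resolution. Deterministic for a
    fixed seed.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells to cluster")
    X = sp.csr_matrix(adata.X)
    # degenerate input: no variance at all -> single cluster
    dense_var = np.asarray(X.power(2).mean(axis=0)).ravel() - np.square(
        np.asarray(X.mean(axis=0)).ravel()
    )
    if not np.any(dense_var > 1e-12):
        labels = pd.Series(0, index=adata.obs_names, name="cluster")
        return ClusterAssignment(labels, resolution, seed)
    work = adata.copy()
    n_comps = int(min(n_pcs, work.n_obs - 1, work.n_vars - 1))
    sc.pp.pca(work, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(
        work, n_neighbors=min(n_neighbors, work.n_obs - 1), random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            work,
            resolution=resolution,
            random_state=seed,
            key_added="cluster",
            flavor="leidenalg",
        )
    labels = work.obs["cluster"].astype(int)
    # dense relabel in first-appearance order
    remap = {old: new for new, old in enumerate(pd.unique(labels))}
    labels = labels.map(remap).rename("cluster")
    return ClusterAssignment(labels, resolution, seed)


def annotate_major_types(
    adata: ad.AnnData,
    clusters: ClusterAssignment,
    marker_sets: dict[str, list[str]] | None = None,
) -> CellTypeCall:
    """Assign one major type per cluster by argmax mean scaled marker score.

    Marker expression is z-scored per gene across all cells; a cluster's
    score for a type is the mean z-score of that type's markers over the
    cluster's cells. Ties break by the fixed type order with a warning.
    """
    marker_sets = marker_sets or DEFAULT_MARKER_SETS
    present = {
        t: [g for g in gs if g in adata.var_names] for t, gs in marker_sets.items()
    }
    if not any(present.values()):
        raise ValueError("no marker gene present in the matrix")
    X = sp.csr_matrix(adata.X)
    scores = {}
    for t, genes in present.items():
        if not genes:
            scores[t] = np.full(adata.n_obs, -np.inf)
            continue
        sub = np.asarray(X[:, [adata.var_names.get_loc(g) for g in genes]].todense())
        mu, sd = sub.mean(axis=0), sub.std(axis=0)
        sd[sd == 0] = 1.0
        scores[t] = ((sub - mu) / sd).mean(axis=1)
    score_df = pd.DataFrame(scores, index=adata.obs_names)
    cluster_scores = score_df.groupby(clusters.labels).mean()
    types = {}
    for cl, row in cluster_scores.iterrows():
        finite = row[np.isfinite(row)]
        best = finite.max()
        winners = [t for t in marker_sets if t in finite.index and finite[t] == best]
        if len(winners) > 1:
            warnings.warn(f"cluster {cl}: marker-score tie among {winners}")
        types[int(cl)] = winners[0]
    return CellTypeCall(cluster_types=types, scores=cluster_scores)


def differential_expression(
    adata: ad.AnnData,
    group_a: np.ndarray | pd.Index,
    group_b: np.ndarray | pd.Index,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per gene with Benjamini-Hochberg adj_p.

    ``group_a``/``group_b`` are cell-id lists or boolean masks over
    ``adata`` (log-normalized values expected in ``.X``). The returned table
    (gene, lfc, p, adj_p) is sorted by adj_p then descending |lfc|; lfc is
    log2 of the ratio of group means on the de-logged scale.
    """

    def resolve(sel):
        arr = np.asarray(sel)
        if arr.dtype == bool:
            return np.flatnonzero(arr)
        if np.issubdtype(arr.dtype, np.integer):
            return arr
        return np.array([adata.obs_names.get_loc(c) for c in sel])

    ia, ib = resolve(group_a), resolve(group_b)
    if len(ia) < min_group_size or len(ib) < min_group_size:
        raise ValueError(f"both groups need >= {min_group_size} cells")
    X = sp.csr_matrix(adata.X)
    A = np.asarray(X[ia].todense())
    B = np.asarray(X[ib].todense())
    res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided", method="asymptotic")
    p = np.asarray(res.pvalue)
    eps = 1e-9
    lfc = np.log2((np.expm1(A).mean(axis=0) + eps) / (np.expm1(B).mean(axis=0) + eps))
    adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"gene": adata.var_names, "lfc": lfc, "p": p, "adj_p": adj}
    )
    table["_abs"] = table["lfc"].abs()
    table = (
        table.sort_values(["adj_p", "_abs"], ascending=[True, False], kind="stable")
        .drop(columns="_abs")
        .reset_index(drop=True)
    )
    return table
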