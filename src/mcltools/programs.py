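"""Consensus NMF expression programs, cophenetic K selection and
meta-programs shared across samples.

Per sample, NMF with random restarts is run over a range of K; restart
stability is summarized by a cell-cell consensus matrix and its cophenetic
correlation, and K is chosen as the first value where the coefficient
starts decreasing. Each program is represented by its 30 top-scoring genes;
programs from all samples are hierarchically clustered using the number of
shared top genes as the similarity, yielding meta-programs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import wilcoxon
from sklearn.decomposition import NMF

TOP_GENES = 30


@dataclass
class ExpressionProgram:
    sample: str
    index: int
    scores: pd.Series  # per-gene non-negative score vector
    top_genes: list[str]
    usages: pd.Series  # per-cell usage weight

    @property
    def name(self) -> str:
        return f"{self.sample}:P{self.index}"


@dataclass
class ConsensusResult:
    k: int
    programs: list[ExpressionProgram]
    cophenetic: float
    consensus: np.ndarray  # cells x cells co-assignment fraction
    reconstruction_error: float


@dataclass
class MetaProgram:
    label: str
    members: list[ExpressionProgram]
    consensus_genes: list[str] = field(default_factory=list)


def prepare_nmf_input(adata) -> tuple[np.ndarray, list[str]]:
    """Variance-scaled non-negative matrix from log-normalized expression.

    Genes are z-scored across cells and negative values clipped at zero
    (the cNMF convention); zero-variance genes are dropped.
    """
    X = np.asarray(sp.csr_matrix(adata.X).todense())
    mu, sd = X.mean(axis=0), X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    return np.clip(Z, 0, None), list(np.asarray(adata.var_names)[keep])


def run_consensus_nmf(
    X: np.ndarray,
    gene_names: list[str],
    k_range=range(2, 11),
    n_restarts: int = 20,
    seed: int = 0,
    sample_id: str = "sample",
    max_iter: int = 300,
) -> dict[int, ConsensusResult]:
    """NMF over a K range with restart-consensus stability per K.

    For each K, ``n_restarts`` random-initialization NMF fits (Frobenius
    objective, coordinate descent) are run; the consensus matrix holds the
    fraction of restarts co-assigning two cells to the same max-usage
    program, and the cophenetic coefficient correlates consensus distances
    with the cophenetic distances of their average-linkage dendrogram.
    Programs are reported from the restart with the lowest reconstruction
    error. K values exceeding the cell count are skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("NMF input must be non-negative")
    n_cells = X.shape[0]
    rng = np.random.default_rng(seed)
    out: dict[int, ConsensusResult] = {}
    for k in k_range:
        if k > n_cells:
            warnings.warn(f"K={k} exceeds the cell count; skipped")
            continue
        consensus = np.zeros((n_cells, n_cells))
        best = None
        for _ in range(n_restarts):
            state = int(rng.integers(0, 2**31 - 1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = NMF(
                    n_components=k, init="random", random_state=state,
                    max_iter=max_iter, solver="cd", beta_loss="frobenius",
                )
                W = model.fit_transform(X)
            assign = W.argmax(axis=1)
            consensus += assign[:, None] == assign[None, :]
            if best is None or model.reconstruction_err_ < best[0]:
                best = (model.reconstruction_err_, W, model.components_)
        consensus /= n_restarts
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        if np.allclose(condensed, 0):
            coph = 1.0  # perfectly stable assignment
        else:
            Z = average(condensed)
            coph = float(cophenet(Z, condensed)[0])
        err, W, H = best
        programs = []
        for j in range(k):
            scores = pd.Series(H[j], index=gene_names)
            top = list(scores.sort_values(ascending=False).index[:TOP_GENES])
            programs.append(
                ExpressionProgram(
                    sample=sample_id, index=j, scores=scores, top_genes=top,
                    usages=pd.Series(W[:, j]),
                )
            )
        out[k] = ConsensusResult(
            k=k, programs=programs, cophenetic=coph, consensus=consensus,
            reconstruction_error=err,
        )
    return out


def select_k(cophenetic: dict[int, float]) -> int:
    """First K where the cophenetic coefficient starts decreasing.

    Returns the smallest K with coph(K) > coph(K+1); a strictly
    non-decreasing sequence returns the largest K with a warning. Requires
    a contiguous K range with at least two entries.
    """
    ks = sorted(cophenetic)
    if len(ks) < 2:
        raise ValueError("need cophenetic coefficients for at least two K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    for k in ks[:-1]:
        if cophenetic[k] > cophenetic[k + 1]:
            return k
    warnings.warn("cophenetic coefficient never decreases; returning max K")
    return ks[-1]


def shared_gene_counts(programs: list[ExpressionProgram]) -> np.ndarray:
    n = len(programs)
    sets = [set(p.top_genes) for p in programs]
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            sim[i, j] = sim[j, i] = len(sets[i] & sets[j])
    return sim


def build_meta_programs(
    programs: list[ExpressionProgram],
    cut_height: float = TOP_GENES - 3,
    min_consensus_members: int = 2,
) -> list[MetaProgram]:
    """Group programs across samples by shared top-gene counts.

    distance(i, j) = 30 - |top_i n top_j|; average-linkage clustering cut
    at ``cut_height`` (default 27, i.e. programs sharing >= 3 of their top
    30 genes merge). The consensus gene set collects genes appearing in at
    least ``min_consensus_members`` member programs (all top genes for
    singleton meta-programs).
    """
    if len(programs) < 2:
        raise ValueError("need at least 2 programs")
    sim = shared_gene_counts(programs)
    dist = TOP_GENES - sim
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    flat = fcluster(Z, t=cut_height, criterion="distance")
    metas = []
    for label in np.unique(flat):
        members = [p for p, f in zip(programs, flat) if f == label]
        if len(members) == 1:
            consensus = list(members[0].top_genes)
        else:
            counts = pd.Series(
                [g for p in members for g in p.top_genes]
            ).value_counts()
            consensus = list(counts.index[counts >= min_consensus_members])
        metas.append(
            MetaProgram(label=f"MP{label}", members=members, consensus_genes=consensus)
        )
    return metas


def score_meta_program(adata, gene_set: list[str]) -> pd.Series:
    """Per-cell mean log-normalized expression over the meta-program genes."""
    if not gene_set:
        raise ValueError("empty gene set")
    present = [g for g in gene_set if g in adata.var_names]
    if not present:
        raise ValueError("gene set disjoint from the matrix")
    X = sp.csr_matrix(adata.X)
    sub = np.asarray(X[:, [adata.var_names.get_loc(g) for g in present]].todense())
    return pd.Series(sub.mean(axis=1), index=adata.obs_names, name="score")


def compare_paired(adata, gene_set: list[str], cells_a, cells_b) -> tuple[float, float]:
    """Paired change of a meta-program between two samples.

    Per-gene means over each sample's cells are compared by a two-sided
    Wilcoxon signed-rank test; returns (mean difference B - A, p). With no
    signed differences at all the test is degenerate and p = 1.
    """
    present = [g for g in gene_set if g in adata.var_names]
    if not present:
        raise ValueError("gene set disjoint from the matrix")
    X = sp.csr_matrix(adata.X)
    cols = [adata.var_names.get_loc(g) for g in present]
    rows_a = [adata.obs_names.get_loc(c) for c in cells_a]
    rows_b = [adata.obs_names.get_loc(c) for c in cells_b]
    mean_a = np.asarray(X[rows_a][:, cols].mean(axis=0)).ravel()
    mean_b = np.asarray(X[rows_b][:, cols].mean(axis=0)).ravel()
    diff = mean_b - mean_a
    delta = float(diff.mean())
    if np.allclose(diff, 0):
        return delta, 1.0
    stat = wilcoxon(diff, alternative="two-sided", zero_method="zsplit")
    return delta, float(stat.pvalue)
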