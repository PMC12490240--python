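"""CellPhoneDB-style ligand-receptor scoring with a label-permutation null.

The interaction statistic for (pair, sender type, receiver type) is the
average of the ligand's mean expression in the sender and the receptor's
mean expression in the receiver; complexes score as the minimum over their
subunits' means. Significance comes from shuffling cell-type labels across
all cells (1000 permutations by default) with the pseudocount estimator
p = (1 + #{null >= observed}) / (1 + n_perm), so p is never 0. Reported
interactions must satisfy p < 0.05, both expressed fractions > 10%, and
membership in a curated immune-related list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class LrPair:
    name: str
    ligand: list[str]
    receptor: list[str]
    annotation: str = "other"  # costimulation | coinhibition | other

    def __post_init__(self):
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor gene sets must be non-empty")


@dataclass
class InteractionResult:
    pair: str
    sender: str
    receiver: str
    statistic: float
    p_value: float
    ligand_fraction: float
    receptor_fraction: float
    extra: dict = field(default_factory=dict)


def _gene_matrix(adata, genes: list[str]) -> np.ndarray | None:
    if any(g not in adata.var_names for g in genes):
        return None
    X = sp.csr_matrix(adata.X)
    return np.asarray(X[:, [adata.var_names.get_loc(g) for g in genes]].todense())


def _counts_matrix(adata, genes: list[str]) -> np.ndarray:
    X = adata.layers.get("counts", adata.X)
    X = sp.csr_matrix(X)
    return np.asarray(X[:, [adata.var_names.get_loc(g) for g in genes]].todense())


def lr_statistic(
    adata,
    types: pd.Series,
    pair: LrPair,
    sender: str,
    receiver: str,
) -> tuple[float, float, float]:
    """Observed statistic plus expressed fractions for one directed pair.

    Returns ``(statistic, ligand_fraction, receptor_fraction)`` where the
    fractions are, per component gene within its own cell type, the
    fraction of cells with a nonzero raw count, minimized over components.
    Missing genes raise KeyError (callers typically skip and log the pair).
    """
    for t, role in ((sender, "sender"), (receiver, "receiver")):
        if not (types == t).any():
            raise ValueError(f"{role} type {t!r} absent from the labels")
    lig = _gene_matrix(adata, pair.ligand)
    rec = _gene_matrix(adata, pair.receptor)
    if lig is None or rec is None:
        raise KeyError(f"pair {pair.name}: component gene missing from the matrix")
    s_mask = (types == sender).to_numpy()
    r_mask = (types == receiver).to_numpy()
    lig_mean = float(lig[s_mask].mean(axis=0).min())
    rec_mean = float(rec[r_mask].mean(axis=0).min())
    stat = (lig_mean + rec_mean) / 2.0
    lig_counts = _counts_matrix(adata, pair.ligand)
    rec_counts = _counts_matrix(adata, pair.receptor)
    lig_frac = float((lig_counts[s_mask] > 0).mean(axis=0).min())
    rec_frac = float((rec_counts[r_mask] > 0).mean(axis=0).min())
    return stat, lig_frac, rec_frac


def permutation_test(
    adata,
    types: pd.Series,
    pair: LrPair,
    sender: str,
    receiver: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> InteractionResult:
    """Label-permutation p-value for one directed ligand-receptor pair.

    The null redistributes the full cell-type label multiset across all
    cells; the observed statistic is compared against the permuted ones
    with a +1 pseudocount on both sides. Deterministic given the seed.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if len(types) != adata.n_obs:
        raise ValueError("label multiset does not match the cell count")
    stat, lig_frac, rec_frac = lr_statistic(adata, types, pair, sender, receiver)
    lig = _gene_matrix(adata, pair.ligand)
    rec = _gene_matrix(adata, pair.receptor)
    labels = types.to_numpy()
    n = len(labels)
    n_s = int((labels == sender).sum())
    n_r = int((labels == receiver).sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        s_idx = perm[:n_s]
        r_idx = perm[n_s : n_s + n_r]
        null[i] = (
            lig[s_idx].mean(axis=0).min() + rec[r_idx].mean(axis=0).min()
        ) / 2.0
    p = (1.0 + float((null >= stat).sum())) / (1.0 + n_perm)
    return InteractionResult(
        pair=pair.name, sender=sender, receiver=receiver, statistic=stat,
        p_value=p, ligand_fraction=lig_frac, receptor_fraction=rec_frac,
    )


def filter_interactions(
    results: list[InteractionResult] | pd.DataFrame,
    curated_pairs: list[str] | None = None,
    max_p: float = 0.05,
    min_fraction: float = 0.10,
) -> pd.DataFrame:
    """Reported set: p < 0.05, both fractions > 10%, pair on the curated list.

    With an empty curated list only the p and fraction filters apply (a
    warning is emitted).
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(
            [
                dict(pair=r.pair, sender=r.sender, receiver=r.receiver,
                     statistic=r.statistic, p_value=r.p_value,
                     ligand_fraction=r.ligand_fraction,
                     receptor_fraction=r.receptor_fraction)
                for r in results
            ]
        )
    keep = (
        (results["p_value"] < max_p)
        & (results["ligand_fraction"] > min_fraction)
        & (results["receptor_fraction"] > min_fraction)
    )
    if curated_pairs:
        keep &= results["pair"].isin(set(curated_pairs))
    else:
        warnings.warn("no curated list supplied; filtering on p and fractions only")
    return results[keep].reset_index(drop=True)
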