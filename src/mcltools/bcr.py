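"""BCR clonotyping: quality filtering, clonotype keys, dominance, SHM and
the kappa/lambda light-chain restriction ratio.

A clonotype is the exact key (heavy V, heavy J, heavy CDR3 peptide, light V,
light J, light CDR3 peptide) over a cell's paired chains. A clonotype is
*dominant* in a sample when strictly more than 5% of that sample's
BCR-assigned cells carry it; remaining cells are polyclonal. SHM is counted
as nucleotide mismatches of the observed IGHV against its germline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HEAVY_LOCUS = "IGH"
LIGHT_LOCI = ("IGK", "IGL")
CLONOTYPE_KEY_COLS = [
    "heavy_v", "heavy_j", "heavy_cdr3_aa", "light_v", "light_j", "light_cdr3_aa",
]
DOMINANCE_THRESHOLD = 0.05


@dataclass
class ClonotypeSet:
    """Clonotype assignments plus per-sample fractions and dominance flags."""

    cells: pd.DataFrame  # per cell: sample, clonotype key cols, clonotype label
    clonotypes: pd.DataFrame  # per (clonotype, sample): n_cells, fraction, dominant

    def dominant_keys(self, sample: str) -> list[str]:
        sub = self.clonotypes
        return sub.loc[
            (sub["sample"] == sample) & sub["dominant"], "clonotype"
        ].tolist()


def filter_rearrangements(raw: pd.DataFrame) -> pd.DataFrame:
    """Reduce an AIRR-style table to cells with one good heavy + one good light.

    Rows must be productive, full length (complete_vdj) and high confidence;
    cells retaining anything other than exactly one heavy and one light
    contig (e.g. two productive heavy chains, or a heavy chain only) are
    excluded from clonotype analysis. Returns one row per kept cell with
    heavy_*/light_* columns.
    """
    if raw.empty:
        return pd.DataFrame(
            columns=["cell_id", "sample", "light_locus", "heavy_sequence"]
            + CLONOTYPE_KEY_COLS
        )
    df = raw.copy()
    valid_locus = df["locus"].isin((HEAVY_LOCUS,) + LIGHT_LOCI)
    if (~valid_locus).any():
        logger.info("rejected %d rows with malformed locus", int((~valid_locus).sum()))
    df = df[valid_locus]
    for flag in ("productive", "complete_vdj", "high_confidence"):
        df = df[df[flag].astype(bool)]
    is_heavy = df["locus"] == HEAVY_LOCUS
    heavy = df[is_heavy]
    light = df[~is_heavy]
    h_counts = heavy.groupby("cell_id").size()
    l_counts = light.groupby("cell_id").size()
    good = h_counts[h_counts == 1].index.intersection(l_counts[l_counts == 1].index)
    n_ambiguous = int((h_counts > 1).sum())
    if n_ambiguous:
        logger.info("excluded %d cells with multiple productive heavy chains",
                    n_ambiguous)
    heavy = heavy.set_index("cell_id").loc[good]
    light = light.set_index("cell_id").loc[good]
    out = pd.DataFrame(index=good)
    if "sample" in heavy.columns:
        out["sample"] = heavy["sample"]
    out["heavy_v"] = heavy["v_call"]
    out["heavy_j"] = heavy["j_call"]
    out["heavy_cdr3_aa"] = heavy["cdr3_aa"]
    out["heavy_sequence"] = heavy["sequence"]
    out["light_locus"] = light["locus"]
    out["light_v"] = light["v_call"]
    out["light_j"] = light["j_call"]
    out["light_cdr3_aa"] = light["cdr3_aa"]
    out.index.name = "cell_id"
    return out.reset_index()


def assign_clonotypes(
    paired: pd.DataFrame,
    cells_per_sample: dict[str, int] | None = None,
    threshold: float = DOMINANCE_THRESHOLD,
) -> ClonotypeSet:
    """Group cells by exact clonotype key and call per-sample dominance.

    Dominance is strict: fraction > ``threshold`` (5%). The denominator is
    the number of BCR-assigned cells in the sample by default; pass
    ``cells_per_sample`` to use total cell counts instead (both readings of
    "cells in each sample" are in circulation).
    """
    cells = paired.copy()
    if cells.empty:
        return ClonotypeSet(
            cells=cells,
            clonotypes=pd.DataFrame(
                columns=["clonotype", "sample", "n_cells", "fraction", "dominant"]
            ),
        )
    cells["clonotype"] = cells[CLONOTYPE_KEY_COLS].agg("|".join, axis=1)
    grp = cells.groupby(["clonotype", "sample"]).size().rename("n_cells").reset_index()
    if cells_per_sample is None:
        denom = cells.groupby("sample").size().to_dict()
    else:
        denom = dict(cells_per_sample)
    grp["fraction"] = [
        n / denom[s] if denom.get(s) else np.nan
        for n, s in zip(grp["n_cells"], grp["sample"])
    ]
    grp["dominant"] = grp["fraction"] > threshold
    dominant = set(
        grp.loc[grp["dominant"], ["clonotype", "sample"]].itertuples(index=False)
    )
    cells["dominant"] = [
        (c, s) in dominant for c, s in zip(cells["clonotype"], cells["sample"])
    ]
    cells.loc[~cells["dominant"], "clonotype_class"] = "polyclonal"
    cells.loc[cells["dominant"], "clonotype_class"] = "dominant"
    return ClonotypeSet(cells=cells, clonotypes=grp)


def count_shm(observed: str, germline: str) -> tuple[int, float]:
    """Mismatch count and rate of an observed IGHV against its germline.

    Sequences are compared position-wise over the aligned V region,
    excluding positions where either base is N. Unequal lengths are resolved
    by a gap-free sliding alignment choosing the offset with maximal
    identity (ties: smallest offset).
    """
    if not observed or not germline:
        raise ValueError("empty sequence")
    a, b = observed.upper(), germline.upper()
    if any(c not in "ACGTN" for c in a + b):
        raise ValueError("sequences must be ACGTN")
    if len(a) != len(b):
        short, long_ = (a, b) if len(a) < len(b) else (b, a)
        best = None
        for off in range(len(long_) - len(short) + 1):
            window = long_[off : off + len(short)]
            ident = sum(x == y for x, y in zip(short, window))
            if best is None or ident > best[0]:
                best = (ident, off)
        off = best[1]
        a, b = short, long_[off : off + len(short)]
    pairs = [(x, y) for x, y in zip(a, b) if x != "N" and y != "N"]
    if not pairs:
        return 0, 0.0
    mismatches = sum(x != y for x, y in pairs)
    return mismatches, mismatches / len(pairs)


def shm_table(paired: pd.DataFrame, germlines: dict[str, str]) -> pd.DataFrame:
    """Per-cell SHM counts/rates from heavy sequences and germline IGHVs."""
    rows = []
    for _, r in paired.iterrows():
        germ = germlines.get(r["heavy_v"])
        if germ is None:
            rows.append((r["cell_id"], np.nan, np.nan))
            continue
        n, rate = count_shm(r["heavy_sequence"], germ)
        rows.append((r["cell_id"], n, rate))
    return pd.DataFrame(rows, columns=["cell_id", "shm_count", "shm_rate"])


def light_chain_ratio(igkc, iglc) -> np.ndarray | float:
    """Kappa restriction ratio: IGKC / (IGKC + max over IGLC1..IGLC7).

    ``iglc`` may be a vector of per-gene values (its max is used) or, for
    arrays, a (cells x IGLC-genes) matrix. Near 1 means kappa-restricted,
    near 0 lambda-restricted. When IGKC and every IGLC are zero the ratio is
    undefined and NaN is returned.
    """
    igkc = np.asarray(igkc, dtype=float)
    iglc = np.asarray(iglc, dtype=float)
    max_iglc = iglc if iglc.ndim == igkc.ndim else iglc.max(axis=-1)
    if igkc.ndim == 0:
        max_iglc = np.asarray(max_iglc, dtype=float).max()
    denom = igkc + max_iglc
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, igkc / np.where(denom > 0, denom, 1.0), np.nan)
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


IGLC_GENES = [f"IGLC{i}" for i in range(1, 8)]


def cell_light_chain_ratio(adata, use_counts: bool = True) -> pd.Series:
    """Per-cell IGK/IGL ratio from expression (raw counts by default)."""
    import scipy.sparse as sp

    if "IGKC" not in adata.var_names:
        raise KeyError("IGKC not present in the matrix")
    present_iglc = [g for g in IGLC_GENES if g in adata.var_names]
    X = adata.layers.get("counts") if use_counts else None
    if X is None:
        X = adata.X
    X = sp.csr_matrix(X)
    k = np.asarray(X[:, adata.var_names.get_loc("IGKC")].todense()).ravel()
    if present_iglc:
        L = np.asarray(
            X[:, [adata.var_names.get_loc(g) for g in present_iglc]].todense()
        )
    else:
        warnings.warn("no IGLC genes present; treating lambda expression as absent")
        L = np.zeros((len(k), 1))
    return pd.Series(light_chain_ratio(k, L), index=adata.obs_names, name="igk_igl_ratio")


def cluster_light_chain_ratio(adata, labels: pd.Series) -> pd.Series:
    """Cluster-level ratio from raw counts summed within each cluster."""
    import scipy.sparse as sp

    present_iglc = [g for g in IGLC_GENES if g in adata.var_names]
    X = adata.layers.get("counts", adata.X)
    X = sp.csr_matrix(X)
    out = {}
    for cl in sorted(labels.unique()):
        rows = np.flatnonzero((labels == cl).to_numpy())
        k = X[rows, adata.var_names.get_loc("IGKC")].sum()
        L = [X[rows, adata.var_names.get_loc(g)].sum() for g in present_iglc] or [0.0]
        out[cl] = light_chain_ratio(float(k), np.asarray(L, dtype=float))
    return pd.Series(out, name="igk_igl_ratio")
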