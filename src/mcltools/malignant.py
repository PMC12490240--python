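"""Multi-criteria malignant B-cell classification at cluster level.

A B-cell subcluster is called malignant when it shows (i) a single dominant
BCR clonotype, (ii) a consistent kappa/lambda light-chain ratio and (iii)
high CCND1 expression relative to a normal-B reference; the
expression-inferred CNV score acts as confirmation only — a cluster passing
the three primary criteria but failing CNV is demoted to ambiguous, never
promoted. T/B doublet clusters are flagged first and set aside.

All numeric thresholds are package defaults exposed as parameters; the
defining criteria are qualitative (clonal BCR + light-chain restriction +
CCND1 + CNV cross-validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

DOUBLET_B_MARKERS = ["CD19", "MS4A1", "CD79A"]
DOUBLET_T_MARKERS = ["CD3E", "CD4", "CD8A"]


@dataclass
class Thresholds:
    min_clonotype_fraction: float = 0.5
    ratio_mean_margin: float = 0.3  # |mean ratio - 0.5| must reach this
    ratio_sd_max: float = 0.15
    min_ccnd1_lfc: float = 1.0  # log2 vs normal-B reference
    cnv_reference_quantile: float = 0.95


def marker_scores(adata, labels: pd.Series, markers: list[str]) -> pd.Series:
    """Per-cluster mean of per-cell mean log-normalized marker expression."""
    present = [g for g in markers if g in adata.var_names]
    if not present:
        raise ValueError(f"none of the markers {markers} present in the matrix")
    X = sp.csr_matrix(adata.X)
    sub = np.asarray(X[:, [adata.var_names.get_loc(g) for g in present]].todense())
    per_cell = pd.Series(sub.mean(axis=1), index=adata.obs_names)
    return per_cell.groupby(labels).mean()


def flag_doublets(
    scores: pd.DataFrame,
    cohort_scores: pd.DataFrame | None = None,
    b_threshold: float | None = None,
    t_threshold: float | None = None,
) -> pd.Series:
    """Flag clusters expressing both B and T marker programs.

    ``scores`` has one row per candidate (B-subset) cluster with columns
    ``b_score``/``t_score``; ``cohort_scores`` supplies the clusters used to
    set thresholds (pass the full-dataset clusters so the score range spans
    genuine negatives; defaults to ``scores``). A cluster is flagged when
    both scores lie in the upper half of the cohort range, i.e. above the
    midpoint of the observed min and max.
    """
    if scores[["b_score", "t_score"]].isna().any().any():
        raise ValueError("marker scores unavailable for some clusters")
    ref = scores if cohort_scores is None else cohort_scores
    if b_threshold is None:
        b_threshold = (ref["b_score"].min() + ref["b_score"].max()) / 2.0
    if t_threshold is None:
        t_threshold = (ref["t_score"].min() + ref["t_score"].max()) / 2.0
    flagged = (scores["b_score"] > b_threshold) & (scores["t_score"] > t_threshold)
    return flagged.rename("doublet")


def classify_b_clusters(
    evidence: pd.DataFrame,
    thresholds: Thresholds | None = None,
    use_cnv: bool = True,
) -> pd.Series:
    """Label each B subcluster malignant, normal or ambiguous.

    ``evidence`` has one row per cluster with columns:

    * ``clonotype_fraction`` — dominant-clonotype fraction among the
      cluster's BCR-assigned cells (NaN switches that cluster to
      three-channel mode);
    * ``ratio_mean`` / ``ratio_sd`` — light-chain ratio statistics;
    * ``ccnd1_lfc`` — log2 fold-change of CCND1 vs the normal-B reference;
    * ``cnv_score_median`` and ``cnv_reference`` — the cluster's median
      CNV score and the normal-B reference (95th percentile).

    malignant = all primary channels positive and CNV confirms;
    primary-positive but CNV-discordant clusters are ambiguous; clusters
    with no positive channel are normal; anything else is ambiguous.
    ``use_cnv=False`` drops the confirmatory channel entirely, which can
    only move labels between malignant/ambiguous or normal/ambiguous.
    """
    thr = thresholds or Thresholds()
    out = {}
    for cl, row in evidence.iterrows():
        has_bcr = not pd.isna(row["clonotype_fraction"])
        bcr_pos = has_bcr and row["clonotype_fraction"] >= thr.min_clonotype_fraction
        ratio_pos = (
            not pd.isna(row["ratio_mean"])
            and abs(row["ratio_mean"] - 0.5) >= thr.ratio_mean_margin
            and row["ratio_sd"] <= thr.ratio_sd_max
        )
        ccnd1_pos = row["ccnd1_lfc"] >= thr.min_ccnd1_lfc
        cnv_pos = row["cnv_score_median"] > row["cnv_reference"]
        primary = [ratio_pos, ccnd1_pos] + ([bcr_pos] if has_bcr else [])
        if all(primary):
            out[cl] = "malignant" if (cnv_pos or not use_cnv) else "ambiguous"
        elif not any(primary) and not (cnv_pos and use_cnv):
            out[cl] = "normal"
        else:
            out[cl] = "ambiguous"
    return pd.Series(out, name="call")


def build_cluster_evidence(
    adata,
    labels: pd.Series,
    clonotype_fraction: pd.Series,
    cell_ratio: pd.Series,
    ccnd1_lfc: pd.Series,
    cnv_scores: pd.Series,
    cnv_reference: float,
    b_scores: pd.Series,
    t_scores: pd.Series,
) -> pd.DataFrame:
    """Assemble the per-cluster evidence table from per-cell inputs."""
    clusters = sorted(labels.unique())
    rows = []
    for cl in clusters:
        cells = labels.index[labels == cl]
        ratios = cell_ratio.loc[cells].dropna()
        rows.append(
            dict(
                cluster=cl,
                n_cells=len(cells),
                clonotype_fraction=clonotype_fraction.get(cl, np.nan),
                ratio_mean=ratios.mean() if len(ratios) else np.nan,
                ratio_sd=ratios.std(ddof=0) if len(ratios) else np.nan,
                ccnd1_lfc=ccnd1_lfc.get(cl, np.nan),
                cnv_score_median=float(cnv_scores.loc[cells].median()),
                cnv_reference=cnv_reference,
                b_score=b_scores.get(cl, np.nan),
                t_score=t_scores.get(cl, np.nan),
            )
        )
    return pd.DataFrame(rows).set_index("cluster")
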