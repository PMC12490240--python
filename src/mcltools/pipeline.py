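"""End-to-end malignant-cell identification over a multi-sample cohort.

Composes the stages: QC -> normalization -> clustering -> major cell types
-> B-cell reclustering -> BCR clonotypes -> light-chain ratio -> CCND1 ->
expression-CNV -> per-cluster classification. Every B cell receives a label
(malignant / normal / ambiguous / doublet); non-B cells keep their major
type. Deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bcr as bcr_mod
from . import cnv as cnv_mod
from .malignant import (
    DOUBLET_B_MARKERS,
    DOUBLET_T_MARKERS,
    Thresholds,
    build_cluster_evidence,
    classify_b_clusters,
    flag_doublets,
    marker_scores,
)
from .preprocess import (
    annotate_major_types,
    apply_qc,
    cluster_cells,
    normalize_log,
)

logger = logging.getLogger(__name__)


@dataclass
class MalignantCallResult:
    labels: pd.Series  # per surviving cell: malignant/normal/ambiguous/doublet or major type
    evidence: pd.DataFrame  # per B subcluster
    b_cluster_labels: pd.Series
    b_cluster_calls: pd.Series
    global_labels: pd.Series
    global_types: pd.Series
    cnv_scores: pd.Series  # per B cell
    cnv_reference: float
    clonotypes: "bcr_mod.ClonotypeSet"
    normalized: object  # the QC'd, log-normalized AnnData


def dominant_clonotype_fraction(
    cset: bcr_mod.ClonotypeSet, labels: pd.Series, min_bcr_cells: int = 5
) -> pd.Series:
    """Per-cluster fraction of BCR-assigned cells carrying the modal clonotype."""
    assigned = cset.cells.set_index("cell_id")["clonotype"]
    out = {}
    for cl in sorted(labels.unique()):
        cells = labels.index[labels == cl]
        sub = assigned.reindex(cells).dropna()
        if len(sub) < min_bcr_cells:
            out[cl] = np.nan
            continue
        out[cl] = sub.value_counts().iloc[0] / len(sub)
    return pd.Series(out, name="clonotype_fraction")


def identify_malignant(
    adata,
    bcr_table: pd.DataFrame | None = None,
    seed: int = 0,
    resolution: float = 0.6,
    thresholds: Thresholds | None = None,
    cnv_window: int = 51,
    min_reference_cells: int = 20,
) -> MalignantCallResult:
    """Label every B cell malignant, normal, ambiguous or doublet.

    ``adata`` holds raw counts; ``bcr_table`` is the AIRR-style
    rearrangement table (omit it for three-channel mode without BCR
    evidence). The normal-B reference is taken from B subclusters without a
    dominant clonotype; it anchors the CCND1 fold-change, the CNV baseline
    and the CNV-score 95th-percentile threshold.
    """
    thresholds = thresholds or Thresholds()
    qc = apply_qc(adata)
    norm = normalize_log(qc)
    global_clusters = cluster_cells(norm, resolution=resolution, seed=seed)
    type_call = annotate_major_types(norm, global_clusters)
    global_types = type_call.cell_types(global_clusters.labels)

    b_scores_global = marker_scores(norm, global_clusters.labels, DOUBLET_B_MARKERS)
    t_scores_global = marker_scores(norm, global_clusters.labels, DOUBLET_T_MARKERS)
    cohort_scores = pd.DataFrame(
        {"b_score": b_scores_global, "t_score": t_scores_global}
    )

    # B compartment: clusters typed B, plus clusters co-expressing B and T
    # markers (where T/B doublets tend to land at the global resolution)
    global_flags = flag_doublets(cohort_scores)
    b_like = [
        cl
        for cl, t in type_call.cluster_types.items()
        if t == "B" or bool(global_flags.get(cl, False))
    ]
    b_cells = global_clusters.labels.index[global_clusters.labels.isin(b_like)]
    if len(b_cells) < 2:
        raise ValueError("no B-cell compartment found")
    norm_b = norm[b_cells].copy()
    b_clusters = cluster_cells(norm_b, resolution=resolution, seed=seed)
    b_labels = b_clusters.labels

    # BCR evidence
    if bcr_table is not None:
        paired = bcr_mod.filter_rearrangements(bcr_table)
        cset = bcr_mod.assign_clonotypes(paired)
        dom_frac = dominant_clonotype_fraction(cset, b_labels)
    else:
        logger.info("no BCR table supplied: three-channel mode")
        cset = bcr_mod.assign_clonotypes(bcr_mod.filter_rearrangements(pd.DataFrame()))
        dom_frac = pd.Series(np.nan, index=sorted(b_labels.unique()))

    cell_ratio = bcr_mod.cell_light_chain_ratio(norm_b)

    b_score = marker_scores(norm_b, b_labels, DOUBLET_B_MARKERS)
    t_score = marker_scores(norm_b, b_labels, DOUBLET_T_MARKERS)
    sub_scores = pd.DataFrame({"b_score": b_score, "t_score": t_score})
    doublet_flags = flag_doublets(sub_scores, cohort_scores=cohort_scores)

    # provisional normal-B reference: non-doublet clusters without clonal BCR
    normal_clusters = [
        cl
        for cl in sub_scores.index
        if not doublet_flags.loc[cl]
        and not (
            not pd.isna(dom_frac.get(cl, np.nan))
            and dom_frac[cl] >= thresholds.min_clonotype_fraction
        )
    ]
    ref_cells = b_labels.index[b_labels.isin(normal_clusters)]
    if len(ref_cells) == 0:
        raise ValueError("no normal-B reference cells available")

    # CCND1 log2 fold-change per cluster vs the reference
    import scipy.sparse as sp

    X = sp.csr_matrix(norm_b.X)
    ccnd1 = pd.Series(
        np.asarray(X[:, norm_b.var_names.get_loc("CCND1")].todense()).ravel(),
        index=norm_b.obs_names,
    )
    eps = 1e-9
    ref_mean = np.expm1(ccnd1.loc[ref_cells]).mean()
    ccnd1_lfc = pd.Series(
        {
            cl: np.log2(
                (np.expm1(ccnd1.loc[b_labels.index[b_labels == cl]]).mean() + eps)
                / (ref_mean + eps)
            )
            for cl in sub_scores.index
        }
    )

    # expression CNV: reference = provisional normal B (fallback: non-B cells)
    cnv_ref = ref_cells
    if len(cnv_ref) < min_reference_cells:
        cnv_ref = global_types.index[
            global_types.isin(["T", "NK", "myeloid"])
        ]
        logger.info("normal-B reference too small; using non-B cells for CNV")
    cnv_cells = pd.Index(b_cells).union(cnv_ref)
    profile = cnv_mod.infer_cnv_profile(norm[cnv_cells].copy(), cnv_ref, window=cnv_window)
    scores_all = cnv_mod.cnv_score(profile)
    cnv_scores = scores_all.loc[b_cells]
    cnv_reference = float(
        np.quantile(scores_all.loc[ref_cells], thresholds.cnv_reference_quantile)
    )

    evidence = build_cluster_evidence(
        norm_b, b_labels, dom_frac, cell_ratio, ccnd1_lfc,
        cnv_scores, cnv_reference, b_score, t_score,
    )
    calls = classify_b_clusters(evidence, thresholds)
    calls[doublet_flags.reindex(calls.index).fillna(False)] = "doublet"

    labels = global_types.copy().astype(object)
    labels.loc[b_labels.index] = b_labels.map(calls).to_numpy()
    labels = labels.rename("label")

    return MalignantCallResult(
        labels=labels,
        evidence=evidence,
        b_cluster_labels=b_labels,
        b_cluster_calls=calls,
        global_labels=global_clusters.labels,
        global_types=global_types,
        cnv_scores=cnv_scores,
        cnv_reference=cnv_reference,
        clonotypes=cset,
        normalized=norm,
    )
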