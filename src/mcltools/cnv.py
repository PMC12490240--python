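"""Expression-inferred copy-number profiles and the per-cell CNV score.

Relative expression along genome order is compared to a reference cell set,
clipped, smoothed by a moving window within each chromosome, re-centered
per cell and exponentiated to a ratio around 1.0. The CNV score of a cell
is the number of genes whose smoothed ratio falls below 0.95 or above 1.05,
genome-wide or within a region. Immunoglobulin-locus genes are excluded by
default because clonal Ig expression mimics copy-number gain.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

LOWER_BAND = 0.95
UPPER_BAND = 1.05
WGS_AMP = 2.3
WGS_DEL = 1.7


def _chrom_sort_key(chrom: str):
    m = re.match(r"chr(\d+)$", str(chrom))
    if m:
        return (0, int(m.group(1)))
    return (1, str(chrom))


@dataclass
class CnvProfile:
    values: pd.DataFrame  # cells x genes (genome order), ratios centered at 1.0
    gene_meta: pd.DataFrame  # chrom, start for the profiled genes, same order
    window: int
    reference: pd.Index

    def mean_profile(self, cells=None) -> pd.Series:
        sub = self.values if cells is None else self.values.loc[cells]
        return sub.mean(axis=0)


def _smooth_block(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over axis 1 with shrinking edge windows."""
    if window == 1 or block.shape[1] == 1:
        return block
    n = block.shape[1]
    half = window // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    cs = np.concatenate(
        [np.zeros((block.shape[0], 1)), np.cumsum(block, axis=1)], axis=1
    )
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def infer_cnv_profile(
    adata,
    reference_cells,
    window: int = 51,
    clip_sd: float = 3.0,
    denoise_sd: float = 2.5,
    exclude_ig: bool = True,
) -> CnvProfile:
    """Reference-relative smoothed expression ratios along the genome.

    ``adata`` carries log-normalized expression in ``.X`` and per-gene
    ``chrom``/``start`` in ``.var``. Per gene, the reference mean is
    subtracted in log space and the residual clipped at +/- ``clip_sd``
    reference standard deviations; a centered ``window``-gene moving average
    is applied within each chromosome (edges shrink); each cell is then
    re-centered by its median; residuals within ``denoise_sd`` reference
    standard deviations of the smoothed reference profile are zeroed
    (``denoise_sd=0`` disables denoising); finally the result is
    exponentiated to a ratio around 1.0.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    reference_cells = pd.Index(reference_cells)
    if len(reference_cells) < 2:
        raise ValueError("need at least 2 reference cells")
    var = adata.var
    placed = var["chrom"].notna() & var["start"].notna()
    if (~placed).any():
        warnings.warn(f"excluding {int((~placed).sum())} unplaced genes")
    keep = placed.copy()
    if exclude_ig and "is_ig" in var:
        keep &= ~var["is_ig"].astype(bool)
    genes = var.index[keep]
    meta = var.loc[genes, ["chrom", "start"]].copy()
    meta["_key"] = meta["chrom"].map(_chrom_sort_key)
    meta = meta.sort_values(["_key", "start"], kind="stable").drop(columns="_key")
    genes = meta.index

    X = sp.csr_matrix(adata.X)
    cols = [adata.var_names.get_loc(g) for g in genes]
    expr = np.asarray(X[:, cols].todense())
    ref_rows = [adata.obs_names.get_loc(c) for c in reference_cells]
    ref = expr[ref_rows]
    ref_mean = ref.mean(axis=0)
    ref_sd = ref.std(axis=0)

    rel = expr - ref_mean
    bound = clip_sd * ref_sd
    rel = np.clip(rel, -bound, bound)

    chroms = meta["chrom"].to_numpy()
    out = np.empty_like(rel)
    start = 0
    for chrom in pd.unique(chroms):
        block = np.flatnonzero(chroms == chrom)
        out[:, block] = _smooth_block(rel[:, block], window)
        start += len(block)
    out = out - np.median(out, axis=1, keepdims=True)
    if denoise_sd > 0:
        ref_sd = out[ref_rows].std(axis=0)
        out[np.abs(out) <= denoise_sd * ref_sd] = 0.0
    ratios = np.exp(out)
    values = pd.DataFrame(ratios, index=adata.obs_names, columns=genes)
    return CnvProfile(values=values, gene_meta=meta, window=window,
                      reference=reference_cells)


def cnv_score(
    profile: CnvProfile,
    region: tuple[str, int, int] | None = None,
    lower: float = LOWER_BAND,
    upper: float = UPPER_BAND,
) -> pd.Series:
    """Per-cell count of genes with ratio < ``lower`` or > ``upper``.

    ``region`` is an optional 1-based inclusive (chrom, start, end)
    interval restricting the counted genes.
    """
    vals = profile.values
    if region is not None:
        chrom, start, end = region
        meta = profile.gene_meta
        in_region = (
            (meta["chrom"] == chrom) & (meta["start"] >= start) & (meta["start"] <= end)
        )
        if not in_region.any():
            warnings.warn(f"region {region} contains no profiled genes")
            return pd.Series(0, index=vals.index, name="cnv_score")
        vals = vals.loc[:, in_region.to_numpy()]
    outside = (vals.to_numpy() < lower) | (vals.to_numpy() > upper)
    return pd.Series(outside.sum(axis=1), index=vals.index, name="cnv_score")


def gene_direction_calls(profile: CnvProfile, cells=None) -> pd.Series:
    """Per-gene gain/neutral/loss call from the mean profile of ``cells``."""
    mean = profile.mean_profile(cells)
    calls = pd.Series("neutral", index=mean.index, name="call")
    calls[mean > UPPER_BAND] = "gain"
    calls[mean < LOWER_BAND] = "loss"
    return calls


def concordance_with_wgs(
    profile: CnvProfile,
    wgs_segments: pd.DataFrame,
    cells=None,
    amp_threshold: float = WGS_AMP,
    del_threshold: float = WGS_DEL,
) -> float:
    """Direction agreement between the expression profile and bulk WGS.

    WGS segments (1-based inclusive: chrom, start, end, copy_number) are
    classified amplified (>= 2.3 copies) / deleted (<= 1.7) / neutral; genes
    covered by any non-neutral segment are compared to the expression-based
    gain/loss call. Returns agreeing / covered, or NaN with no overlap.
    """
    calls = gene_direction_calls(profile, cells)
    meta = profile.gene_meta
    agree = covered = 0
    for _, seg in wgs_segments.iterrows():
        cn = seg["copy_number"]
        if del_threshold < cn < amp_threshold:
            continue
        wgs_call = "gain" if cn >= amp_threshold else "loss"
        genes = meta.index[
            (meta["chrom"] == seg["chrom"])
            & (meta["start"] >= seg["start"])
            & (meta["start"] <= seg["end"])
        ]
        covered += len(genes)
        agree += int((calls.loc[genes] == wgs_call).sum())
    if covered == 0:
        return float("nan")
    return agree / covered
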