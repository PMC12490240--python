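"""Readers/writers for the plain-text exchange formats the pipeline uses.

Count matrices travel as 10x-style Matrix Market triplets (matrix.mtx +
features.tsv + barcodes.tsv); BCR rearrangements, variant calls, panels,
pileups and segments as TSV; ground truth as JSON (see
:class:`mcltools.simulate.GroundTruth`).
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def write_10x_dir(adata: ad.AnnData, outdir: str) -> None:
    """Write counts as matrix.mtx (genes x cells, 10x orientation) + TSVs."""
    os.makedirs(outdir, exist_ok=True)
    X = sp.csc_matrix(adata.X.T)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), X, field="integer")
    feats = adata.var.reset_index()
    feats.to_csv(os.path.join(outdir, "features.tsv"), sep="\t", index=False)
    obs = adata.obs.reset_index()
    obs.to_csv(os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False)


def read_10x_dir(indir: str) -> ad.AnnData:
    X = scipy.io.mmread(os.path.join(indir, "matrix.mtx"))
    var = pd.read_csv(os.path.join(indir, "features.tsv"), sep="\t")
    obs = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t")
    var = var.set_index(var.columns[0])
    obs = obs.set_index(obs.columns[0])
    return ad.AnnData(X=sp.csr_matrix(X.T), obs=obs, var=var)


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bed_ig_loci(path: str) -> pd.DataFrame:
    """Read Ig loci from BED (0-based half-open) into 1-based inclusive."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame(
        {
            "chrom": bed[0],
            "start": bed[1].astype(int) + 1,
            "end": bed[2].astype(int),
        }
    )
    if bed.shape[1] > 3:
        out["locus"] = bed[3]
    return out


def read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def matrix_bytes(adata: ad.AnnData) -> bytes:
    """Canonical byte serialization of a count matrix, for determinism checks."""
    X = sp.csr_matrix(adata.X)
    X.sort_indices()
    return (
        X.indptr.tobytes()
        + X.indices.tobytes()
        + np.asarray(X.data).tobytes()
        + "\n".join(adata.obs_names).encode()
        + "\n".join(adata.var_names).encode()
    )
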